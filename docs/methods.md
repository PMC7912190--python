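# Methods

## Thermal indices

All indices are computed per reading from dry-bulb temperature (AT, °C),
relative humidity (RH, %), air speed (AS, m/s) and black-globe temperature
(GT, °C).

**Dew point.** Magnus-form inversion: `b = [ln(RH/100) +
17.27·AT/(237.3+AT)]/17.27`, `Tdp = 237.3·b/(1−b)`. `ln` is the natural
logarithm; at saturation (RH = 100) this gives `Tdp = AT` exactly. RH = 0
is a domain error (reported as invalid humidity), not a value.

**THI (Yousef).** `THI = AT + 0.36·Tdp + 41.2`; an exact affine form,
monotone in both arguments. Other THI formulations can be layered on top
of the index engine but are not built in.

**HLI.** Piecewise in GT with the branch switch at GT = 25 °C; GT = 25
exactly takes the high branch. The low-branch humidity coefficient
defaults to 0.28 (the coefficient of the source HLI formulation); the
value 2.8 that circulates in some secondary descriptions is physically
implausible (RH = 80% alone would contribute 224 index units) but can be
requested via `low_rh_coeff=2.8` or the CLI flag for comparison work.

**AHLU.** Hourly increment `HLI − 77` below the lower threshold (77),
zero in [77, 86], `HLI − 86` above the upper threshold (86); thresholds
configurable. The series starts fresh at the first time point of a
farm-day — its first value is the unweighted increment there — and each
later value adds increment × interval (hours), clamping at zero after
every update. There is no overnight carry-over between farm-days.
Irregular measurement intervals are supported; the 11:00 → 14:00 gap is an
ordinary 3 h interval. Heat-stress bands for all four indices are
half-open `[lower, upper)` and partition the real line.

A consequence worth noting for anyone comparing against daily summary
tables: daily-mean HLI is *not* HLI of the daily-mean inputs wherever GT
crosses 25 °C during the day. In highland-like conditions the morning
readings sit on the low branch, pulling the daily mean HLI several units
below the high-branch value at mean inputs; only where the high branch
applies all day do the two agree to ~1 unit.

## Synthetic study-design generator

The generator emulates a four-region (SL/SH south, NL/NH north; lowland
altitudes ~31–47 m, highlands ~937–967 m), eight-farms-per-region design
with seven measurement hours (06:00, 08:00, 10:00, 11:00, 14:00, 16:00,
18:00).

**Housing tables.** Quantitative variables are truncated normals centred
on region-typical medians (e.g. floor area 5.2/7.5/6.7/12.5 m²/cow for
SL/SH/NL/NH) with per-variable absolute spreads (MatCow 1.0, FloorCow 2.0,
RidgeHei 0.6, EaveHei 0.5, SideOpen 15, FanCow 0.15, HoseCoFlo 0.5)
chosen so that variables that do not differ regionally in this kind of
survey (mat area, ridge height, hosing frequency) really overlap across
regions while the regionally distinctive ones (floor area, eave height,
fans) remain distinctive. Ridge height is floored at eave height.
Qualitative variables are drawn from regional frequencies through a single
per-farm latent "equipment level" (comonotone coupling): the same farms
that fit roof soakers also tend to have fans, roof vents, asbestos roofs
and tie-up stalls. This coupling preserves the regional margins and is
what makes housing type, roof type, fans-per-cow and roof soakers mutually
collinear (VIF > 5) — the confounding structure the regression screen has
to resolve.

**Model mode** draws each response (AT, AS, HLI, THI) from its own linear
predictor — intercept + altitude + south-latitude + eave height + floor
area + sides-open terms (defaults: AT intercept 33.86, altitude −0.004/m,
south −1.43, eave −0.87, floor −0.12; HLI 107.1, −0.013, −2.46, −3.31,
sides-open −0.05; THI 88.01, −0.008, −1.57, −1.42; AS eave +0.14) — plus a
diurnal offset and Gaussian noise (sd 0.8 °C AT, 0.12 m/s AS, 2.0 HLI, 1.2
THI per time point, keeping model R² near 79/15/88/86%). The diurnal
offset is zero at the 11:00 reference hour and equal at 11:00 and 14:00
(midday plateau), so on dip-active farms the 11:00-vs-14:00 paired
contrast isolates the soaker/fan dip. The four responses are generated
independently from their own fitted forms; no single physically consistent
set of raw readings can reproduce all four fitted models at once, which is
why coefficient-recovery work uses this mode.

**Physical mode** generates raw AT/RH/AS/GT series (GT = AT + 0.4 °C,
diurnal AT and RH shapes summing to zero around the regional daily means)
for exercising the index pipeline end to end. It makes no attempt to match
the model-mode fitted coefficients.

**Soaker/fan dip.** North-lowland farms run roof soakers and fans through
the hottest hours; this is modelled as fixed per-response amplitudes
(AT −1.3 °C, HLI −3.2, THI −2.5) subtracted inside a clock-time window,
default {14:00, 16:00}: systems go on around 10:00 and the cooling effect
is at full amplitude by early afternoon, so the 11:00 value is still
undipped. The dip is phenomenological, not a fan/soaker physical model.

**Archetype fixture.** For cluster-recovery testing the generator can draw
32 farms from 7 housing archetypes with membership sizes (4, 10, 9, 1, 2,
1, 5): a common baseline cowshed plus one distinctive signature per
archetype (extra mats; wide-open sides; tight tie-up floor space; very
large floor area; sprinkler+soaker cooling; tall ridge with frequent
hosing; the fan+soaker+asbestos tie-up package). Signatures deviate on
near-disjoint variables so that no single component swallows the cluster
structure, and within-archetype noise (2% of each variable's range) keeps
the separation far above ten within-archetype spreads.

**Seeds.** The default seed is 20170824; every draw flows from
`numpy.random.default_rng(seed)`, so all outputs are reproducible
byte-for-byte.

What the generator does *not* emulate: day-to-day and seasonal weather
variation (each farm gets one synthetic day), within-shed spatial
variation, measurement error of the logger, and any dependence of housing
on unobserved farm wealth or herd size. Tests passing on this generator
show the estimators recover the structure they were built for, not that
the fitted values would hold on new field data.

## Factor analysis of mixed data and clustering

**Encoding.** Quantitative columns are centred and scaled by the
population (1/n) standard deviation; a constant column is an error. Each
qualitative category indicator is divided by √(category proportion) and
centred (MCA weighting), so one qualitative variable with K observed
categories contributes total inertia K − 1 and the two blocks are
comparable.

**Decomposition.** Plain SVD of the encoded matrix; eigenvalues are
squared singular values over n; row scores are U·s so that retaining all
components reconstructs the encoded matrix to machine precision.

**Retention.** The smallest m whose cumulative explained-variance share
reaches the threshold (default 0.70).

**Clustering.** Ward linkage on Euclidean distances of the first m scores
only. The suggested cut maximises the ratio of successive within-inertia
losses ΔW(k)/ΔW(k+1), k in [2, 10]: the best k is the one after which
further splitting stops paying. All points identical is degenerate
(k = 1). The partition is consolidated by Lloyd iterations started from
the hierarchical-cut centroids — deterministic, no random restarts; an
emptied cluster is re-seeded at the point farthest from its assigned
centroid; at most 100 rounds.

**V-tests.** Quantitative: `v = (x̄_k − x̄) / sqrt(((N−n_k)/(N−1))·s²/n_k)`
with s the population sd over all N farms, two-sided p from the standard
normal; zero overall variance is reported as not applicable. Qualitative:
hypergeometric tail for the category count in the cluster (drawing n_k
from N with K category members); v is the signed standard-normal quantile
of the smaller tail (positive = over-represented) and the reported p is
twice the smaller tail, capped at 1. V-test p-values are reported
unadjusted.

## Regression protocol

Candidate predictors: altitude (m), latitude class (south vs north
reference) and the twelve housing variables; qualitative predictors enter
as treatment contrasts with recorded references (latitude: north;
otherwise the alphabetically first observed level).

**VIF screening.** `VIF_j = 1/(1−R²_j)` from regressing column j on all
other candidates (intercept included); perfect collinearity reports +inf.
The single highest-VIF column is removed repeatedly until all remaining
are below the threshold (default 5); ties break by column order and every
removal is logged. Altitude and latitude are exempt from removal (they are
the design's geography terms — the main drivers of outdoor climate — and
the screen's job is to resolve collinearity among the housing variables
around them); the exemption is configurable via `ModelSpec.forced`.

**Backward elimination.** From the screened model, repeatedly drop the
term with the largest p-value above the retention threshold (default 0.1)
and refit; a multi-level categorical term is dropped as a block judged by
its largest level p. The intercept is exempt and an intercept-only final
model is allowed (a humidity model typically ends there).

**Diagnostics.** Internally standardised residuals and hat-matrix
leverage, flagged at |r| > 3 and h > 2·p/n (both configurable). P-values
are classical t-based; no small-sample corrections and no robust errors.

## Comparison battery

The normality gate applies Shapiro–Wilk (α = 0.05) to pooled
within-group-centred residuals, not raw values, so group mean shifts do
not masquerade as non-normality; constant data is non-normal by
convention. Normal variables: one-way ANOVA with Tukey–Kramer pairwise
comparisons (valid for unequal n). Non-normal: Kruskal–Wallis with tie
correction and Dunn post hoc z tests, Holm-adjusted by default
(configurable). Categorical: exact R×C Fisher test computed by full
enumeration of tables with the observed margins (two-sided: total
probability of tables no more probable than the observed one); beyond an
enumeration budget the p-value falls back to fixed-seed Monte Carlo
(100,000 draws) and the method used is recorded in the output. Pairwise
group comparisons use 2×2 Fisher tests with Bonferroni multiplication.
Pairwise outcomes condense to a compact letter display built from maximal
runs of mutually non-significant groups ordered by mean.

The cluster-effect analysis is a two-way ANOVA of each microclimate
response on the cluster factor plus altitude and latitude covariates,
using Type-II sums of squares (clusters are unbalanced); clusters with
three or fewer members are excluded first.

## Pipeline and reproducibility

Every stage reads and writes plain UTF-8 CSV with documented columns, so
any stage can be re-run from persisted intermediates. Each run writes the
resolved YAML config and a log with package version, seed and config hash.
Report tables round temperatures and indices to one decimal; machine
outputs keep full precision.

The acceptance script re-estimates the recovery targets at 20 replicates
of 100 farms per region (8,000 farms per response model) and 20 dip-active
cohorts of 8 farms; these sizes give Monte-Carlo standard errors an order
of magnitude below the quantities being recovered while the whole script
completes in seconds.
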