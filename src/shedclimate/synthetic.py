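"""Synthetic smallholder-dairy-farm housing tables and diurnal microclimate.

The study design being emulated: four climatically contrasting regions of
Vietnam — south lowland (SL), south highland (SH), north lowland (NL) and
north highland (NH) — with eight smallholder dairy farms (SDFs) per region,
each farm described by seven quantitative and five qualitative housing
variables, and its cowshed microclimate measured at seven clock times
(06:00–18:00) in one day.

Two generation modes:

``model``
    Each microclimate response (AT, AS, HLI, THI) is drawn directly from its
    fitted linear predictor (intercept + altitude + latitude + eave height +
    floor area + sides-open terms) plus a diurnal offset and Gaussian noise.
    This is the mode for coefficient-recovery work: the study fitted HLI and
    THI as responses in their own right, and no single set of physically
    consistent raw readings can reproduce all four fitted models at once.

``physical``
    Raw AT/RH/AS/GT series from regional diurnal curves (GT = AT + 0.4 °C),
    for exercising the index pipeline end to end.

North-lowland farms run roof soakers and fans during the hottest part of
the day; this appears as a configurable midday dip subtracted from AT, HLI
and THI within a clock-time window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegionSpec",
    "SoakerDip",
    "GeneratorConfig",
    "REGIONS",
    "MEASUREMENT_HOURS",
    "REFERENCE_HOUR",
    "generate_farms",
    "generate_archetype_farms",
    "generate_microclimate",
    "ARCHETYPES",
    "ARCHETYPE_SIZES",
]

#: Measurement clock times, fractional hours.
MEASUREMENT_HOURS = (6.0, 8.0, 10.0, 11.0, 14.0, 16.0, 18.0)

#: Clock time at which the model-mode diurnal offset is zero, so that the
#: linear-predictor intercept is the expected response at this hour.
REFERENCE_HOUR = 11.0

QUANTITATIVE_VARS = ("MatCow", "FloorCow", "RidgeHei", "EaveHei",
                     "SideOpen", "FanCow", "HoseCoFlo")
QUALITATIVE_VARS = ("Housing", "RoofType", "RoofVent", "Sprinkler", "RoofCooler")


@dataclass(frozen=True)
class SoakerDip:
    """Midday roof-soaker + fan cooling dip subtracted from model-mode responses.

    Amplitudes are per response (°C for AT, index units for HLI/THI) and are
    applied in full at each clock time in ``window``.  The default window is
    14:00–16:00: systems go on around 10:00 and the cooling effect is at
    full amplitude by early afternoon, so the 11:00-vs-14:00 contrast equals
    the configured amplitude.
    """

    active: bool = False
    dAT: float = 1.3
    dHLI: float = 3.2
    dTHI: float = 2.5
    window: tuple[float, ...] = (14.0, 16.0)


@dataclass(frozen=True)
class RegionSpec:
    """Region-level generating parameters (altitudes, diurnal levels, dip)."""

    name: str
    altitude_mean: float          # m
    altitude_sd: float            # m
    latitude_class: str           # "north" | "south"
    at_mean: float                # daily-mean dry-bulb temperature, °C
    rh_level: float               # %
    as_level: float               # m/s
    soaker_dip: SoakerDip = field(default_factory=SoakerDip)


# Regional daily means: altitudes 47/967/31/937 m, AT 29.5/25.4/29.7/26.0 °C,
# RH ~81%, AS 0.33-0.47 m/s.  Altitude spreads are assumptions (the study
# reports only regional means): 10 m within a lowland district, 60 m within
# a highland one.
REGIONS: dict[str, RegionSpec] = {
    "SL": RegionSpec("SL", 47.0, 10.0, "south", 29.5, 81.8, 0.44),
    "SH": RegionSpec("SH", 967.0, 60.0, "south", 25.4, 80.5, 0.36),
    "NL": RegionSpec("NL", 31.0, 10.0, "north", 29.7, 82.0, 0.47,
                     SoakerDip(active=True)),
    "NH": RegionSpec("NH", 937.0, 60.0, "north", 26.0, 80.6, 0.33),
}

# Within-region spreads (sd of the truncated normal) of the quantitative
# housing variables.  Anchored to the reported overall spreads (e.g. mat
# area 1.17 ± 1.09 m²/cow across all farms): large enough that variables
# reported as similar across regions (mat area, ridge height, sides open,
# hosing) really are similar, while regionally distinctive ones (floor
# area, eave height, fans) stay distinctive.
HOUSING_SDS: dict[str, float] = {
    "MatCow": 1.0, "FloorCow": 2.0, "RidgeHei": 0.6, "EaveHei": 0.5,
    "SideOpen": 15.0, "FanCow": 0.15, "HoseCoFlo": 0.5,
}

# Regional medians of the quantitative housing variables.
HOUSING_MEDIANS: dict[str, dict[str, float]] = {
    "MatCow":    {"SL": 0.6, "SH": 0.0, "NL": 1.4, "NH": 1.4},
    "FloorCow":  {"SL": 5.2, "SH": 7.5, "NL": 6.7, "NH": 12.5},
    "RidgeHei":  {"SL": 3.3, "SH": 3.3, "NL": 4.1, "NH": 3.6},
    "EaveHei":   {"SL": 2.6, "SH": 2.3, "NL": 3.4, "NH": 2.8},
    "SideOpen":  {"SL": 75.0, "SH": 87.0, "NL": 75.0, "NH": 90.0},
    "FanCow":    {"SL": 0.1, "SH": 0.0, "NL": 0.8, "NH": 0.0},
    "HoseCoFlo": {"SL": 2.0, "SH": 2.0, "NL": 2.0, "NH": 2.0},
}

# Regional frequencies (out of 8 farms) of the first-listed category.
HOUSING_QUAL_PROBS: dict[str, tuple[str, str, dict[str, float]]] = {
    # variable: (category if "success", other category, P(success) per region)
    "Housing":    ("loose", "tie-up",
                   {"SL": 0 / 8, "SH": 8 / 8, "NL": 3 / 8, "NH": 8 / 8}),
    "RoofType":   ("asbestos", "metal",
                   {"SL": 0 / 8, "SH": 1 / 8, "NL": 7 / 8, "NH": 3 / 8}),
    "RoofVent":   ("yes", "no",
                   {"SL": 0 / 8, "SH": 1 / 8, "NL": 8 / 8, "NH": 3 / 8}),
    "Sprinkler":  ("yes", "no",
                   {"SL": 0 / 8, "SH": 0 / 8, "NL": 2 / 8, "NH": 0 / 8}),
    "RoofCooler": ("yes", "no",
                   {"SL": 0 / 8, "SH": 0 / 8, "NL": 7 / 8, "NH": 0 / 8}),
}

# Final fitted-model coefficients used as the model-mode generating truth.
# Terms: intercept, altitude (per m), latitude-south indicator, eave roof
# height (per m), floor area (per m²/cow), shed sides open (per %).
MODEL_COEFFICIENTS: dict[str, dict[str, float]] = {
    "AT":  {"intercept": 33.86, "altitude": -0.004, "latitude_south": -1.43,
            "EaveHei": -0.87, "FloorCow": -0.12, "SideOpen": 0.0},
    "AS":  {"intercept": 0.02, "altitude": 0.0, "latitude_south": 0.0,
            "EaveHei": 0.14, "FloorCow": 0.0, "SideOpen": 0.0},
    "HLI": {"intercept": 107.1, "altitude": -0.013, "latitude_south": -2.46,
            "EaveHei": -3.31, "FloorCow": 0.0, "SideOpen": -0.05},
    "THI": {"intercept": 88.01, "altitude": -0.008, "latitude_south": -1.57,
            "EaveHei": -1.42, "FloorCow": 0.0, "SideOpen": 0.0},
}

# Residual noise standard deviations per response (per time point), chosen
# to keep model R² in the neighbourhood of the fitted models' 79/15/88/86%.
MODEL_NOISE_SD: dict[str, float] = {"AT": 0.8, "AS": 0.12, "HLI": 2.0, "THI": 1.2}

# Diurnal offsets added to each model-mode linear predictor, zero at the
# 11:00 reference hour and equal at 11:00 and 14:00 (the midday plateau), so
# the only systematic 11:00-vs-14:00 contrast is the soaker dip.
DIURNAL_OFFSETS: dict[str, dict[float, float]] = {
    "AT":  {6.0: -5.0, 8.0: -3.0, 10.0: -1.0, 11.0: 0.0, 14.0: 0.0,
            16.0: -0.7, 18.0: -1.5},
    "AS":  {h: 0.0 for h in MEASUREMENT_HOURS},
    "HLI": {6.0: -12.0, 8.0: -7.0, 10.0: -2.5, 11.0: 0.0, 14.0: 0.0,
            16.0: -1.5, 18.0: -3.5},
    "THI": {6.0: -6.0, 8.0: -3.5, 10.0: -1.2, 11.0: 0.0, 14.0: 0.0,
            16.0: -0.8, 18.0: -1.8},
}

# Physical-mode diurnal AT shape (°C, deviations from the daily mean; sums
# to zero so the daily mean matches the regional mean) and RH shape (%).
AT_SHAPE = {6.0: -3.5, 8.0: -1.5, 10.0: 0.5, 11.0: 1.5, 14.0: 1.5,
            16.0: 1.0, 18.0: 0.5}
RH_SHAPE = {6.0: 7.0, 8.0: 6.0, 10.0: -1.0, 11.0: -4.0, 14.0: -4.0,
            16.0: -2.0, 18.0: -2.0}
GT_OFFSET = 0.4  # black-globe minus dry-bulb, °C


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that parameterises the synthetic-farm generator.

    The ``seed`` fully determines the output.  The default seed, 20170824,
    is the date the field campaign being emulated began.
    """

    mode: str = "model"                       # "model" | "physical"
    n_farms_per_region: int = 8
    seed: int = 20170824
    regions: dict[str, RegionSpec] = field(default_factory=lambda: dict(REGIONS))
    coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in MODEL_COEFFICIENTS.items()})
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(MODEL_NOISE_SD))
    # within-region truncated-normal spreads of the quantitative housing
    # variables (the study reports regional medians and overall spreads)
    housing_sds: dict[str, float] = field(
        default_factory=lambda: dict(HOUSING_SDS))
    physical_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"AT": 0.8, "RH": 3.0, "AS": 0.12})


def _trunc_normal(rng: np.random.Generator, mean, sd, low, high, size):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def generate_farms(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a per-farm housing table emulating the study's four regions.

    Quantitative variables are truncated normals centred on the regional
    medians; qualitative variables are Bernoulli draws at the regional
    frequencies; altitude is normal around the regional mean (truncated at
    0).  Ridge height is floored at eave height.  Reproducible under
    ``config.seed``.
    """
    config = config or GeneratorConfig()
    if config.n_farms_per_region < 1:
        raise ValueError("n_farms_per_region must be >= 1")
    rng = np.random.default_rng(config.seed)
    rows = []
    for region_name, spec in config.regions.items():
        if region_name not in HOUSING_MEDIANS["FloorCow"]:
            raise ValueError(f"unknown region name: {region_name!r}")
        n = config.n_farms_per_region
        altitude = _trunc_normal(rng, spec.altitude_mean, spec.altitude_sd,
                                 0.0, np.inf, n)
        quant = {}
        for var in QUANTITATIVE_VARS:
            med = HOUSING_MEDIANS[var][region_name]
            sd = config.housing_sds[var]
            upper = 100.0 if var == "SideOpen" else np.inf
            quant[var] = _trunc_normal(rng, med, sd, 0.0, upper, n)
        quant["RidgeHei"] = np.maximum(quant["RidgeHei"], quant["EaveHei"])
        # One latent "equipment level" per farm drives all qualitative
        # draws (comonotone coupling, regional margins preserved): the same
        # farms that fit roof soakers also tend to have fans, asbestos
        # roofs, vents and tie-up stalls, which is the within-region
        # co-occurrence behind the study's collinear housing variables.
        z = rng.random(n)
        qual = {}
        for var, (cat1, cat0, probs) in HOUSING_QUAL_PROBS.items():
            qual[var] = np.where(z < probs[region_name], cat1, cat0)
        for i in range(n):
            row = {"farm_id": f"{region_name}{i + 1}",
                   "region": region_name,
                   "altitude": altitude[i],
                   "latitude_class": spec.latitude_class}
            row.update({v: quant[v][i] for v in QUANTITATIVE_VARS})
            row.update({v: qual[v][i] for v in QUALITATIVE_VARS})
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Archetype fixture: 32 farms drawn from 7 sharply separated housing
# archetypes whose membership sizes mirror the study's seven housing
# clusters (4, 10, 9, 1, 2, 1, 5).  Used for cluster-recovery checks.
# ---------------------------------------------------------------------------

ARCHETYPE_SIZES = (4, 10, 9, 1, 2, 1, 5)

# Each archetype is (quantitative values, qualitative categories): a common
# baseline cowshed plus a distinctive signature per archetype (more mats,
# more open sides, tight floor space, very large floor space, sprinkler
# cooling, tall ridge with frequent hosing, or the fan+soaker+asbestos
# tie-up package).  Signatures deviate on mostly disjoint variables so no
# single factor-analysis component swallows the cluster structure, and
# they are far apart relative to the within-archetype noise (separation at
# least ten within-archetype spreads).
_BASE_QUANT = {"MatCow": 0.6, "FloorCow": 7.0, "RidgeHei": 3.6, "EaveHei": 2.7,
               "SideOpen": 75.0, "FanCow": 0.1, "HoseCoFlo": 2.0}
_BASE_QUAL = {"Housing": "loose", "RoofType": "metal", "RoofVent": "no",
              "Sprinkler": "no", "RoofCooler": "no"}
ARCHETYPES: tuple[tuple[dict[str, float], dict[str, str]], ...] = (
    ({**_BASE_QUANT, "MatCow": 2.9, "RidgeHei": 3.0}, {**_BASE_QUAL}),
    ({**_BASE_QUANT, "SideOpen": 95.0, "MatCow": 0.0},
     {**_BASE_QUAL, "RoofVent": "yes"}),
    ({**_BASE_QUANT, "FloorCow": 4.5}, {**_BASE_QUAL, "Housing": "tie-up"}),
    ({**_BASE_QUANT, "FloorCow": 21.3}, {**_BASE_QUAL}),
    ({**_BASE_QUANT, "HoseCoFlo": 3.5},
     {**_BASE_QUAL, "Sprinkler": "yes", "RoofCooler": "yes"}),
    ({**_BASE_QUANT, "RidgeHei": 6.0, "HoseCoFlo": 5.0, "FanCow": 1.0},
     {**_BASE_QUAL}),
    ({**_BASE_QUANT, "FanCow": 0.8, "EaveHei": 3.6},
     {**_BASE_QUAL, "Housing": "tie-up", "RoofType": "asbestos",
      "RoofVent": "yes", "RoofCooler": "yes"}),
)


def generate_archetype_farms(seed: int = 20170824,
                             sizes: tuple[int, ...] = ARCHETYPE_SIZES,
                             noise_scale: float = 0.02) -> pd.DataFrame:
    """32-farm housing table drawn from the 7 archetypes, with true labels.

    Quantitative noise has standard deviation ``noise_scale`` times each
    variable's overall scale, which keeps the between-archetype separation
    well above ten within-archetype spreads; qualitative categories are
    fixed per archetype.  Returns the housing schema of
    :func:`generate_farms` plus a ``true_archetype`` column.
    """
    rng = np.random.default_rng(seed)
    scales = {v: max(np.ptp([a[0][v] for a in ARCHETYPES]), 1.0)
              for v in QUANTITATIVE_VARS}
    rows = []
    fid = 0
    for arch_idx, size in enumerate(sizes):
        quant, qual = ARCHETYPES[arch_idx]
        for _ in range(size):
            fid += 1
            row = {"farm_id": f"F{fid:02d}", "region": f"A{arch_idx + 1}",
                   "altitude": 100.0, "latitude_class": "north",
                   "true_archetype": arch_idx + 1}
            for v in QUANTITATIVE_VARS:
                row[v] = max(quant[v] + rng.normal(0.0, noise_scale * scales[v]),
                             0.0)
            row.update(qual)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Microclimate generation
# ---------------------------------------------------------------------------

def _dip_active(farms: pd.DataFrame, config: GeneratorConfig) -> pd.Series:
    active = {name for name, spec in config.regions.items()
              if spec.soaker_dip.active}
    return farms["region"].isin(active)


def generate_microclimate(farms: pd.DataFrame,
                          config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate per-farm diurnal microclimate at the seven measurement hours.

    ``model`` mode returns a long table with columns ``farm_id, region,
    clock_time, AT, AS, HLI, THI`` — each response drawn from its own linear
    predictor + diurnal offset + Gaussian noise, with the soaker dip
    subtracted in-window on dip-active farms.

    ``physical`` mode returns ``farm_id, region, clock_time, AT, RH, AS,
    GT`` raw readings suitable for :func:`shedclimate.indices.compute_indices`.
    """
    config = config or GeneratorConfig()
    if len(farms) == 0:
        raise ValueError("farms table is empty")
    rng = np.random.default_rng(config.seed + 1)
    hours = list(MEASUREMENT_HOURS)
    dip_active = _dip_active(farms, config)

    if config.mode == "model":
        rows = []
        for (_, farm), dip in zip(farms.iterrows(), dip_active):
            spec = config.regions[farm["region"]]
            dipcfg = spec.soaker_dip
            south = 1.0 if farm["latitude_class"] == "south" else 0.0
            for h in hours:
                row = {"farm_id": farm["farm_id"], "region": farm["region"],
                       "clock_time": f"{int(h):02d}:{int(round((h % 1) * 60)):02d}"}
                for resp, beta in config.coefficients.items():
                    mu = (beta["intercept"]
                          + beta["altitude"] * farm["altitude"]
                          + beta["latitude_south"] * south
                          + beta["EaveHei"] * farm["EaveHei"]
                          + beta["FloorCow"] * farm["FloorCow"]
                          + beta["SideOpen"] * farm["SideOpen"]
                          + DIURNAL_OFFSETS[resp][h])
                    if dip and h in dipcfg.window:
                        mu -= {"AT": dipcfg.dAT, "HLI": dipcfg.dHLI,
                               "THI": dipcfg.dTHI}.get(resp, 0.0)
                    sd = config.noise_sd[resp]
                    val = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    if resp == "AS":
                        val = max(val, 0.0)
                    row[resp] = val
                rows.append(row)
        return pd.DataFrame(rows)

    if config.mode == "physical":
        rows = []
        for (_, farm), dip in zip(farms.iterrows(), dip_active):
            spec = config.regions[farm["region"]]
            dipcfg = spec.soaker_dip
            nsd = config.physical_noise_sd
            farm_at = rng.normal(0.0, nsd["AT"])  # farm-level offset
            for h in hours:
                at = spec.at_mean + AT_SHAPE[h] + farm_at + rng.normal(0.0, nsd["AT"] / 2)
                if dip and h in dipcfg.window:
                    at -= dipcfg.dAT
                rh = float(np.clip(spec.rh_level + RH_SHAPE[h]
                                   + rng.normal(0.0, nsd["RH"]), 1.0, 100.0))
                as_ = max(spec.as_level + rng.normal(0.0, nsd["AS"]), 0.0)
                rows.append({"farm_id": farm["farm_id"], "region": farm["region"],
                             "clock_time": f"{int(h):02d}:{int(round((h % 1) * 60)):02d}",
                             "AT": at, "RH": rh, "AS": as_, "GT": at + GT_OFFSET})
        return pd.DataFrame(rows)

    raise ValueError(f"unknown mode: {config.mode!r} (expected 'model' or 'physical')")


def nl_dip_cohort_config(seed: int, n_farms: int = 8) -> GeneratorConfig:
    """Config for a dip-active north-lowland-like cohort of ``n_farms`` farms."""
    return GeneratorConfig(mode="model", n_farms_per_region=n_farms, seed=seed,
                           regions={"NL": REGIONS["NL"]})
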