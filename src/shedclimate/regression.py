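"""Multivariable linear modelling of cowshed microclimate on geography and
housing, with multicollinearity screening and backward elimination.

The modelling protocol: candidate predictors are altitude (m), latitude
class (south vs north reference) and the twelve housing variables
(qualitative ones as treatment-coded indicators).  Predictors are first
screened by variance inflation factor — the column with the highest VIF is
removed repeatedly until all VIFs fall below the threshold (default 5) —
then an ordinary least squares model is pruned by manual backward
elimination: the term with the largest p-value above the retention
threshold (default 0.1) is removed one step at a time, multi-level
categorical terms as a block judged by their largest level p-value.
Model assumptions are checked on standardised residuals and leverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "build_design",
    "compute_vif",
    "vif_screen",
    "fit_ols",
    "backward_eliminate",
    "diagnostics",
    "fit_microclimate_model",
    "DEFAULT_PREDICTORS",
]

#: Candidate predictors of the microclimate models, in entry order.
DEFAULT_PREDICTORS = (
    "altitude", "latitude_class", "MatCow", "FloorCow", "RidgeHei",
    "EaveHei", "SideOpen", "FanCow", "HoseCoFlo", "Housing", "RoofType",
    "RoofVent", "Sprinkler", "RoofCooler",
)

#: Fixed reference levels for treatment contrasts; any category not listed
#: uses the alphabetically first observed level as reference.
REFERENCE_LEVELS = {"latitude_class": "north"}


@dataclass(frozen=True)
class ModelSpec:
    response: str
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    vif_threshold: float = 5.0
    p_keep: float = 0.1
    #: geography terms exempt from VIF removal: altitude and latitude are
    #: the main drivers of outdoor climate and are kept in every initial
    #: model; the screen resolves collinearity among the housing variables
    #: around them.
    forced: tuple[str, ...] = ("altitude", "latitude_class")

    def __post_init__(self):
        if self.response in self.predictors:
            raise ValueError("response must not be among the predictors")


def build_design(table: pd.DataFrame,
                 predictors=DEFAULT_PREDICTORS) -> tuple[pd.DataFrame, dict]:
    """Numeric design matrix with treatment contrasts.

    Qualitative predictors are expanded to indicator columns named
    ``var[level]`` dropping the recorded reference level (north for
    latitude, otherwise the alphabetically first observed level).  Returns
    the design and a ``blocks`` map from term name to its columns (used for
    block-wise elimination of multi-level factors).
    """
    cols, blocks = {}, {}
    for var in predictors:
        if var not in table.columns:
            raise ValueError(f"missing predictor column: {var!r}")
        s = table[var]
        if pd.api.types.is_numeric_dtype(s):
            cols[var] = s.to_numpy(dtype=float)
            blocks[var] = [var]
        else:
            levels = sorted(s.astype(str).unique())
            ref = REFERENCE_LEVELS.get(var, levels[0])
            if ref not in levels:
                ref = levels[0]
            block = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{var}[{lev}]"
                cols[name] = (s.astype(str) == lev).to_numpy(dtype=float)
                block.append(name)
            blocks[var] = block
    return pd.DataFrame(cols, index=table.index), blocks


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per column: 1/(1−R²) of that column
    regressed on all others (with intercept).  Perfect collinearity gives
    +inf."""
    if design.shape[1] < 2:
        raise ValueError("need at least two predictor columns")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more rows than columns")
    X = design.to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(len(y)), np.delete(X, j, axis=1)])
        beta, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = ((y - y.mean())**2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-10 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_screen(design: pd.DataFrame, threshold: float = 5.0,
               forced: tuple[str, ...] = ()
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively drop the single highest-VIF column until all < threshold.

    Ties are broken by column order (the earlier column is removed).
    ``forced`` columns are exempt from removal (they still count when
    computing the VIF of the others); the screen stops when every
    non-forced column has VIF below the threshold.  Returns the retained
    design and an exclusion report with the VIF of every removed column at
    the step it was removed.
    """
    kept = design.copy()
    removed = []
    step = 0
    while kept.shape[1] >= 2:
        vifs = compute_vif(kept)
        candidates = vifs.drop(index=[c for c in forced if c in vifs.index])
        if candidates.empty or candidates.max() < threshold:
            break
        step += 1
        name = candidates.index[int(np.argmax(candidates.to_numpy()))]
        removed.append({"step": step, "column": name,
                        "vif_at_removal": candidates.max()})
        kept = kept.drop(columns=name)
    report = pd.DataFrame(removed, columns=["step", "column", "vif_at_removal"])
    return kept, report


@dataclass
class RegressionFit:
    """An OLS fit with its screening, elimination and diagnostic context."""

    response: str
    coefficients: pd.DataFrame          # term, estimate, se, t, p
    r_squared_pct: float
    nobs: int
    vif_report: pd.DataFrame = field(default_factory=pd.DataFrame)
    elimination_log: pd.DataFrame = field(default_factory=pd.DataFrame)
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)
    _results: object = None             # statsmodels results, for reuse


def fit_ols(y, design: pd.DataFrame, response: str = "y") -> RegressionFit:
    """Classical OLS with intercept; raises on a rank-deficient design."""
    X = sm.add_constant(design, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        raise ValueError("rank-deficient design (screen collinear columns first)")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    coef = pd.DataFrame({
        "term": X.columns,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "t": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    return RegressionFit(response=response, coefficients=coef,
                         r_squared_pct=100 * res.rsquared, nobs=int(res.nobs),
                         _results=res)


def backward_eliminate(y, design: pd.DataFrame,
                       blocks: dict[str, list[str]] | None = None,
                       p_keep: float = 0.1,
                       response: str = "y") -> RegressionFit:
    """Manual backward elimination at retention threshold ``p_keep``.

    Repeatedly refits, removing the term with the largest p-value above
    ``p_keep``; a multi-level categorical term is removed as a block, judged
    by the largest p among its levels.  The intercept is exempt.  An empty
    (intercept-only) final model is allowed.
    """
    if blocks is None:
        blocks = {c: [c] for c in design.columns}
    blocks = {t: [c for c in cs if c in design.columns]
              for t, cs in blocks.items()}
    blocks = {t: cs for t, cs in blocks.items() if cs}
    log = []
    current = design.copy()
    step = 0
    while True:
        fit = fit_ols(y, current, response=response)
        pvals = fit.coefficients.set_index("term")["p"]
        term_p = {t: max(pvals[c] for c in cs) for t, cs in blocks.items()}
        if not term_p:
            break
        worst_term = max(term_p, key=lambda t: term_p[t])
        if term_p[worst_term] <= p_keep:
            break
        step += 1
        log.append({"step": step, "term": worst_term,
                    "p_at_removal": term_p[worst_term]})
        current = current.drop(columns=blocks[worst_term])
        del blocks[worst_term]
    fit.elimination_log = pd.DataFrame(log, columns=["step", "term", "p_at_removal"])
    return fit


def diagnostics(fit: RegressionFit,
                resid_flag: float = 3.0,
                leverage_factor: float = 2.0) -> pd.DataFrame:
    """Internally standardised residuals and hat-matrix leverage per row.

    Flags |r| > ``resid_flag`` and h > ``leverage_factor``·p/n with p the
    number of fitted parameters (intercept included).
    """
    res = fit._results
    infl = res.get_influence()
    h = infl.hat_matrix_diag
    # a numerically perfect fit has no residual scale to standardise by
    y_scale = float(np.std(res.model.endog)) or 1.0
    if np.max(np.abs(res.resid)) <= 1e-10 * max(y_scale, 1.0):
        r = np.zeros_like(res.resid)
    else:
        r = infl.resid_studentized_internal
    n, p = int(res.nobs), int(res.df_model + 1)
    out = pd.DataFrame({"std_residual": r, "leverage": h})
    out["residual_flag"] = np.abs(r) > resid_flag
    out["leverage_flag"] = h > leverage_factor * p / n
    return out


def fit_microclimate_model(table: pd.DataFrame, response: str,
                           spec: ModelSpec | None = None) -> RegressionFit:
    """Full protocol for one response: design → VIF screen → OLS →
    backward elimination → diagnostics.

    ``table`` is a merged per-farm frame with the response column plus the
    candidate predictor columns.  The fitted model is reported even when no
    term survives elimination (intercept-only).
    """
    spec = spec or ModelSpec(response=response)
    predictors = [p for p in spec.predictors if p in table.columns]
    design, blocks = build_design(table, predictors)
    forced_cols = tuple(c for term in spec.forced
                        for c in blocks.get(term, ()))
    kept, vif_report = vif_screen(design, spec.vif_threshold, forced=forced_cols)
    fit = backward_eliminate(table[response].to_numpy(dtype=float), kept,
                             blocks=blocks, p_keep=spec.p_keep,
                             response=response)
    fit.vif_report = vif_report
    fit.diagnostics = diagnostics(fit)
    return fit
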