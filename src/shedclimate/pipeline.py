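"""End-to-end pipeline: simulate → indices → compare → cluster → regress → report.

Every intermediate is persisted as a documented UTF-8 CSV so each stage can
be re-run and tested independently; each run also writes the resolved
configuration (YAML) and a log recording package version, seed and config
hash beside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import comparisons, famd, indices, regression, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "summarize_daily",
           "overall_mean_of_medians", "load_config"]

logger = logging.getLogger("shedclimate")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run (YAML round-trippable)."""

    seed: int = 20170824
    n_farms_per_region: int = 8
    generator_mode: str = "physical"       # raw readings for the index stage
    hli_low_rh_coeff: float = 0.28
    hli_lower_threshold: float = 77.0
    hli_upper_threshold: float = 86.0
    variance_threshold: float = 0.70
    cluster_k: int | None = None           # None: use the suggested cut
    vif_threshold: float = 5.0
    p_keep: float = 0.1
    responses: tuple[str, ...] = ("AT", "AS", "HLI", "THI", "RH")
    out_dir: str = "shedclimate_run"

    def to_yaml(self, path: Path):
        d = dataclasses.asdict(self)
        d["responses"] = list(d["responses"])
        path.write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @property
    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["responses"] = list(d["responses"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if "responses" in data:
        data["responses"] = tuple(data["responses"])
    return PipelineConfig(**data)


def overall_mean_of_medians(values, groups) -> tuple[float, float]:
    """Mean and SEM of the per-group medians (the 'overall' summary used for
    non-normal housing variables)."""
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    meds = np.array([np.median(x[g == lev]) for lev in pd.unique(g)])
    sem = meds.std(ddof=1) / np.sqrt(meds.size) if meds.size > 1 else 0.0
    return float(meds.mean()), float(sem)


def summarize_daily(index_table: pd.DataFrame,
                    variables=("AT", "RH", "AS", "THI", "HLI", "AHLU"),
                    region_col: str = "region") -> dict[str, pd.DataFrame]:
    """Regional daily summaries of microclimate/index series.

    Returns three tables:

    ``regional`` — per-region mean and SEM of each variable over all time
    points (daily 06:00–18:00 averages per farm first, then across farms);
    ``by_time`` — per-region mean at each clock time;
    ``overall`` — across-region mean ± SEM of the regional daily means,
    plus the mean of regional medians.
    """
    present = [v for v in variables if v in index_table.columns]
    farm_daily = (index_table.groupby(["farm_id", region_col])[present]
                  .mean().reset_index())
    regional = (farm_daily.groupby(region_col)[present]
                .agg(["mean", "sem"]))
    by_time = (index_table.groupby([region_col, "clock_time"])[present]
               .mean().reset_index())
    rows = []
    for v in present:
        region_means = farm_daily.groupby(region_col)[v].mean()
        mom, mom_sem = overall_mean_of_medians(farm_daily[v],
                                               farm_daily[region_col])
        rows.append({"variable": v,
                     "mean_of_region_means": region_means.mean(),
                     "sem_of_region_means": region_means.sem(),
                     "mean_of_region_medians": mom,
                     "sem_of_region_medians": mom_sem})
    return {"regional": regional, "by_time": by_time,
            "overall": pd.DataFrame(rows)}


def _compare_housing(farms: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Region comparison battery over the twelve housing variables."""
    rows = []
    for var in synthetic.QUANTITATIVE_VARS:
        x, g = farms[var].to_numpy(dtype=float), farms["region"].to_numpy()
        if np.ptp(x) == 0:
            rows.append({"variable": var, "test": "constant", "statistic": 0.0,
                         "p": 1.0, "letters": ""})
            continue
        family, _ = comparisons.normality_gate(x, g)
        res = (comparisons.anova_tukey(x, g, variable=var) if family == "normal"
               else comparisons.kruskal_dunn(x, g, variable=var))
        rows.append({"variable": var, "test": res.test,
                     "statistic": res.statistic, "p": res.p_value,
                     "letters": ";".join(f"{k}:{v}" for k, v in res.letters.items())})
    for var in synthetic.QUALITATIVE_VARS:
        tab = pd.crosstab(farms["region"], farms[var])
        if tab.shape[1] < 2:
            rows.append({"variable": var, "test": "constant", "statistic": 0.0,
                         "p": 1.0, "letters": ""})
            continue
        res = comparisons.fisher_battery(tab, variable=var, seed=seed)
        rows.append({"variable": var, "test": res.test,
                     "statistic": res.statistic, "p": res.p_value,
                     "letters": ";".join(f"{k}:{v}" for k, v in res.letters.items())})
    return pd.DataFrame(rows)


class SchemaError(ValueError):
    """An input table is missing required columns."""


def run_pipeline(config: PipelineConfig) -> int:
    """Run the full pipeline; returns 0 on success, 2 on partial failure.

    Stage outputs are written even when later stages fail; the run log and
    resolved config are always written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("shedclimate %s seed=%s config=%s", __version__,
                config.seed, config.config_hash)
    config.to_yaml(out / "config.resolved.yaml")
    failures = []

    try:
        farms = synthetic.generate_farms(synthetic.GeneratorConfig(
            mode="physical", n_farms_per_region=config.n_farms_per_region,
            seed=config.seed))
        farms.to_csv(out / "farms.csv", index=False)
        readings = synthetic.generate_microclimate(
            farms, synthetic.GeneratorConfig(mode="physical",
                                             n_farms_per_region=config.n_farms_per_region,
                                             seed=config.seed))
        readings.to_csv(out / "readings.csv", index=False)
        responses = synthetic.generate_microclimate(
            farms, synthetic.GeneratorConfig(mode="model",
                                             n_farms_per_region=config.n_farms_per_region,
                                             seed=config.seed))
        responses.to_csv(out / "responses.csv", index=False)
    except Exception:
        logger.exception("simulate stage failed")
        logger.removeHandler(handler)
        return 2

    try:
        idx = indices.compute_indices(readings,
                                      hli_low_rh_coeff=config.hli_low_rh_coeff,
                                      lower=config.hli_lower_threshold,
                                      upper=config.hli_upper_threshold)
        idx.to_csv(out / "indices.csv", index=False)
        summ = summarize_daily(idx)
        summ["regional"].to_csv(out / "summary_regional.csv")
        summ["by_time"].to_csv(out / "summary_by_time.csv", index=False)
        summ["overall"].to_csv(out / "summary_overall.csv", index=False)
    except Exception:
        logger.exception("indices stage failed")
        failures.append("indices")

    try:
        _compare_housing(farms, config.seed).to_csv(
            out / "comparisons_region.csv", index=False)
    except Exception:
        logger.exception("compare stage failed")
        failures.append("compare")

    model = None
    try:
        model = famd.fit_housing_clusters(farms,
                                          variance_threshold=config.variance_threshold,
                                          k=config.cluster_k,
                                          drop_constant_qualitative=True)
        model.assignments.to_csv(out / "clusters.csv", index=False)
        model.vtests.to_csv(out / "vtests.csv", index=False)
    except Exception:
        logger.exception("cluster stage failed")
        failures.append("cluster")

    try:
        daily = (responses.groupby(["farm_id", "region"])[["AT", "AS", "HLI", "THI"]]
                 .mean().reset_index())
        merged = farms.merge(daily.drop(columns="region"), on="farm_id")
        # RH response only exists in physical-mode readings
        rh_daily = readings.groupby("farm_id")["RH"].mean().reset_index()
        merged = merged.merge(rh_daily, on="farm_id")
        coef_rows = []
        for resp in config.responses:
            fit = regression.fit_microclimate_model(
                merged, resp, regression.ModelSpec(
                    response=resp, vif_threshold=config.vif_threshold,
                    p_keep=config.p_keep))
            for _, r in fit.coefficients.iterrows():
                coef_rows.append({"response": resp, **r.to_dict(),
                                  "r_squared_pct": fit.r_squared_pct})
            fit.vif_report.assign(response=resp).to_csv(
                out / f"vif_{resp}.csv", index=False)
        pd.DataFrame(coef_rows).to_csv(out / "regression_coefficients.csv",
                                       index=False)
    except Exception:
        logger.exception("regress stage failed")
        failures.append("regress")

    if model is not None:
        try:
            daily_idx = merged
            rows = []
            cl = model.assignments.merge(daily_idx, on="farm_id")
            for resp in ("AT", "RH", "AS", "HLI", "THI"):
                if resp not in cl.columns:
                    continue
                try:
                    res = comparisons.cluster_twoway_anova(cl, resp)
                    rows.append({"response": resp, "F": res.statistic,
                                 "p": res.p_value})
                except ValueError as e:
                    rows.append({"response": resp, "F": np.nan, "p": np.nan,
                                 "note": str(e)})
            pd.DataFrame(rows).to_csv(out / "cluster_anova.csv", index=False)
        except Exception:
            logger.exception("cluster-anova stage failed")
            failures.append("cluster-anova")

    logger.info("done; failed stages: %s", failures or "none")
    logger.removeHandler(handler)
    handler.close()
    return 2 if failures else 0
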