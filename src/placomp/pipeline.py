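"""End-to-end study orchestration.

Runs the full analysis: deconvolve bulk methylation against the
reference panel, impute rounded zeros, IQR-standardize the three
trimester exposures on the full analytic sample (so "one IQR" means the
same thing in every stratum), then fit the compositional regression with
bootstrap inference and the per-cell-type beta regressions — overall and
stratified by infant sex — and optionally repeat everything excluding
participants with severe pregnancy complications (preeclampsia or
eclampsia). All tables are written as CSV next to a machine-readable
JSON run log (seed, per-stratum n, exclusion counts).
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import betareg as _betareg
from . import compreg as _compreg
from .containers import CellComposition, ReferencePanel, BulkMethylation
from .deconvolution import estimate_composition, replace_zeros
from .design import ModelSpec
from .preprocess import iqr_standardize

__all__ = [
    "AnalysisConfig",
    "ResultsBundle",
    "iqr_standardize",
    "summarize_cohort",
    "run_analysis",
]

MODELLED_COLUMNS = [
    "sex",
    "maternal_age",
    "race_ethnicity",
    "gestational_age",
    "season_of_birth",
    "pm25_t1",
    "pm25_t2",
    "pm25_t3",
]

CONTINUOUS_SUMMARY = [
    "gestational_age",
    "maternal_age",
    "pm25_t1",
    "pm25_t2",
    "pm25_t3",
]
CATEGORICAL_SUMMARY = ["race_ethnicity", "season_of_birth", "preeclampsia", "eclampsia"]


@dataclass
class AnalysisConfig:
    """Configuration of one analysis run (mirrors the YAML config file)."""

    bulk_path: str | None = None
    panel_path: str | None = None
    cohort_path: str | None = None
    out_dir: str = "results"
    strata: tuple[str, ...] = ("overall", "female", "male")
    sensitivity_exclude_complications: bool = True
    B: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    delta: float = 1e-3
    min_overlap: int = 100
    simulate: dict | None = None  # parameters for a synthetic run instead of file input

    def __post_init__(self) -> None:
        if self.B < 100:
            raise ValueError("B must be at least 100")
        if not (0.5 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0.5, 1)")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)


@dataclass
class ResultsBundle:
    composition: CellComposition
    descriptives: pd.DataFrame
    compositional: pd.DataFrame   # trimester x stratum effect table with CIs and overall p
    beta_regression: pd.DataFrame  # trimester x stratum x cell-type log-odds table
    log: dict = field(default_factory=dict)
    sensitivity_compositional: pd.DataFrame | None = None
    sensitivity_beta_regression: pd.DataFrame | None = None

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.composition.to_csv(out / "composition.csv")
        self.descriptives.to_csv(out / "descriptives.csv", index=False)
        self.compositional.to_csv(out / "compositional_results.csv", index=False)
        self.beta_regression.to_csv(out / "betareg_results.csv", index=False)
        if self.sensitivity_compositional is not None:
            self.sensitivity_compositional.to_csv(
                out / "compositional_results_sensitivity.csv", index=False
            )
        if self.sensitivity_beta_regression is not None:
            self.sensitivity_beta_regression.to_csv(
                out / "betareg_results_sensitivity.csv", index=False
            )
        (out / "run_log.json").write_text(json.dumps(self.log, indent=2, default=str))


def summarize_cohort(cohort: pd.DataFrame, comp: CellComposition | None = None) -> pd.DataFrame:
    """Descriptive table: mean (SD) or N (%) overall and by infant sex,
    with two-sided t-test p-values for continuous variables and
    chi-square p-values for categorical ones."""
    df = cohort.reset_index(drop=True)
    if comp is not None:
        cf = comp.to_frame()
        cf.index.name = None
        df = df.merge(cf, left_on="sample_id", right_index=True, how="left")
    female = df[df["sex"] == "female"]
    male = df[df["sex"] == "male"]
    rows = []
    cont = [c for c in CONTINUOUS_SUMMARY if c in df.columns]
    if comp is not None:
        cont += list(comp.cell_types)
    for col in cont:
        row = {"variable": col, "kind": "continuous"}
        for name, sub in (("all", df), ("female", female), ("male", male)):
            row[f"{name}_mean"] = sub[col].mean()
            row[f"{name}_sd"] = sub[col].std(ddof=1)
        if len(female) >= 2 and len(male) >= 2:
            row["p"] = float(stats.ttest_ind(female[col], male[col]).pvalue)
        else:
            row["p"] = np.nan
        rows.append(row)
    for col in (c for c in CATEGORICAL_SUMMARY if c in df.columns):
        table = pd.crosstab(df[col], df["sex"])
        try:
            p = float(stats.chi2_contingency(table).pvalue) if table.shape[0] > 1 else np.nan
        except ValueError:
            p = np.nan
        for level in table.index:
            row = {"variable": f"{col}={level}", "kind": "categorical", "p": p}
            for name, sub in (("all", df), ("female", female), ("male", male)):
                count = int((sub[col] == level).sum())
                row[f"{name}_n"] = count
                row[f"{name}_pct"] = 100.0 * count / len(sub) if len(sub) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def _stratum_frame(cohort: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "overall":
        return cohort
    return cohort[cohort["sex"] == stratum]


def _fit_stratum_models(
    comp: CellComposition,
    cohort: pd.DataFrame,
    strata,
    B: int,
    ci_level: float,
    seed: int,
    log: dict,
    label: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    comp_frame = comp.to_frame()
    comp_rows = []
    beta_rows = []
    base_spec = ModelSpec()
    for s_i, stratum in enumerate(strata):
        sub = _stratum_frame(cohort, stratum)
        if len(sub) == 0:
            log.setdefault("warnings", []).append(f"{label}: stratum {stratum} empty, skipped")
            continue
        spec = base_spec if stratum == "overall" else base_spec.without_sex()
        sub_comp = CellComposition(
            sample_ids=list(sub["sample_id"]),
            cell_types=comp.cell_types,
            values=comp_frame.loc[sub["sample_id"]].to_numpy(dtype=float),
        )
        # stratified subsamples (~100 records) with 4-level dummies hit
        # rank-deficient resamples often enough that the library's 10%
        # redraw cap would abort whole runs; relax it here and log counts
        fit = _compreg.bootstrap_inference(
            sub_comp, sub, spec, B=B, ci_level=ci_level, seed=seed + s_i,
            max_redraw_frac=0.5,
        )
        tab = fit.results_frame()
        tab.insert(0, "stratum", stratum)
        comp_rows.append(tab)
        log.setdefault("strata_n", {})[f"{label}:{stratum}"] = int(len(sub))
        log.setdefault("bootstrap_redrawn", {})[f"{label}:{stratum}"] = fit.n_redrawn

        for ct in comp.cell_types:
            bfit = _betareg.fit_beta_regression(
                sub_comp.to_frame()[ct].to_numpy(), sub, spec, cell_type=ct
            )
            wt = _betareg.wald_summary(bfit, ci_level)
            for tri in spec.exposures:
                beta_rows.append(
                    {
                        "stratum": stratum,
                        "trimester": tri,
                        "cell_type": ct,
                        "estimate": wt.loc[tri, "estimate"],
                        "ci_lo": wt.loc[tri, "ci_lo"],
                        "ci_hi": wt.loc[tri, "ci_hi"],
                        "p": wt.loc[tri, "p"],
                    }
                )
    comp_table = pd.concat(comp_rows, ignore_index=True) if comp_rows else pd.DataFrame()
    return comp_table, pd.DataFrame(beta_rows)


def run_analysis(config: AnalysisConfig) -> ResultsBundle:
    """Execute the configured study end to end and write all outputs."""
    log: dict = {"seed": config.seed, "config": {
        k: v for k, v in asdict(config).items() if not isinstance(v, dict)
    }}
    log["config_hash"] = hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    if config.simulate is not None:
        from . import synthetic_data as sd

        sim = dict(config.simulate)
        n = int(sim.pop("n", 226))
        panel = sd.generate_reference_panel(seed=config.seed)
        cohort, truth = sd.generate_cohort(n=n, seed=config.seed, **sim)
        bulk = sd.mix_bulk(panel, truth, sample_ids=list(cohort["sample_id"]))
        log["input"] = {"mode": "simulated", "n": n}
    else:
        if not (config.bulk_path and config.panel_path and config.cohort_path):
            raise ValueError("provide bulk/panel/cohort paths or a simulate block")
        panel = ReferencePanel.from_csv(config.panel_path)
        bulk = BulkMethylation.from_csv(config.bulk_path)
        cohort = pd.read_csv(config.cohort_path)
        cohort["sample_id"] = cohort["sample_id"].astype(str)
        cohort = cohort.set_index("sample_id", drop=False)
        log["input"] = {"mode": "files", "n": int(len(cohort))}

    n_input = len(cohort)
    missing_bulk = [s for s in cohort["sample_id"] if s not in set(bulk.sample_ids)]
    extra_bulk = [s for s in bulk.sample_ids if s not in set(cohort["sample_id"])]
    if missing_bulk or extra_bulk:
        raise ValueError(
            f"sample-ID mismatch between cohort and bulk: missing={missing_bulk[:5]}, "
            f"unmatched={extra_bulk[:5]}"
        )

    # complete-case rule on modelled covariates and exposures
    complete = cohort.dropna(subset=[c for c in MODELLED_COLUMNS if c in cohort.columns])
    n_dropped_missing = n_input - len(complete)
    log["n_dropped_missing_covariates"] = int(n_dropped_missing)
    cohort = complete

    comp_raw = estimate_composition(bulk, panel, min_overlap=config.min_overlap)
    comp = replace_zeros(comp_raw, delta=config.delta)
    comp_frame = comp.to_frame().loc[cohort["sample_id"]]
    comp = CellComposition(
        sample_ids=list(cohort["sample_id"]),
        cell_types=comp.cell_types,
        values=comp_frame.to_numpy(dtype=float),
    )

    # IQR standardization on the full analytic sample, before stratification
    cohort = cohort.copy()
    log["iqr"] = {}
    for tri in ("pm25_t1", "pm25_t2", "pm25_t3"):
        cohort[tri], iqr = iqr_standardize(cohort[tri].to_numpy())
        log["iqr"][tri] = iqr

    descriptives = summarize_cohort(cohort, comp)
    comp_table, beta_table = _fit_stratum_models(
        comp, cohort, config.strata, config.B, config.ci_level, config.seed, log, "main"
    )

    sens_comp = sens_beta = None
    if config.sensitivity_exclude_complications:
        flags = cohort.get("preeclampsia", 0).astype(bool) | cohort.get("eclampsia", 0).astype(bool)
        n_excluded = int(flags.sum())
        log["n_excluded_complications"] = n_excluded
        if n_excluded == 0:
            sens_comp, sens_beta = comp_table.copy(), beta_table.copy()
        else:
            keep = cohort[~flags]
            keep_comp = CellComposition(
                sample_ids=list(keep["sample_id"]),
                cell_types=comp.cell_types,
                values=comp.to_frame().loc[keep["sample_id"]].to_numpy(dtype=float),
            )
            sens_comp, sens_beta = _fit_stratum_models(
                keep_comp, keep, config.strata, config.B, config.ci_level,
                config.seed, log, "sensitivity",
            )

    bundle = ResultsBundle(
        composition=comp,
        descriptives=descriptives,
        compositional=comp_table,
        beta_regression=beta_table,
        log=log,
        sensitivity_compositional=sens_comp,
        sensitivity_beta_regression=sens_beta,
    )
    bundle.write(config.out_dir)
    return bundle
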