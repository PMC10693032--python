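"""Design-matrix construction for the exposure models.

One shared builder feeds both the compositional and the beta regressions
so that "the model" means the same design everywhere: an intercept, the
three IQR-standardized trimester PM2.5 averages, and the adjustment
covariates (infant sex in unstratified runs, maternal age, race/ethnicity,
gestational age, season of birth). Categorical covariates are dummy-coded
against a configurable reference level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXPOSURES: tuple[str, ...] = ("pm25_t1", "pm25_t2", "pm25_t3")

DEFAULT_CATEGORICAL_REFERENCES = {"race_ethnicity": "White", "season_of_birth": "Winter"}

DEFAULT_CATEGORICAL_LEVELS = {
    "race_ethnicity": ("White", "Black", "Hispanic", "Other"),
    "season_of_birth": ("Winter", "Spring", "Summer", "Fall"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors enter the regression design.

    ``include_sex`` is switched off automatically for sex-stratified fits.
    Continuous covariates enter as-is; categorical covariates are expanded
    into dummies relative to their reference level.
    """

    exposures: tuple[str, ...] = EXPOSURES
    continuous: tuple[str, ...] = ("maternal_age", "gestational_age")
    categorical: tuple[str, ...] = ("race_ethnicity", "season_of_birth")
    include_sex: bool = True
    references: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORICAL_REFERENCES))

    def without_sex(self) -> "ModelSpec":
        return ModelSpec(self.exposures, self.continuous, self.categorical, False, dict(self.references))


def build_design(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Build the N x P design matrix (with intercept) from a cohort table.

    Raises ``ValueError`` naming collinear columns if the design is
    rank-deficient, which is how degenerate bootstrap resamples and
    misconfigured covariate lists surface.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    if spec.include_sex:
        cols["sex_male"] = (cohort["sex"].astype(str) == "male").to_numpy(dtype=float)
    for name in spec.exposures:
        cols[name] = cohort[name].to_numpy(dtype=float)
    for name in spec.continuous:
        cols[name] = cohort[name].to_numpy(dtype=float)
    for name in spec.categorical:
        ref = spec.references.get(name)
        levels = [lv for lv in sorted(cohort[name].astype(str).unique()) if lv != ref]
        for lv in levels:
            cols[f"{name}_{lv}"] = (cohort[name].astype(str) == lv).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=cohort.index)
    _check_rank(X)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name the columns that add no rank, scanning left to right
        bad = []
        kept: list[int] = []
        for j in range(A.shape[1]):
            trial = kept + [j]
            if np.linalg.matrix_rank(A[:, trial]) == len(kept):
                bad.append(X.columns[j])
            else:
                kept.append(j)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def reference_profile(X: pd.DataFrame, spec: ModelSpec) -> np.ndarray:
    """Reference covariate profile at which composition effects are evaluated.

    Continuous covariates sit at their sample mean, categorical dummies at
    the modal observed level, exposures at 0 (their median after IQR
    standardization). Returns a 1 x P vector aligned with ``X.columns``.
    """
    x = np.zeros(X.shape[1])
    for j, col in enumerate(X.columns):
        if col == "intercept":
            x[j] = 1.0
        elif col in spec.exposures:
            x[j] = 0.0
        elif col in spec.continuous:
            x[j] = X[col].mean()
    # modal level per categorical group (0 everywhere if the reference is modal)
    groups = list(spec.categorical) + (["sex"] if spec.include_sex else [])
    for name in groups:
        dummies = [c for c in X.columns if c.startswith(f"{name}_")]
        if not dummies:
            continue
        counts = {d: X[d].sum() for d in dummies}
        n_ref = len(X) - sum(counts.values())
        modal = max(counts, key=lambda d: counts[d])
        if counts[modal] > n_ref:
            x[X.columns.get_loc(modal)] = 1.0
    return x
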