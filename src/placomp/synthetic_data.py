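"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a birth-cohort placental
methylation study: a marker-based reference panel, per-sample cell-type
compositions with sex-specific baselines and effects injected in ilr
space, trimester-average PM2.5 exposures with realistic means, spreads
and cross-trimester correlation, demographic covariates with frequencies
matching a Northeastern US urban pregnancy cohort, and noisy bulk
methylation mixtures for the deconvolution stage.

Defaults reproduce the cohort's descriptive statistics: mean
syncytiotrophoblast proportion 0.636, trimester PM2.5 means near
8.3 ug/m^3 with SD 1.3-1.8, 44.7% female infants, and so on. Effects are
injected additively on the ilr scale against IQR-standardized exposures,
so the compositional regression has an exactly recoverable truth on its
own parameter scale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    PLACENTA_CELL_TYPES,
    BulkMethylation,
    CellComposition,
    GroundTruth,
    ReferencePanel,
    closure,
)
from .compreg import ilr_basis, ilr_inverse, ilr_transform
from .preprocess import iqr_standardize

__all__ = [
    "generate_reference_panel",
    "generate_cohort",
    "mix_bulk",
    "write_simulation",
    "DEFAULT_BASELINES",
    "DEFAULT_EXPOSURE_MEANS",
    "DEFAULT_EXPOSURE_SDS",
]

# Sex-specific baseline compositions (cohort means, renormalized to unit sum).
DEFAULT_BASELINES: dict[str, np.ndarray] = {
    "female": closure(np.array([0.623, 0.099, 0.129, 0.102, 0.010, 0.036])),
    "male": closure(np.array([0.644, 0.084, 0.125, 0.096, 0.014, 0.036])),
}

DEFAULT_EXPOSURE_MEANS = np.array([8.25, 8.24, 8.56])  # ug/m^3, trimesters 1-3
DEFAULT_EXPOSURE_SDS = np.array([1.36, 1.34, 1.77])
#: Within-pregnancy correlation between trimester averages. Not reported by
#: the cohort; 0.4 is a plausible stand-in for temporally adjacent exposures.
DEFAULT_EXPOSURE_CORR = 0.4

DEFAULT_FEMALE_FRAC = 101.0 / 226.0

RACE_LEVELS = ("White", "Black", "Hispanic", "Other")
RACE_PROBS = closure(np.array([0.3186, 0.4027, 0.2035, 0.0619]))
SEASON_LEVELS = ("Spring", "Summer", "Fall", "Winter")
SEASON_PROBS = closure(np.array([0.2611, 0.2389, 0.2301, 0.2699]))

MATERNAL_AGE_MEAN, MATERNAL_AGE_SD = 30.57, 5.59
GESTATIONAL_AGE_MEAN, GESTATIONAL_AGE_SD = 38.96, 1.50
PREECLAMPSIA_PROB = 15.0 / 226.0
ECLAMPSIA_PROB = 2.0 / 226.0

#: Default ilr-coordinate noise SD; chosen so the marginal cell-type
#: proportion SDs match the cohort's (syncytiotrophoblast ~0.065-0.07).
DEFAULT_COMPOSITION_NOISE_SD = 0.25


def generate_reference_panel(
    K: int = 6,
    markers_per_type: int = 100,
    contrast: float = 0.6,
    seed: int | None = None,
    jitter_sd: float = 0.02,
    cell_types: tuple[str, ...] | None = None,
) -> ReferencePanel:
    """Marker-block reference panel: each cell type owns a block of
    ``markers_per_type`` CpGs that are hypermethylated (0.5 + contrast/2)
    in that type and hypomethylated (0.5 - contrast/2) elsewhere, plus
    small seeded Gaussian jitter, clipped to [0, 1]."""
    if K < 2 or markers_per_type < 1:
        raise ValueError("K must be >= 2 and markers_per_type >= 1")
    if not (0 < contrast <= 1):
        raise ValueError("contrast must lie in (0, 1]")
    if cell_types is None:
        cell_types = (
            PLACENTA_CELL_TYPES if K == len(PLACENTA_CELL_TYPES)
            else tuple(f"cell_{i + 1}" for i in range(K))
        )
    L = K * markers_per_type
    hi, lo = 0.5 + contrast / 2.0, 0.5 - contrast / 2.0
    values = np.full((L, K), lo)
    for k in range(K):
        values[k * markers_per_type:(k + 1) * markers_per_type, k] = hi
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, jitter_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)
    cpg_ids = [f"cg{i:08d}" for i in range(L)]
    return ReferencePanel(cpg_ids=cpg_ids, cell_types=tuple(cell_types), values=values)


def generate_cohort(
    n: int = 226,
    female_frac: float = DEFAULT_FEMALE_FRAC,
    baseline_composition: dict[str, np.ndarray] | None = None,
    effect_spec: dict[str, np.ndarray] | None = None,
    exposure_means: np.ndarray = DEFAULT_EXPOSURE_MEANS,
    exposure_sds: np.ndarray = DEFAULT_EXPOSURE_SDS,
    exposure_corr: float = DEFAULT_EXPOSURE_CORR,
    composition_noise_sd: float = DEFAULT_COMPOSITION_NOISE_SD,
    noise_sd: float = 0.02,
    seed: int | None = None,
    cell_types: tuple[str, ...] = PLACENTA_CELL_TYPES,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort table and its ground-truth compositions.

    The true composition of sample i is
    ``ilr_inv( ilr(baseline_sex(i)) + Gamma' x_i + eps_i )`` where ``x_i``
    holds the predictors named in ``effect_spec`` (trimester exposures are
    taken IQR-standardized within the generated cohort, so injected
    effects live on the same scale the regression estimates) and ``eps_i``
    is iid Gaussian per ilr coordinate with SD ``composition_noise_sd``.

    ``effect_spec`` maps a predictor name — ``pm25_t1``/``t2``/``t3`` or a
    cohort column such as ``maternal_age`` — to a (K-1) ilr-scale vector.
    A key of the form ``"pm25_t1:male"`` restricts the effect to one sex
    (the predictor is multiplied by the sex indicator), which is how
    sex-specific exposure effects are simulated.
    Returns the cohort table (one row per mother-infant pair) and a
    :class:`GroundTruth` carrying the true mixing weights.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if baseline_composition is None:
        baseline_composition = DEFAULT_BASELINES
    K = len(cell_types)
    for sex, base in baseline_composition.items():
        base = np.asarray(base, dtype=float)
        if base.min() <= 0 or abs(base.sum() - 1.0) > 1e-8 or len(base) != K:
            raise ValueError(f"baseline composition for {sex!r} is not a strict K-simplex point")
    effect_spec = {k: np.asarray(v, dtype=float) for k, v in (effect_spec or {}).items()}
    for name, vec in effect_spec.items():
        if vec.shape != (K - 1,):
            raise ValueError(f"effect vector for {name!r} must have length K-1={K - 1}")

    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < female_frac, "female", "male")

    # correlated trimester exposures, truncated at zero by resampling
    sds = np.asarray(exposure_sds, dtype=float)
    corr = np.full((3, 3), exposure_corr)
    np.fill_diagonal(corr, 1.0)
    cov = corr * np.outer(sds, sds)
    pm = rng.multivariate_normal(np.asarray(exposure_means, dtype=float), cov, size=n)
    while np.any(pm <= 0):
        bad = np.any(pm <= 0, axis=1)
        pm[bad] = rng.multivariate_normal(
            np.asarray(exposure_means, dtype=float), cov, size=int(bad.sum())
        )

    maternal_age = np.clip(rng.normal(MATERNAL_AGE_MEAN, MATERNAL_AGE_SD, n), 18.0, None)
    gestational_age = np.clip(rng.normal(GESTATIONAL_AGE_MEAN, GESTATIONAL_AGE_SD, n), 25.0, 43.0)
    race = rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS)
    season = rng.choice(SEASON_LEVELS, size=n, p=SEASON_PROBS)
    preeclampsia = rng.random(n) < PREECLAMPSIA_PROB
    eclampsia = rng.random(n) < ECLAMPSIA_PROB

    cohort = pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "sex": sex,
            "maternal_age": maternal_age,
            "race_ethnicity": race,
            "gestational_age": gestational_age,
            "season_of_birth": season,
            "preeclampsia": preeclampsia.astype(int),
            "eclampsia": eclampsia.astype(int),
            "pm25_t1": pm[:, 0],
            "pm25_t2": pm[:, 1],
            "pm25_t3": pm[:, 2],
        }
    ).set_index("sample_id", drop=False)

    basis = ilr_basis(cell_types)
    eta = np.vstack(
        [ilr_transform(baseline_composition[s].reshape(1, -1), basis)[0] for s in sex]
    )
    for name, gamma in effect_spec.items():
        pred, _, sex_only = name.partition(":")
        if pred in ("pm25_t1", "pm25_t2", "pm25_t3"):
            x, _ = iqr_standardize(cohort[pred].to_numpy()) if n >= 4 else (cohort[pred].to_numpy(), 1.0)
        elif pred == "sex_male":
            x = (sex == "male").astype(float)
        else:
            x = cohort[pred].to_numpy(dtype=float)
        if sex_only:
            x = x * (sex == sex_only)
        eta = eta + np.outer(x, gamma)
    if composition_noise_sd > 0:
        eta = eta + rng.normal(0.0, composition_noise_sd, size=eta.shape)
    compositions = ilr_inverse(eta, basis)

    truth = GroundTruth(
        compositions=compositions,
        cell_types=tuple(cell_types),
        effects=effect_spec,
        seed=seed,
        noise_sd=noise_sd,
        baselines={s: np.asarray(b, dtype=float) for s, b in baseline_composition.items()},
    )
    return cohort, truth


def mix_bulk(
    panel: ReferencePanel,
    truth: GroundTruth,
    seed: int | None = None,
    sample_ids: list[str] | None = None,
) -> BulkMethylation:
    """Forward model: bulk beta values ``B = W R' + noise``, clipped to [0, 1].

    Noise is iid Gaussian with SD ``truth.noise_sd``; the seed defaults to
    ``truth.seed`` so that cohort and bulk are jointly reproducible.
    """
    W = truth.compositions
    if W.shape[1] != panel.n_cell_types:
        raise ValueError(
            f"truth has {W.shape[1]} cell types but panel has {panel.n_cell_types}"
        )
    B = W @ panel.values.T
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed if seed is None else seed)
        B = B + rng.normal(0.0, truth.noise_sd, size=B.shape)
    B = np.clip(B, 0.0, 1.0)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(W.shape[0])]
    return BulkMethylation(sample_ids=sample_ids, cpg_ids=list(panel.cpg_ids), values=B)


def write_simulation(
    out_dir,
    n: int = 226,
    seed: int | None = None,
    **kwargs,
) -> dict:
    """Generate panel + cohort + truth + bulk and write them as CSVs with a
    JSON sidecar recording the seed and all generator parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = generate_reference_panel(seed=seed)
    cohort, truth = generate_cohort(n=n, seed=seed, **kwargs)
    bulk = mix_bulk(panel, truth, sample_ids=list(cohort["sample_id"]))
    panel.to_csv(out / "panel.csv")
    cohort.to_csv(out / "cohort.csv", index=False)
    bulk.to_csv(out / "bulk.csv")
    CellComposition(
        sample_ids=list(cohort["sample_id"]),
        cell_types=truth.cell_types,
        values=truth.compositions,
    ).to_csv(out / "true_composition.csv")
    meta = {
        "n": n,
        "seed": seed,
        "noise_sd": truth.noise_sd,
        "cell_types": list(truth.cell_types),
        "effects": {k: list(map(float, v)) for k, v in truth.effects.items()},
        "parameters": {
            k: (list(map(float, v)) if isinstance(v, np.ndarray) else v)
            for k, v in kwargs.items()
            if not isinstance(v, dict)
        },
    }
    (out / "simulation.json").write_text(json.dumps(meta, indent=2))
    return meta
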