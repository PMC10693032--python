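"""Domain containers shared across the pipeline.

All matrices are dense numpy arrays with explicit row/column identifier
lists, convertible to/from tidy ``pandas`` frames for CSV round trips.
The cohort table itself is a plain :class:`pandas.DataFrame` with the
column contract documented in :mod:`placomp.synthetic_data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The six placental cell types resolved by the methylation reference,
#: in conventional abundance order.
PLACENTA_CELL_TYPES: tuple[str, ...] = (
    "syncytiotrophoblast",
    "trophoblasts",
    "stromal",
    "endothelial",
    "hofbauer",
    "nrbc",
)


class DegenerateSampleError(ValueError):
    """A sample produced an unusable (all-zero) composition."""


@dataclass
class ReferencePanel:
    """CpG x cell-type matrix of reference methylation beta values.

    Each column is the methylation signature of one cell type; rows are
    marker CpGs. Entries are beta values in [0, 1] and the columns must
    be linearly independent for deconvolution to be identifiable.
    """

    cpg_ids: list[str]
    cell_types: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        L, K = self.values.shape
        if K < 2:
            raise ValueError("reference panel needs at least two cell types")
        if L < K:
            raise ValueError("reference panel needs at least K CpGs")
        if len(self.cpg_ids) != L or len(self.cell_types) != K:
            raise ValueError("identifier lengths do not match matrix shape")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("beta values must lie in [0, 1]")
        if np.linalg.matrix_rank(self.values) < K:
            raise ValueError("reference panel columns are collinear")

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cpg_ids, columns=list(self.cell_types))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferencePanel":
        return cls(
            cpg_ids=[str(i) for i in df.index],
            cell_types=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="cpg_id")

    @classmethod
    def from_csv(cls, path) -> "ReferencePanel":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass
class BulkMethylation:
    """Sample x CpG matrix of bulk-tissue beta values (deconvolution input)."""

    sample_ids: list[str]
    cpg_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        N, L = self.values.shape
        if len(self.sample_ids) != N or len(self.cpg_ids) != L:
            raise ValueError("identifier lengths do not match matrix shape")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("beta values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.cpg_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BulkMethylation":
        return cls(
            sample_ids=[str(i) for i in df.index],
            cpg_ids=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "BulkMethylation":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass
class CellComposition:
    """Sample x cell-type matrix of simplex-valued proportions.

    Rows sum to one. After zero replacement every entry is strictly
    positive, which is what log-ratio transforms require.
    """

    sample_ids: list[str]
    cell_types: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        N, K = self.values.shape
        if len(self.sample_ids) != N or len(self.cell_types) != K:
            raise ValueError("identifier lengths do not match matrix shape")
        if self.values.min() < -1e-12:
            raise ValueError("proportions must be nonnegative")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("composition rows must sum to 1")

    @property
    def n_cell_types(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=list(self.cell_types))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellComposition":
        return cls(
            sample_ids=[str(i) for i in df.index],
            cell_types=tuple(str(c) for c in df.columns),
            values=df.to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path) -> "CellComposition":
        return cls.from_frame(pd.read_csv(path, index_col=0))


@dataclass
class GroundTruth:
    """Simulation truth: mixing weights, injected effects and noise level."""

    compositions: np.ndarray  # N x K, rows on the simplex, strictly positive
    cell_types: tuple[str, ...]
    effects: Mapping[str, np.ndarray] = field(default_factory=dict)  # predictor -> (K-1) ilr vector
    seed: int | None = None
    noise_sd: float = 0.0
    baselines: Mapping[str, np.ndarray] = field(default_factory=dict)  # sex -> K simplex

    def __post_init__(self) -> None:
        self.compositions = np.asarray(self.compositions, dtype=float)
        if self.compositions.min() <= 0:
            raise ValueError("true compositions must be strictly positive")
        if not np.allclose(self.compositions.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("true composition rows must sum to 1")
        for name, vec in self.effects.items():
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"effect vector for {name!r} is not finite")

    @property
    def effect_matrix(self) -> np.ndarray:
        """Stacked P x (K-1) matrix of injected ilr-scale effects."""
        if not self.effects:
            return np.zeros((0, len(self.cell_types) - 1))
        return np.vstack([np.asarray(v, dtype=float) for v in self.effects.values()])


def closure(x: np.ndarray) -> np.ndarray:
    """Renormalize rows of a nonnegative matrix to unit sum."""
    x = np.asarray(x, dtype=float)
    return x / x.sum(axis=-1, keepdims=True)
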