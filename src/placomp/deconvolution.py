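"""Reference-based cell-type deconvolution of bulk methylation profiles.

Each bulk sample's beta-value vector is projected onto the reference
panel under simplex constraints: minimize ``||b - R w||^2`` subject to
``w >= 0`` and ``sum(w) <= 1`` (constrained projection), after which the
weights are renormalized to sum exactly to one. Because K is small the
quadratic program is solved exactly by enumerating active sets, so the
solution carries no iterative-solver tolerance.

Estimated proportions can contain exact zeros (rounded zeros: the cell
type is below the method's detection limit, not absent). Before
log-ratio analysis these are imputed by multiplicative simple
replacement, which assigns each zero a small detection-limit-like value
delta and rescales the remaining parts, preserving their ratios and the
unit sum exactly.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

from .containers import (
    BulkMethylation,
    CellComposition,
    DegenerateSampleError,
    ReferencePanel,
)

__all__ = ["estimate_composition", "replace_zeros", "solve_projection"]

logger = logging.getLogger(__name__)

_FEAS_TOL = 1e-10
_MAX_ENUM_K = 14  # 2^(K+1) active sets; exact enumeration is cheap up to here


def solve_projection(R: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact solution of min ||b - R w||^2 s.t. w >= 0, sum(w) <= 1.

    Enumerates all active sets (each weight clamped at zero or free, the
    sum constraint tight or slack), solves the corresponding
    equality-constrained least-squares problem, and returns the feasible
    candidate with the smallest objective. The global optimum of this
    convex QP is the equality-constrained solution of its own active set,
    so it is always among the candidates.
    """
    R = np.asarray(R, dtype=float)
    b = np.asarray(b, dtype=float)
    K = R.shape[1]
    if K > _MAX_ENUM_K:
        raise NotImplementedError(
            f"active-set enumeration supports up to {_MAX_ENUM_K} cell types"
        )
    best_w = np.zeros(K)
    best_obj = float(np.dot(b, b))  # objective of the all-zero candidate
    for free in itertools.chain.from_iterable(
        itertools.combinations(range(K), r) for r in range(1, K + 1)
    ):
        free = list(free)
        Rf = R[:, free]
        for sum_active in (False, True):
            if sum_active:
                # substitute w_f = w0 + N t with 1'w_f = 1 via the constraint nullspace
                nf = len(free)
                w0 = np.full(nf, 1.0 / nf)
                if nf == 1:
                    wf = w0
                else:
                    Nmat = _simplex_nullspace(nf)
                    t, *_ = np.linalg.lstsq(Rf @ Nmat, b - Rf @ w0, rcond=None)
                    wf = w0 + Nmat @ t
            else:
                wf, *_ = np.linalg.lstsq(Rf, b, rcond=None)
            if wf.min() < -_FEAS_TOL or wf.sum() > 1.0 + _FEAS_TOL:
                continue
            w = np.zeros(K)
            w[free] = np.clip(wf, 0.0, None)
            r = b - R @ w
            obj = float(np.dot(r, r))
            if obj < best_obj - 1e-14:
                best_obj = obj
                best_w = w
    return best_w


def _simplex_nullspace(n: int) -> np.ndarray:
    """Orthonormal basis of the hyperplane {x : 1'x = 0} in R^n."""
    A = np.ones((1, n))
    _, _, Vt = np.linalg.svd(A)
    return Vt[1:].T


def estimate_composition(
    bulk: BulkMethylation,
    panel: ReferencePanel,
    min_overlap: int | None = None,
) -> CellComposition:
    """Estimate per-sample cell-type proportions by constrained projection.

    CpGs are matched between bulk and panel by identifier (order
    insensitive); the count of panel CpGs absent from the bulk matrix is
    logged. ``min_overlap`` sets the minimum number of shared CpGs
    (default: the number of cell types K; the pipeline raises this to 100
    for real-data runs).
    """
    K = panel.n_cell_types
    shared = [c for c in panel.cpg_ids if c in set(bulk.cpg_ids)]
    threshold = max(K, min_overlap or 0)
    if len(shared) < threshold:
        raise ValueError(
            f"only {len(shared)} CpGs shared between bulk and panel "
            f"(minimum {threshold})"
        )
    dropped = len(panel.cpg_ids) - len(shared)
    if dropped:
        logger.info("dropped %d panel CpGs absent from the bulk matrix", dropped)
    panel_pos = {c: i for i, c in enumerate(panel.cpg_ids)}
    bulk_pos = {c: i for i, c in enumerate(bulk.cpg_ids)}
    R = panel.values[[panel_pos[c] for c in shared]]
    B = bulk.values[:, [bulk_pos[c] for c in shared]]

    W = np.empty((B.shape[0], K))
    for i in range(B.shape[0]):
        w = solve_projection(R, B[i])
        s = w.sum()
        if s <= 0:
            raise DegenerateSampleError(
                f"sample {bulk.sample_ids[i]!r} projects to the all-zero composition"
            )
        W[i] = w / s
    return CellComposition(
        sample_ids=list(bulk.sample_ids),
        cell_types=panel.cell_types,
        values=W,
    )


def replace_zeros(comp: CellComposition, delta: float = 1e-3) -> CellComposition:
    """Impute rounded zeros by multiplicative simple replacement.

    Zero entries become ``delta``; each nonzero entry ``x`` in a row with
    ``z`` zeros is rescaled to ``x * (1 - z * delta)``, so rows keep unit
    sum and the ratios among originally nonzero parts are untouched. Rows
    without zeros are returned unchanged.
    """
    K = comp.n_cell_types
    if not (0 < delta < 1.0 / K):
        raise ValueError(f"delta must lie in (0, 1/K); got {delta} with K={K}")
    W = comp.values.copy()
    zero = W == 0.0
    nz_count = zero.sum(axis=1)
    if np.any(nz_count == K):
        i = int(np.argmax(nz_count == K))
        raise DegenerateSampleError(
            f"sample {comp.sample_ids[i]!r} has an all-zero composition"
        )
    rows = np.nonzero(nz_count > 0)[0]
    for i in rows:
        z = nz_count[i]
        W[i, ~zero[i]] *= 1.0 - z * delta
        W[i, zero[i]] = delta
    return CellComposition(
        sample_ids=list(comp.sample_ids),
        cell_types=comp.cell_types,
        values=W,
    )
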