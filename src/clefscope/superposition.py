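"""Rigid-body superposition and invariant-core analysis.

A structure family aligned by sequence can be compared geometrically by
least-squares (Kabsch) superposition of equivalent Cα positions.  The
*invariant core* of such a family is the set of alignment columns whose
positional scatter across the superposed members stays small: for each
ungapped column the 3×3 positional covariance defines an ellipsoid with
semi-axes √λ₁, √λ₂, √λ₃ (the principal-axis standard deviations) and volume

    V = (4/3) π √(λ₁ λ₂ λ₃) = (4/3) π √det(Σ)   [Å³]

Columns are eliminated one at a time — largest volume first, re-superposing
on the survivors — until every remaining column's volume falls below a
cutoff (default 1.0 Å³) or a minimum core size is reached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, PreconditionError
from .structures_io import AlignmentMap, Structure

__all__ = [
    "Superposition",
    "CoreResult",
    "kabsch_superpose",
    "superpose_ensemble",
    "column_ellipsoid_volume",
    "column_volumes",
    "find_invariant_core",
]


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid transform: x ↦ rotation @ x + translation."""

    rotation: np.ndarray  # 3×3, det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # minimised Cα RMSD, Å

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass
class CoreResult:
    """Outcome of the iterative invariant-core elimination.

    ``volumes`` holds the per-ungapped-column ellipsoid volumes at the final
    iteration (indexed by alignment column), ``core_columns`` the surviving
    columns, and ``removal_order`` the eliminated columns in elimination
    order.
    """

    volumes: dict[int, float]
    core_columns: list[int]
    removal_order: list[int]
    cutoff: float


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Optimal rigid transform taking ``mobile`` onto ``reference``.

    Both are n×3 point sets in correspondence, n ≥ 3 and non-collinear.
    The reflection case is excluded (proper rotation only).
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise PreconditionError("point sets must share an n×3 shape")
    n = mob.shape[0]
    if n < 3:
        raise GeometryError("superposition requires at least 3 points")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    # Collinear/coincident configurations leave the rotation underdetermined.
    if min(np.linalg.matrix_rank(np.round(mob_c, 12)),
           np.linalg.matrix_rank(np.round(ref_c, 12))) < 2:
        raise GeometryError("rank-deficient (collinear or coincident) point set")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    rmsd = float(rssd) / np.sqrt(n)
    R = rot.as_matrix()
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    return Superposition(R, t, rmsd)


def superpose_ensemble(structures: Sequence[Structure], amap: AlignmentMap,
                       fit_columns: Sequence[int] | None = None,
                       reference: int = 0) -> np.ndarray:
    """Superpose every structure onto a reference over selected columns.

    Returns an S×C×3 coordinate block over the alignment's ungapped columns
    (C = number of ungapped columns), with each member rigid-fitted to the
    reference structure using only ``fit_columns`` (default: all ungapped
    columns).
    """
    cols = list(amap.ungapped_columns)
    if not cols:
        raise PreconditionError("alignment has no ungapped columns")
    if fit_columns is None:
        fit = cols
    else:
        fit = sorted(fit_columns)
        if not fit:
            raise PreconditionError("fit_columns must be non-empty")
        if not set(fit) <= set(cols):
            raise PreconditionError("fit_columns must be ungapped columns")
    if len(fit) < 3:
        raise PreconditionError("need at least 3 fit columns")
    ref_s = structures[reference]
    ref_fit = amap.coords_at(ref_s, fit)
    out = np.empty((len(structures), len(cols), 3), dtype=float)
    for i, s in enumerate(structures):
        sup = kabsch_superpose(amap.coords_at(s, fit), ref_fit)
        out[i] = sup.apply(amap.coords_at(s, cols))
    return out


def column_ellipsoid_volume(points: np.ndarray) -> float:
    """Volume of the covariance ellipsoid of a set of 3-D points.

    Semi-axes are the square roots of the eigenvalues of the population
    (1/n) covariance; any zero eigenvalue (coincident, collinear or coplanar
    points) gives volume 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise PreconditionError("need at least 2 points of dimension 3")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / pts.shape[0]
    det = np.linalg.det(cov)
    return float(4.0 / 3.0 * np.pi * np.sqrt(max(det, 0.0)))


def column_volumes(block: np.ndarray) -> np.ndarray:
    """Per-column covariance-ellipsoid volumes of an S×C×3 aligned block."""
    centred = block - block.mean(axis=0, keepdims=True)
    # Batched 3×3 population covariances, one per column.
    cov = np.einsum("sci,scj->cij", centred, centred) / block.shape[0]
    det = np.clip(np.linalg.det(cov), 0.0, None)
    return 4.0 / 3.0 * np.pi * np.sqrt(det)


def find_invariant_core(structures: Sequence[Structure], amap: AlignmentMap,
                        cutoff: float = 1.0, min_core: int = 3,
                        resuperpose: bool = True,
                        criterion: str = "per_column") -> CoreResult:
    """Iteratively strip the most variable alignment columns from a family.

    At each step the family is superposed on the current candidate core
    (optionally only once, on all columns, when ``resuperpose`` is False),
    per-column ellipsoid volumes are computed, and the single largest-volume
    column is removed (ties broken toward the lowest column index).
    Iteration stops when the stopping criterion is met or ``min_core``
    columns remain.

    criterion:
        ``per_column`` — stop when every surviving column's volume < cutoff;
        ``total`` — stop when the summed volume of survivors < cutoff.
    """
    if min_core < 3:
        raise PreconditionError("min_core must be at least 3")
    if len(structures) < 3:
        raise PreconditionError("invariant-core analysis requires ≥ 3 structures")
    if criterion not in ("per_column", "total"):
        raise PreconditionError(f"unknown criterion {criterion!r}")
    cols = list(amap.ungapped_columns)
    if len(cols) < min_core:
        raise PreconditionError("fewer ungapped columns than min_core")
    col_index = {c: k for k, c in enumerate(cols)}

    candidate = list(cols)
    removal_order: list[int] = []
    block = superpose_ensemble(structures, amap, fit_columns=cols)
    while True:
        if resuperpose:
            block = superpose_ensemble(structures, amap, fit_columns=candidate)
        vols_all = column_volumes(block)
        vols = {c: float(vols_all[col_index[c]]) for c in candidate}
        if criterion == "per_column":
            done = max(vols.values()) < cutoff
        else:
            done = sum(vols.values()) < cutoff
        if done or len(candidate) <= min_core:
            # report every ungapped column's volume at the final superposition
            final = {c: float(vols_all[col_index[c]]) for c in cols}
            return CoreResult(final, sorted(candidate), removal_order, cutoff)
        # argmax with lowest-index tie-break: candidate list is kept sorted
        worst = max(candidate, key=lambda c: (vols[c], -c))
        candidate.remove(worst)
        removal_order.append(worst)
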