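"""Coordinate PCA of aligned structure families and quadrant clustering.

Each superposed family member is flattened to a 3C-vector over the ungapped
alignment columns (C columns → 3C coordinates); PCA diagonalises the
covariance of these vectors.  Families of structural homologues typically
concentrate variance in a handful of components, and the sign pattern of two
selected component scores — the plane's four quadrants — provides a crude
but reproducible clustering of the family.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .errors import PreconditionError

__all__ = ["PCAResult", "coordinate_pca", "quadrant_cluster", "QUADRANTS"]

QUADRANTS = ("(+,+)", "(+,-)", "(-,+)", "(-,-)")


@dataclass
class PCAResult:
    """Principal components of a flattened coordinate ensemble.

    components: K×3C orthonormal rows, descending eigenvalue order;
    eigenvalues: length K, ≥ 0; variance_fractions sum to 1 over all
    variance; projections: S×K member scores (mean structure scores 0).
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    projections: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def coordinate_pca(block: np.ndarray) -> PCAResult:
    """PCA of an S×C×3 superposed coordinate block.

    The number of retained components is min(S−1, 3C).  Component signs are
    fixed by making each component's largest-magnitude loading positive, so
    results are deterministic (up to that convention, which leaves quadrant
    labels arbitrary under reflection).
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 3 or block.shape[2] != 3:
        raise PreconditionError("expected an S×C×3 coordinate block")
    S = block.shape[0]
    if S < 3:
        raise PreconditionError("coordinate PCA requires at least 3 structures")
    X = block.reshape(S, -1)
    X = X - X.mean(axis=0, keepdims=True)
    k = min(S - 1, X.shape[1])
    # SVD of the centred data matrix: eigenvalues of the (1/S) covariance
    U, sv, Vt = np.linalg.svd(X, full_matrices=False)
    evals = (sv**2) / S
    total = evals.sum()
    comp = Vt[:k]
    evals = evals[:k]
    # deterministic sign: largest-|loading| entry positive
    for i in range(k):
        j = int(np.argmax(np.abs(comp[i])))
        if comp[i, j] < 0:
            comp[i] = -comp[i]
    proj = X @ comp.T
    fractions = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(comp, evals, fractions, proj)


def quadrant_cluster(p: PCAResult, axis_x: int = 1, axis_y: int = 3) -> list[str]:
    """Label members by the sign quadrant of two component scores.

    ``axis_x``/``axis_y`` are 1-based component indices (the customary
    choice pairs the dominant component with a later one that separates the
    family further).  Scores exactly 0 count as positive.
    """
    for ax in (axis_x, axis_y):
        if not 1 <= ax <= p.n_components:
            raise PreconditionError(f"component {ax} not available "
                                    f"({p.n_components} computed)")
    x = p.projections[:, axis_x - 1]
    y = p.projections[:, axis_y - 1]
    return [f"({'+' if xi >= 0 else '-'},{'+' if yi >= 0 else '-'})"
            for xi, yi in zip(x, y)]
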