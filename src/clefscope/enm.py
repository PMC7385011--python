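"""Elastic-network normal-mode analysis, fluctuation profiles and DCCMs.

The model is the anisotropic network model (ANM): every Cα pair within a
distance cutoff is joined by a Hookean spring of stiffness γ, giving the
potential  U = Σ_contacts (γ/2)(|r_ij| − |r⁰_ij|)².  Its 3N×3N Hessian has
off-diagonal superblocks

    H_ij = −γ (d dᵀ) / |d|²,     d = x_j − x_i,  |d| ≤ cutoff,

with diagonal superblocks H_ii = −Σ_{j≠i} H_ij.  For a connected,
non-collinear structure exactly six eigenvalues vanish (rigid translations
and rotations); the remaining eigenpairs are the non-trivial modes, indexed
1-based in ascending eigenvalue order so the first non-trivial mode is
mode 7.  Frequencies are reported as ω = √λ in the model's arbitrary units —
absolute frequencies depend on γ and are not physical.

Mode-derived fluctuations follow the standard pseudo-inverse forms:

    rmsf_i  = √( Σ_k λ_k⁻¹ |v_{k,i}|² )
    C_ij    = Σ_k λ_k⁻¹ v_{k,i}·v_{k,j} / √(⟨Δr_i²⟩⟨Δr_j²⟩)

with k running over a selected non-trivial mode window (default 7–18, the
low-frequency end that carries domain-scale motion).  Ensemble-derived
counterparts use deviations from the frame mean of a pre-superposed
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import (
    DisconnectedStructureError,
    PreconditionError,
    UndefinedCorrelationError,
)
from .structures_io import Structure

__all__ = [
    "ModeSet",
    "FluctuationProfile",
    "CorrelationMap",
    "build_hessian",
    "normal_modes",
    "mode_rmsf",
    "ensemble_rmsf",
    "dccm_from_modes",
    "dccm_from_ensemble",
]

#: eigenvalues below ZERO_MODE_RTOL × λ_max count as rigid-body (zero) modes
ZERO_MODE_RTOL = 1e-8

DEFAULT_CUTOFF = 15.0
DEFAULT_GAMMA = 1.0
DEFAULT_MODE_RANGE = (7, 18)


@dataclass
class ModeSet:
    """Eigenpairs of an elastic-network Hessian, ascending by eigenvalue."""

    eigenvalues: np.ndarray  # shape (3N,), ascending, ≥ 0 up to round-off
    eigenvectors: np.ndarray  # shape (3N, 3N); column k is mode k+1
    n_atoms: int
    cutoff: float
    gamma: float

    @property
    def frequencies(self) -> np.ndarray:
        """ω_k = √λ_k in arbitrary units, non-decreasing."""
        return np.sqrt(np.clip(self.eigenvalues, 0.0, None))

    @property
    def n_zero_modes(self) -> int:
        tol = ZERO_MODE_RTOL * float(self.eigenvalues[-1])
        return int(np.sum(self.eigenvalues < tol))

    def mode(self, k: int) -> np.ndarray:
        """Eigenvector of 1-based mode k, reshaped to N×3."""
        if not 1 <= k <= self.eigenvectors.shape[1]:
            raise PreconditionError(f"mode index {k} out of range")
        return self.eigenvectors[:, k - 1].reshape(self.n_atoms, 3)

    def nontrivial(self, k: int) -> np.ndarray:
        """k-th non-trivial mode (1-based): mode 6 + k."""
        return self.mode(6 + k)


@dataclass
class FluctuationProfile:
    """Per-residue RMSF with the spread summaries Δrmsf = max−min and σ.

    Mode-derived profiles are in relative (model) units; ensemble-derived
    profiles are in Å.
    """

    rmsf: np.ndarray
    source: str  # "modes" | "ensemble"

    @property
    def delta(self) -> float:
        return float(self.rmsf.max() - self.rmsf.min())

    @property
    def sigma(self) -> float:
        return float(self.rmsf.std())


@dataclass
class CorrelationMap:
    """N×N normalised cross-correlation of residue displacement vectors."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise PreconditionError("correlation matrix must be square")
        if np.abs(m - m.T).max() > 1e-10:
            raise PreconditionError("correlation matrix must be symmetric")
        if np.abs(np.diag(m) - 1.0).max() > 1e-10:
            raise PreconditionError("correlation diagonal must be 1")
        if m.min() < -1 - 1e-10 or m.max() > 1 + 1e-10:
            raise PreconditionError("correlations must lie in [-1, 1]")


def build_hessian(s: Structure | np.ndarray, cutoff: float = DEFAULT_CUTOFF,
                  gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Dense 3N×3N ANM Hessian of a Cα structure (or bare N×3 coordinates)."""
    xyz = s.coords if isinstance(s, Structure) else np.asarray(s, dtype=float)
    n = xyz.shape[0]
    if n < 2:
        raise PreconditionError("Hessian needs at least 2 residues")
    if cutoff <= 0 or gamma <= 0:
        raise PreconditionError("cutoff and gamma must be positive")
    diff = xyz[None, :, :] - xyz[:, None, :]  # d[i,j] = x_j − x_i
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    contact = (dist2 <= cutoff**2) & ~np.eye(n, dtype=bool)
    H = np.zeros((n, n, 3, 3))
    ii, jj = np.nonzero(contact)
    d = diff[ii, jj]
    H[ii, jj] = -gamma * np.einsum("ka,kb->kab", d, d) / dist2[ii, jj, None, None]
    H[np.arange(n), np.arange(n)] = -H.sum(axis=1)
    return H.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def normal_modes(H: np.ndarray, cutoff: float = DEFAULT_CUTOFF,
                 gamma: float = DEFAULT_GAMMA) -> ModeSet:
    """Full eigen-decomposition of a symmetric ENM Hessian.

    Raises :class:`DisconnectedStructureError` when more than six eigenvalues
    are numerically zero, the signature of an elastic network that has fallen
    apart into independent pieces.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1] or H.shape[0] % 3:
        raise PreconditionError("Hessian must be 3N×3N")
    if np.abs(H - H.T).max() > 1e-8 * max(1.0, np.abs(H).max()):
        raise PreconditionError("Hessian must be symmetric")
    evals, evecs = scipy.linalg.eigh(H)
    modes = ModeSet(evals, evecs, H.shape[0] // 3, cutoff, gamma)
    if modes.n_zero_modes > 6:
        raise DisconnectedStructureError(
            f"{modes.n_zero_modes} zero modes found (> 6): the elastic network is "
            "disconnected; raise the cutoff or check the structure")
    return modes


def compute_modes(s: Structure | np.ndarray, cutoff: float = DEFAULT_CUTOFF,
                  gamma: float = DEFAULT_GAMMA) -> ModeSet:
    """Convenience: Hessian construction followed by diagonalisation."""
    return normal_modes(build_hessian(s, cutoff, gamma), cutoff=cutoff, gamma=gamma)


def _check_mode_range(m: ModeSet, mode_range: tuple[int, int]) -> range:
    lo, hi = mode_range
    if lo <= 6:
        raise PreconditionError("mode range must exclude the six rigid-body modes")
    if hi < lo or hi > 3 * m.n_atoms:
        raise PreconditionError(f"invalid mode range {mode_range}")
    tol = ZERO_MODE_RTOL * float(m.eigenvalues[-1])
    if np.any(m.eigenvalues[lo - 1:hi] < tol):
        raise PreconditionError("selected mode range contains a zero mode")
    return range(lo, hi + 1)


def _mode_covariance_3d(m: ModeSet, mode_range: tuple[int, int]) -> np.ndarray:
    """⟨Δr_i·Δr_j⟩ (N×N) from the pseudo-inverse over the selected modes."""
    ks = _check_mode_range(m, mode_range)
    idx = [k - 1 for k in ks]
    V = m.eigenvectors[:, idx].reshape(m.n_atoms, 3, len(idx))
    w = 1.0 / m.eigenvalues[idx]
    return np.einsum("iak,jak,k->ij", V, V, w)


def mode_rmsf(m: ModeSet,
              mode_range: tuple[int, int] = DEFAULT_MODE_RANGE) -> FluctuationProfile:
    """Per-residue RMSF from a window of non-trivial modes (relative units)."""
    cov = _mode_covariance_3d(m, mode_range)
    return FluctuationProfile(np.sqrt(np.diag(cov)), source="modes")


def ensemble_rmsf(frames: np.ndarray) -> FluctuationProfile:
    """Per-residue RMSF (Å) about the frame mean of a superposed F×N×3 ensemble."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise PreconditionError("ensemble RMSF needs an F×N×3 array with F ≥ 2")
    dev = frames - frames.mean(axis=0, keepdims=True)
    return FluctuationProfile(np.sqrt(np.einsum("fia,fia->i", dev, dev)
                                      / frames.shape[0]),
                              source="ensemble")


def _normalise_covariance(cov3d: np.ndarray, labels: list[str]) -> CorrelationMap:
    var = np.diag(cov3d)
    zero = np.nonzero(var <= 0)[0]
    if zero.size:
        raise UndefinedCorrelationError(
            f"residue {labels[zero[0]]} has zero displacement variance; "
            "its correlation is undefined")
    denom = np.sqrt(np.outer(var, var))
    C = cov3d / denom
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMap(C, labels)


def _labels(n: int, labels: list[str] | None) -> list[str]:
    return labels if labels is not None else [str(i + 1) for i in range(n)]


def dccm_from_modes(m: ModeSet, mode_range: tuple[int, int] = DEFAULT_MODE_RANGE,
                    labels: list[str] | None = None) -> CorrelationMap:
    """Dynamic cross-correlation map from an ENM mode window."""
    cov = _mode_covariance_3d(m, mode_range)
    return _normalise_covariance(cov, _labels(m.n_atoms, labels))


def dccm_from_ensemble(frames: np.ndarray,
                       labels: list[str] | None = None) -> CorrelationMap:
    """Dynamic cross-correlation map from a superposed coordinate ensemble."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise PreconditionError("ensemble DCCM needs an F×N×3 array with F ≥ 2")
    dev = frames - frames.mean(axis=0, keepdims=True)
    cov = np.einsum("fia,fja->ij", dev, dev) / frames.shape[0]
    return _normalise_covariance(cov, _labels(frames.shape[1], labels))


def sample_mode_ensemble(m: ModeSet, n_frames: int,
                         mode_range: tuple[int, int] = DEFAULT_MODE_RANGE,
                         rng: np.random.Generator | None = None,
                         base: np.ndarray | None = None) -> np.ndarray:
    """Draw Gaussian frames with per-mode variance 1/λ (the ENM equilibrium
    distribution restricted to a mode window); used to cross-validate the
    analytic DCCM against a sampled one."""
    rng = np.random.default_rng() if rng is None else rng
    ks = _check_mode_range(m, mode_range)
    idx = [k - 1 for k in ks]
    V = m.eigenvectors[:, idx]  # 3N × K
    amp = rng.standard_normal((n_frames, len(idx))) / np.sqrt(m.eigenvalues[idx])
    disp = amp @ V.T
    frames = disp.reshape(n_frames, m.n_atoms, 3)
    if base is not None:
        frames = frames + np.asarray(base, dtype=float)[None]
    return frames
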