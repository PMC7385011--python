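"""Interaction-surface detection and buried-area quantification.

Multi-domain endoglucanases couple their GH9 catalytic domain, linker and
CBM49 through contact patches whose residues move together.  Two signals are
combined here:

* **Correlated segments** — rectangular blocks of high positive correlation
  in a DCCM between sequence-separated residue runs mark residue pairs with
  concerted displacements.  Runs are trimmed to single domain labels and the
  resulting segment pairs classified by the domains they join (GC, GL, CL,
  or GLC when one connected patch touches all three).
* **Buried surface area** — the solvent-accessible surface area (SASA) lost
  on forming the interface,  BSA = SASA(A) + SASA(B) − SASA(A∪B),  computed
  with Shrake–Rupley quadrature on a residue-sphere model (one sphere per
  Cα, default radius 3.0 Å approximating side-chain extent, probe 1.4 Å).
  The sphere model keeps the method applicable to Cα-only homology models;
  its absolute scale is coarser than an all-atom SASA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm import CorrelationMap
from .errors import AnnotationError, GeometryError, PreconditionError
from .structures_io import DomainAnnotation, Structure

__all__ = [
    "Segment",
    "InteractionSurface",
    "correlated_segments",
    "classify_surfaces",
    "sphere_points",
    "shrake_rupley_sasa",
    "buried_interface_area",
]

DEFAULT_RESIDUE_RADIUS = 3.0  # Å, effective side-chain sphere on each Cα
DEFAULT_PROBE = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960

_CLASS_BY_DOMAINS = {
    frozenset({"GH9", "CBM49"}): "GC",
    frozenset({"GH9", "L"}): "GL",
    frozenset({"CBM49", "L"}): "CL",
    frozenset({"GH9", "L", "CBM49"}): "GLC",
}


@dataclass(frozen=True)
class Segment:
    """A contiguous residue run inside one domain."""

    chain: str
    start_res: int
    end_res: int  # inclusive
    domain: str
    sublabel: str = ""

    def __post_init__(self):
        if self.start_res > self.end_res:
            raise PreconditionError("segment start must not exceed end")

    @property
    def res_ids(self) -> range:
        return range(self.start_res, self.end_res + 1)


@dataclass
class InteractionSurface:
    """A connected set of correlated segment pairs joining two or three domains."""

    pairs: list[tuple[Segment, Segment]]
    surface_class: str  # GC | GL | CL | GLC
    mean_correlation: float
    buried_area: float = 0.0  # Å², filled by buried_interface_area when a structure is given

    @property
    def segments(self) -> list[Segment]:
        seen, out = set(), []
        for a, b in self.pairs:
            for seg in (a, b):
                if seg not in seen:
                    seen.add(seg)
                    out.append(seg)
        return out


def _split_by_domain(res_ids: list[int], lo: int, hi: int,
                     domains: DomainAnnotation) -> list[tuple[int, int, str]]:
    """Split index range [lo, hi) into maximal same-domain stretches."""
    out = []
    i = lo
    while i < hi:
        lab = domains.label_of(res_ids[i])
        j = i
        while j < hi and domains.label_of(res_ids[j]) == lab:
            j += 1
        if lab is not None:
            out.append((i, j, lab))
        i = j
    return out


def correlated_segments(C: CorrelationMap, domains: DomainAnnotation,
                        res_ids: list[int] | None = None,
                        chain: str = "A",
                        r_min: float = 0.8, min_len: int = 4,
                        min_separation: int = 10
                        ) -> list[tuple[Segment, Segment, float]]:
    """Find sequence-separated rectangular blocks of high positive correlation.

    Returns (segment_i, segment_j, mean correlation) triples with
    segment_i preceding segment_j in sequence.  A block is a run-pair
    (i-run × j-run) whose entries are all ≥ ``r_min``; blocks are grown from
    connected regions of the thresholded map, trimmed to single-domain runs
    and to full rectangles, and kept when both runs reach ``min_len``
    residues and the runs are at least ``min_separation`` residues apart.
    """
    if not 0 < r_min <= 1:
        raise PreconditionError("r_min must lie in (0, 1]")
    if min_len < 2:
        raise PreconditionError("min_len must be ≥ 2")
    M = C.matrix
    n = M.shape[0]
    ids = res_ids if res_ids is not None else list(range(1, n + 1))
    hot = M >= r_min
    # keep only well-separated upper-triangle entries
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) >= min_separation
    hot &= sep
    hot &= np.triu(np.ones((n, n), dtype=bool), 1)

    # connected components (4-connectivity) of the thresholded map
    from scipy.ndimage import label as cc_label

    lab, n_comp = cc_label(hot)
    results = []
    for comp in range(1, n_comp + 1):
        rows, cols = np.nonzero(lab == comp)
        i0, i1 = rows.min(), rows.max() + 1
        j0, j1 = cols.min(), cols.max() + 1
        for a0, a1, dom_a in _split_by_domain(ids, i0, i1, domains):
            for b0, b1, dom_b in _split_by_domain(ids, j0, j1, domains):
                block = hot[a0:a1, b0:b1]
                ra0, ra1, rb0, rb1 = _shrink_to_full(block, a0, a1, b0, b1)
                if ra1 - ra0 < min_len or rb1 - rb0 < min_len:
                    continue
                if ids[rb0] - ids[ra1 - 1] < min_separation:
                    continue
                mean_r = float(M[ra0:ra1, rb0:rb1].mean())
                seg_a = Segment(chain, ids[ra0], ids[ra1 - 1], dom_a)
                seg_b = Segment(chain, ids[rb0], ids[rb1 - 1], dom_b)
                results.append((seg_a, seg_b, mean_r))
    results.sort(key=lambda t: (t[0].start_res, t[1].start_res))
    return _assign_sublabels(results)


def _shrink_to_full(block: np.ndarray, a0: int, a1: int, b0: int, b1: int
                    ) -> tuple[int, int, int, int]:
    """Greedily drop the sparsest boundary row/column until the block is all-True."""
    r0, r1, c0, c1 = 0, block.shape[0], 0, block.shape[1]
    while r1 > r0 and c1 > c0 and not block[r0:r1, c0:c1].all():
        sub = block[r0:r1, c0:c1]
        frac = [sub[0].mean(), sub[-1].mean(), sub[:, 0].mean(), sub[:, -1].mean()]
        k = int(np.argmin(frac))
        if k == 0:
            r0 += 1
        elif k == 1:
            r1 -= 1
        elif k == 2:
            c0 += 1
        else:
            c1 -= 1
    return a0 + r0, a0 + r1, b0 + c0, b0 + c1


def _assign_sublabels(triples):
    """Label segments G1..Gk / L1..Lk / C1..Ck by ascending start position."""
    prefix = {"GH9": "G", "L": "L", "CBM49": "C"}
    counters: dict[str, int] = {}
    seen: dict[tuple, str] = {}
    out = []
    for a, b, r in triples:
        labelled = []
        for seg in (a, b):
            key = (seg.chain, seg.start_res, seg.end_res, seg.domain)
            if key not in seen:
                counters[seg.domain] = counters.get(seg.domain, 0) + 1
                seen[key] = f"{prefix[seg.domain]}{counters[seg.domain]}"
            labelled.append(Segment(seg.chain, seg.start_res, seg.end_res,
                                    seg.domain, seen[key]))
        out.append((labelled[0], labelled[1], r))
    return out


def classify_surfaces(pairs: list[tuple[Segment, Segment, float]],
                      domains: DomainAnnotation) -> list[InteractionSurface]:
    """Group correlated segment pairs into interaction surfaces.

    Pairs sharing a segment belong to one surface (connected components of
    the segment-pair graph).  A component joining GH9 and CBM49 is class GC,
    GH9–linker GL, CBM49–linker CL; a component touching all three domains
    is the composite class GLC.
    """
    for a, b, _ in pairs:
        for seg in (a, b):
            for rid in (seg.start_res, seg.end_res):
                if domains.label_of(rid) is None:
                    raise AnnotationError(f"residue {rid} carries no domain annotation")

    parent: dict[Segment, Segment] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    for a, b, _ in pairs:
        union(a, b)
    comps: dict[Segment, list[tuple[Segment, Segment, float]]] = {}
    for a, b, r in pairs:
        comps.setdefault(find(a), []).append((a, b, r))
    surfaces = []
    for members in comps.values():
        doms = frozenset(s.domain for a, b, _ in members for s in (a, b))
        cls = _CLASS_BY_DOMAINS.get(doms)
        if cls is None:  # intra-domain correlation patch: not an interface
            continue
        mean_r = float(np.mean([r for *_, r in members]))
        surfaces.append(InteractionSurface([(a, b) for a, b, _ in members],
                                           cls, mean_r))
    surfaces.sort(key=lambda s: min(seg.start_res for seg in s.segments))
    return surfaces


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere quadrature (golden-angle spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def shrake_rupley_sasa(s: Structure, radii: np.ndarray | float = DEFAULT_RESIDUE_RADIUS,
                       probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS,
                       subset: np.ndarray | None = None) -> np.ndarray:
    """Per-residue solvent-accessible surface area (Å²) on the sphere model.

    Each residue is one sphere centred on its Cα; the accessible area of
    residue i is the fraction of quadrature points on its probe-expanded
    sphere not buried inside any other residue's expanded sphere, times
    4π(r_i+probe)².  ``subset`` (boolean mask or index array) restricts the
    computation to a sub-structure, as needed for buried-area differences.
    """
    centers = s.coords
    n = centers.shape[0]
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,)).copy()
    if np.any(radii <= 0):
        raise PreconditionError("radii must be positive")
    if n_points < 92:
        raise PreconditionError("need at least 92 quadrature points")
    if subset is not None:
        idx = np.arange(n)[subset] if np.asarray(subset).dtype == bool \
            else np.asarray(subset, dtype=int)
        centers, radii = centers[idx], radii[idx]
        n = centers.shape[0]
    expanded = radii + probe
    d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
    if np.any(d[~np.eye(n, dtype=bool)] < 1e-9):
        raise GeometryError("coincident sphere centers")
    pts = sphere_points(n_points)
    areas = np.empty(n)
    for i in range(n):
        shell = centers[i] + expanded[i] * pts  # quadrature on residue i's shell
        neighbours = np.nonzero((d[i] < expanded[i] + expanded) &
                                (np.arange(n) != i))[0]
        buried = np.zeros(n_points, dtype=bool)
        for j in neighbours:
            buried |= (np.linalg.norm(shell - centers[j], axis=1) < expanded[j])
        areas[i] = (1.0 - buried.mean()) * 4.0 * np.pi * expanded[i] ** 2
    return areas


def buried_interface_area(s: Structure, set_a: set[int], set_b: set[int],
                          probe: float = DEFAULT_PROBE,
                          radii: np.ndarray | float = DEFAULT_RESIDUE_RADIUS,
                          n_points: int = DEFAULT_N_POINTS) -> float:
    """Buried surface area (Å²) between two disjoint residue-id sets.

    BSA = SASA(A alone) + SASA(B alone) − SASA(A ∪ B together); other
    residues of the structure are ignored entirely.
    """
    if set_a & set_b:
        raise PreconditionError("residue sets must be disjoint")
    ids = np.array(s.res_ids)
    mask_a = np.isin(ids, list(set_a))
    mask_b = np.isin(ids, list(set_b))
    if not mask_a.any() or not mask_b.any():
        raise PreconditionError("both residue sets must be present in the structure")
    n = len(s)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,))
    a_alone = shrake_rupley_sasa(s, radii, probe, n_points, subset=mask_a).sum()
    b_alone = shrake_rupley_sasa(s, radii, probe, n_points, subset=mask_b).sum()
    together = shrake_rupley_sasa(s, radii, probe, n_points,
                                  subset=mask_a | mask_b).sum()
    return float(a_alone + b_alone - together)
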