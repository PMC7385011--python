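"""End-to-end orchestration: structures → core → modes/RMSF/DCCM → surfaces
→ PCA → grooves → active site.

The pipeline is driven by a :class:`PipelineConfig` whose defaults equal the
per-module defaults documented in each module; every run writes one TSV per
stage plus a ``summary.yaml`` recording parameters, seed, package version
and per-stage wall time.  All randomness flows from the single ``seed``.
Stage failures abort the run with the stage name prefixed to the error.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .active_site import (AA_CLASSES, ResidueSet, combine_active_site,
                          composition, parse_residue_list)
from .enm import compute_modes, dccm_from_modes, mode_rmsf, ensemble_rmsf
from .errors import ClefscopeError
from .groove import assign_groove_domains, cylinder_from_groove, grid_groove_measure
from .pca import coordinate_pca, quadrant_cluster
from .structures_io import (DomainAnnotation, read_alignment,
                            read_structure, write_structure)
from .superposition import find_invariant_core, superpose_ensemble
from .surfaces import (buried_interface_area, classify_surfaces,
                       correlated_segments)
from .synthetic import (SyntheticSpec, family_msa_fasta, make_ensemble,
                        make_family, make_multidomain_structure)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

STAGES = ("structures_io", "core", "enm", "surfaces", "pca", "groove",
          "active_site")


class PipelineError(ClefscopeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameters with their documented defaults."""

    # inputs: either a directory of PDBs (+ MSA) or synthetic generation
    pdb_dir: str | None = None
    msa: str | None = None
    domains: dict | None = None  # {"GH9": [[a, b]], ...}
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)  # SyntheticSpec overrides

    # superposition / invariant core
    core_cutoff: float = 1.0  # Å³ per-column ellipsoid volume
    min_core: int = 20
    core_criterion: str = "per_column"  # or "total"
    resuperpose: bool = True
    reference: int = 0

    # elastic network model
    enm_cutoff: float = 15.0  # Å
    gamma: float = 1.0
    mode_range: tuple = (7, 18)

    # interaction surfaces
    r_min: float = 0.8
    min_len: int = 4
    min_separation: int = 10
    probe: float = 1.4  # Å
    residue_radius: float = 3.0  # Å
    n_points: int = 960

    # PCA
    pca_axes: tuple = (1, 3)
    pca_columns: str = "all"  # or "core"

    # groove detection
    groove_spacing: float = 0.5  # Å
    groove_min_volume: float = 50.0  # Å³

    # active site (docking-favourable residues are external input)
    dock_list: str | None = None  # path to a "L60, Q64, ..." text file

    out_dir: str = "clefscope_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("mode_range", "pca_axes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ClefscopeError as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


def _load_inputs(cfg: PipelineConfig, out: Path):
    if cfg.simulate or cfg.pdb_dir is None:
        spec = SyntheticSpec(**{"seed": cfg.seed, **cfg.synthetic})
        base, annotation = make_multidomain_structure(spec)
        members, core_cols, labels, amap = make_family(base, annotation, spec)
        frames = make_ensemble(base, annotation, spec)
        write_structure(base, out / "base_structure.pdb")
        (out / "family.fasta").write_text(family_msa_fasta(members))
        truth = {"core_columns": [c + 1 for c in core_cols],
                 "cluster_labels": labels}
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh)
        return base, annotation, members, amap, frames
    pdbs = sorted(Path(cfg.pdb_dir).glob("*.pdb"))
    if not pdbs:
        raise ClefscopeError(f"no PDB files under {cfg.pdb_dir}")
    members = [read_structure(p) for p in pdbs]
    base = members[cfg.reference]
    if cfg.domains is None:
        raise ClefscopeError("domain annotation required for real input")
    annotation = DomainAnnotation.from_dict(cfg.domains)
    if cfg.msa is None:
        raise ClefscopeError("an MSA is required for family analyses")
    amap = read_alignment(cfg.msa, members)
    return base, annotation, members, amap, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns {stage: output path} and writes summary.yaml."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    timings: dict[str, float] = {}

    def timed(stage, fn, *args, **kw):
        t0 = time.perf_counter()
        result = _stage(stage)(fn)(*args, **kw)
        timings[stage] = round(time.perf_counter() - t0, 3)
        return result

    base, annotation, members, amap, frames = timed(
        "structures_io", _load_inputs, cfg, out)
    annotation.validate_against(base)

    # --- invariant core ---------------------------------------------------
    core = timed("core", find_invariant_core, members, amap,
                 cutoff=cfg.core_cutoff, min_core=cfg.min_core,
                 resuperpose=cfg.resuperpose, criterion=cfg.core_criterion)
    rank = {c: i + 1 for i, c in enumerate(core.removal_order)}
    core_df = pd.DataFrame({
        "column_1based": [c + 1 for c in sorted(core.volumes)],
        "volume_A3": [core.volumes[c] for c in sorted(core.volumes)],
        "in_core": [int(c in set(core.core_columns)) for c in sorted(core.volumes)],
        "removal_rank": [rank.get(c, 0) for c in sorted(core.volumes)],
    })
    outputs["core"] = _write(core_df, out / "core.tsv")

    # --- elastic-network dynamics ----------------------------------------
    def enm_stage():
        modes = compute_modes(base, cutoff=cfg.enm_cutoff, gamma=cfg.gamma)
        prof = mode_rmsf(modes, tuple(cfg.mode_range))
        if frames is not None:
            block = _superpose_frames(frames)
            ens_prof = ensemble_rmsf(block)
        else:
            ens_prof = None
        C = dccm_from_modes(modes, tuple(cfg.mode_range),
                            labels=[str(r.res_id) for r in base.residues])
        return modes, prof, ens_prof, C

    modes, prof, ens_prof, C = timed("enm", enm_stage)
    k = min(30, len(modes.eigenvalues))
    modes_df = pd.DataFrame({
        "mode": np.arange(1, k + 1),
        "eigenvalue": modes.eigenvalues[:k],
        "frequency_arb": modes.frequencies[:k],
    })
    _write(modes_df, out / "modes.tsv")
    rmsf_df = pd.DataFrame({
        "res_id": base.res_ids,
        "domain": [annotation.label_of(r) for r in base.res_ids],
        "rmsf_mode_rel": prof.rmsf,
    })
    if ens_prof is not None:
        rmsf_df["rmsf_ensemble_A"] = ens_prof.rmsf
    _write(rmsf_df, out / "rmsf.tsv")
    dccm_df = pd.DataFrame(C.matrix, index=C.labels, columns=C.labels)
    dccm_df.to_csv(out / "dccm.tsv", sep="\t")
    outputs["enm"] = str(out / "rmsf.tsv")

    # --- interaction surfaces --------------------------------------------
    def surfaces_stage():
        pairs = correlated_segments(C, annotation, res_ids=base.res_ids,
                                    r_min=cfg.r_min, min_len=cfg.min_len,
                                    min_separation=cfg.min_separation)
        surfs = classify_surfaces(pairs, annotation)
        rows = []
        for s in surfs:
            set_a = {rid for seg in s.segments[:1] for rid in seg.res_ids}
            set_b = {rid for seg in s.segments[1:] for rid in seg.res_ids}
            set_b -= set_a
            bsa = buried_interface_area(base, set_a, set_b, probe=cfg.probe,
                                        radii=cfg.residue_radius,
                                        n_points=cfg.n_points) if set_b else 0.0
            s.buried_area = bsa
            rows.append({
                "class": s.surface_class,
                "segments": ";".join(f"{seg.sublabel}:{seg.start_res}-{seg.end_res}"
                                     for seg in s.segments),
                "buried_area_A2": round(bsa, 2),
                "mean_r": round(s.mean_correlation, 3),
            })
        return surfs, pd.DataFrame(
            rows, columns=["class", "segments", "buried_area_A2", "mean_r"])

    surfs, surf_df = timed("surfaces", surfaces_stage)
    outputs["surfaces"] = _write(surf_df, out / "surfaces.tsv")

    # --- coordinate PCA ---------------------------------------------------
    def pca_stage():
        fit_cols = (core.core_columns if cfg.pca_columns == "core"
                    else amap.ungapped_columns)
        block = superpose_ensemble(members, amap, fit_columns=fit_cols,
                                   reference=cfg.reference)
        if cfg.pca_columns == "core":
            keep = [amap.ungapped_columns.index(c) for c in core.core_columns]
            block = block[:, keep, :]
        p = coordinate_pca(block)
        ax, ay = cfg.pca_axes
        ax = min(ax, p.n_components)
        ay = min(ay, p.n_components)
        quads = quadrant_cluster(p, ax, ay)
        cols = {"structure": [m.name for m in members]}
        for i in range(min(4, p.n_components)):
            cols[f"pc{i + 1}"] = np.round(p.projections[:, i], 4)
        cols["quadrant"] = quads
        return p, pd.DataFrame(cols)

    p, pca_df = timed("pca", pca_stage)
    outputs["pca"] = _write(pca_df, out / "pca.tsv")

    # --- grooves ----------------------------------------------------------
    def groove_stage():
        grooves = grid_groove_measure(base, probe=cfg.probe,
                                      spacing=cfg.groove_spacing,
                                      min_volume=cfg.groove_min_volume,
                                      residue_radius=cfg.residue_radius)
        rows = []
        for g in grooves:
            cyl = cylinder_from_groove(g.A_o, g.V_o)
            doms = assign_groove_domains(g, annotation)
            rows.append({
                "A_o_A2": round(g.A_o, 2), "V_o_A3": round(g.V_o, 2),
                "r_A": round(cyl.r, 2), "h_A": round(cyl.h, 2),
                "l_A": round(cyl.l, 2), "A_c_A2": round(cyl.A_c, 2),
                "V_c_A3": round(cyl.V_c, 2), "dA_A2": round(cyl.phi, 2),
                "dV_A3": round(cyl.beta, 2),
                "domains": "".join(sorted(d[0] for d in doms)),
                "n_lining": len(g.lining_residues),
            })
        return grooves, pd.DataFrame(
            rows, columns=["A_o_A2", "V_o_A3", "r_A", "h_A", "l_A", "A_c_A2",
                           "V_c_A3", "dA_A2", "dV_A3", "domains", "n_lining"])

    grooves, groove_df = timed("groove", groove_stage)
    outputs["groove"] = _write(groove_df, out / "grooves.tsv")

    # --- active-site set algebra -----------------------------------------
    def active_site_stage():
        by_id = {r.res_id: r.aa for r in base.residues}
        cvg_ids = set().union(*(g.lining_residues for g in grooves)) \
            if grooves else set()
        is_ids = {rid for s in surfs for seg in s.segments for rid in seg.res_ids}
        cvg = ResidueSet(frozenset((rid, by_id[rid]) for rid in cvg_ids), "CvG")
        is_set = ResidueSet(frozenset((rid, by_id[rid]) for rid in is_ids), "IS")
        if cfg.dock_list:
            dock = parse_residue_list(Path(cfg.dock_list).read_text(), "Dock")
        else:  # docking is external input; default to the CvG candidates
            dock = ResidueSet(cvg.members, "Dock")
        combined, flags = combine_active_site(dock, cvg, is_set)
        rows = []
        for rid, aa in sorted(dock.members | cvg.members | is_set.members):
            cls = next((c for c, mem in AA_CLASSES.items() if aa in mem), "")
            rows.append({"res_id": rid, "aa": aa,
                         "in_dock": int((rid, aa) in dock.members),
                         "in_cvg": int((rid, aa) in cvg.members),
                         "in_is": int((rid, aa) in is_set.members),
                         "in_combined": int((rid, aa) in combined.members),
                         "class": cls})
        df = pd.DataFrame(rows, columns=["res_id", "aa", "in_dock", "in_cvg",
                                         "in_is", "in_combined", "class"])
        stats = composition(combined) if len(combined) else None
        return df, stats, flags

    aa_df, aa_stats, aa_flags = timed("active_site", active_site_stage)
    outputs["active_site"] = _write(aa_df, out / "activesite.tsv")

    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": asdict(cfg),
        "stage_seconds": timings,
        "n_structures": len(members),
        "n_core_columns": len(core.core_columns),
        "n_surfaces": len(surfs),
        "n_grooves": len(grooves),
        "pca_variance_fractions": [float(f) for f in p.variance_fractions[:4]],
        "active_site_flags": [f"{aa}{rid}" for rid, aa in aa_flags],
        "active_site_composition": (
            {k: round(v, 4) for k, v in aa_stats.fractions.items()}
            if aa_stats else None),
    }
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    outputs["summary"] = str(out / "summary.yaml")
    return outputs


def _superpose_frames(frames: np.ndarray) -> np.ndarray:
    """Rigid-fit every frame onto the first (all residues as fit set)."""
    from .superposition import kabsch_superpose

    ref = frames[0]
    out = np.empty_like(frames)
    out[0] = ref
    for f in range(1, frames.shape[0]):
        sup = kabsch_superpose(frames[f], ref)
        out[f] = sup.apply(frames[f])
    return out


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False)
    return str(path)
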