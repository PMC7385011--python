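"""Structure and alignment I/O for Cα-level analysis of multi-domain enzymes.

The central container is :class:`Structure`, an ordered list of residues each
carrying its author numbering, one-letter code and Cα coordinate.  Plant
class C endoglucanases are annotated with a :class:`DomainAnnotation` mapping
the labels ``GH9`` (catalytic domain), ``L`` (linker) and ``CBM49``
(carbohydrate-binding module) onto author residue ranges.  A multiple
sequence alignment over a set of structures becomes an :class:`AlignmentMap`
that lets downstream code address equivalent residues by alignment column.

Conventions: author PDB numbering is kept verbatim; user-facing residue
intervals are 1-based inclusive; alignment columns are 0-based internally and
reported 1-based.  Only Cα atoms are required — all analyses here are
Cα-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
from biotite.sequence import ProteinSequence

from .errors import (
    FormatError,
    IntegrityError,
    MappingError,
    PreconditionError,
    SerializationError,
)

__all__ = [
    "Residue",
    "Structure",
    "DomainAnnotation",
    "AlignmentMap",
    "read_structure",
    "write_structure",
    "read_alignment",
    "corrected_subset",
]

DOMAIN_LABELS = ("GH9", "L", "CBM49")


@dataclass(frozen=True)
class Residue:
    chain_id: str
    res_id: int
    aa: str
    xyz: tuple[float, float, float]


@dataclass
class Structure:
    """Ordered Cα trace of one protein model."""

    residues: list[Residue]
    name: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise PreconditionError("a Structure must contain at least one residue")
        keys = [(r.chain_id, r.res_id) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise IntegrityError(f"duplicate (chain, res_id) pairs in {self.name!r}")
        if not np.all(np.isfinite(self.coords)):
            raise IntegrityError(f"non-finite coordinates in {self.name!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """N×3 Cα coordinates in Å, in residue order."""
        return np.asarray([r.xyz for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def res_ids(self) -> list[int]:
        return [r.res_id for r in self.residues]

    def subset(self, indices: Sequence[int], name: str | None = None) -> "Structure":
        return Structure([self.residues[i] for i in indices],
                         name=self.name if name is None else name)


@dataclass
class DomainAnnotation:
    """Maps domain labels to inclusive author res_id ranges.

    ``intervals`` is e.g. ``{"GH9": [(1, 450)], "L": [(451, 510)],
    "CBM49": [(511, 620)]}``.  Ranges within and across domains must be
    disjoint.
    """

    intervals: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        covered: set[int] = set()
        for label, ranges in self.intervals.items():
            if label not in DOMAIN_LABELS:
                raise PreconditionError(
                    f"unknown domain label {label!r}; expected one of {DOMAIN_LABELS}")
            for a, b in ranges:
                if a > b:
                    raise PreconditionError(f"inverted range ({a}, {b}) in {label}")
                ids = set(range(a, b + 1))
                if covered & ids:
                    raise PreconditionError(f"overlapping domain ranges at {label}")
                covered |= ids

    def label_of(self, res_id: int) -> str | None:
        for label, ranges in self.intervals.items():
            for a, b in ranges:
                if a <= res_id <= b:
                    return label
        return None

    def residue_ids(self, label: str) -> list[int]:
        return [i for a, b in self.intervals.get(label, []) for i in range(a, b + 1)]

    def validate_against(self, s: Structure) -> None:
        present = set(s.res_ids)
        for label, ranges in self.intervals.items():
            for a, b in ranges:
                missing = [i for i in range(a, b + 1) if i not in present]
                if missing:
                    raise PreconditionError(
                        f"domain {label} annotates res_id {missing[0]} absent from "
                        f"structure {s.name!r}")

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[Iterable[int]]]) -> "DomainAnnotation":
        return cls({k: [(int(a), int(b)) for a, b in v] for k, v in d.items()})


@dataclass
class AlignmentMap:
    """Column → residue correspondence for a set of aligned structures.

    ``column_maps[name][c]`` gives the residue *index* (position in the
    Structure's residue list) occupying alignment column ``c`` for structure
    ``name``; columns where the sequence is gapped are absent from the
    mapping.  ``ungapped_columns`` lists columns occupied in every structure.
    """

    n_columns: int
    column_maps: dict[str, dict[int, int]]
    ungapped_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, cmap in self.column_maps.items():
            if len(set(cmap.values())) != len(cmap):
                raise IntegrityError(f"non-injective column map for {name!r}")

    def occupied(self, name: str) -> set[int]:
        return set(self.column_maps[name])

    def coords_at(self, s: Structure, columns: Sequence[int]) -> np.ndarray:
        """C×3 coordinates of structure ``s`` at the given columns (all must be occupied)."""
        cmap = self.column_maps[s.name]
        xyz = s.coords
        return xyz[[cmap[c] for c in columns]]


def _three_to_one(res_name: str) -> str:
    try:
        return ProteinSequence.convert_letter_3to1(res_name)
    except KeyError:
        return "X"


def read_structure(path: str | Path, chain: str | None = None,
                   name: str | None = None) -> Structure:
    """Read a Cα trace from a PDB file.

    One :class:`Residue` is produced per residue bearing a CA atom, in file
    order.  Alternate locations are resolved to the highest-occupancy
    (first-listed on ties) conformer.  Insertion codes are rejected.
    """
    path = Path(path)
    pdb = bpdb.PDBFile.read(str(path))
    try:
        atoms = bpdb.get_structure(pdb, model=1, altloc="occupancy",
                                   extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises on files without ATOM records
        raise FormatError(f"{path}: cannot parse PDB structure: {exc}") from exc
    ca = atoms[atoms.atom_name == "CA"]
    if chain is not None:
        ca = ca[ca.chain_id == chain]
    if ca.array_length() == 0:
        raise FormatError(f"{path}: no CA atoms found"
                          + (f" in chain {chain!r}" if chain else ""))
    if np.any(ca.ins_code != ""):
        bad = ca[ca.ins_code != ""][0]
        raise FormatError(
            f"{path}: insertion code {bad.ins_code!r} at residue {bad.res_id}; "
            "insertion codes are not supported")
    residues = []
    for a in ca:
        residues.append(Residue(str(a.chain_id), int(a.res_id),
                                _three_to_one(str(a.res_name)),
                                tuple(float(x) for x in a.coord)))
    keys = [(r.chain_id, r.res_id) for r in residues]
    if len(set(keys)) != len(keys):
        raise IntegrityError(f"{path}: duplicate (chain, res_id) after altloc resolution")
    return Structure(residues, name=name if name is not None else path.stem)


def _one_to_three(aa: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(aa)
    except KeyError:
        return "UNK"


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as a Cα-only PDB file (one ATOM record per residue)."""
    for r in s.residues:
        if not (-999 <= r.res_id <= 9999):
            raise SerializationError(
                f"res_id {r.res_id} exceeds the 4-character PDB field")
        for x in r.xyz:
            if not (-999.999 <= x <= 9999.999):
                raise SerializationError(f"coordinate {x} exceeds the PDB field width")
    atoms = bst.AtomArray(len(s))
    atoms.coord = s.coords
    atoms.chain_id = np.array([r.chain_id for r in s.residues])
    atoms.res_id = np.array(s.res_ids)
    atoms.res_name = np.array([_one_to_three(r.aa) for r in s.residues])
    atoms.atom_name = np.full(len(s), "CA")
    atoms.element = np.full(len(s), "C")
    atoms.hetero = np.full(len(s), False)
    pdb = bpdb.PDBFile()
    bpdb.set_structure(pdb, atoms)
    pdb.write(str(path))


def write_ensemble(s: Structure, frames: np.ndarray, path: str | Path) -> None:
    """Write an F×N×3 coordinate ensemble as a multi-MODEL Cα PDB."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != len(s):
        raise PreconditionError("frames must be F×N×3 with N = len(structure)")
    stack = bst.AtomArrayStack(frames.shape[0], len(s))
    stack.coord = frames
    stack.chain_id = np.array([r.chain_id for r in s.residues])
    stack.res_id = np.array(s.res_ids)
    stack.res_name = np.array([_one_to_three(r.aa) for r in s.residues])
    stack.atom_name = np.full(len(s), "CA")
    stack.element = np.full(len(s), "C")
    stack.hetero = np.full(len(s), False)
    pdb = bpdb.PDBFile()
    bpdb.set_structure(pdb, stack)
    pdb.write(str(path))


def read_ensemble(path: str | Path) -> tuple[Structure, np.ndarray]:
    """Read a multi-MODEL Cα PDB into (Structure of model 1, F×N×3 coords)."""
    path = Path(path)
    pdb = bpdb.PDBFile.read(str(path))
    stack = bpdb.get_structure(pdb, altloc="first")
    ca = stack[:, stack.atom_name == "CA"]
    if ca.array_length() == 0:
        raise FormatError(f"{path}: no CA atoms found")
    first = ca[0]
    residues = [Residue(str(a.chain_id), int(a.res_id),
                        _three_to_one(str(a.res_name)),
                        tuple(float(x) for x in a.coord))
                for a in first]
    return Structure(residues, name=path.stem), np.asarray(ca.coord, dtype=float)


def _read_msa_records(path: str | Path) -> list[tuple[str, str]]:
    """Parse a FASTA or Clustal MSA into (id, gapped sequence) pairs.

    Both ``-`` and ``.`` count as gaps and are normalised to ``-``.
    """
    from Bio import AlignIO

    path = Path(path)
    with open(path) as fh:
        head = fh.read(64)
    fmt = "clustal" if head.lstrip().upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse as {fmt} MSA: {exc}") from exc
    return [(rec.id, str(rec.seq).upper().replace(".", "-")) for rec in aln]


def read_alignment(path: str | Path, structures: Sequence[Structure]) -> AlignmentMap:
    """Build an AlignmentMap from an MSA file over the given structures.

    Sequences are matched to structures by record id when every structure
    name appears in the MSA, otherwise positionally.  Each sequence, gaps
    removed, must equal its structure's amino-acid string.
    """
    records = _read_msa_records(path)
    if len(records) != len(structures):
        raise MappingError(
            f"MSA has {len(records)} sequences but {len(structures)} structures given")
    by_id = {rid: seq for rid, seq in records}
    names = [s.name for s in structures]
    if len(by_id) == len(records) and all(n in by_id for n in names):
        ordered = [(s, by_id[s.name]) for s in structures]
    else:
        ordered = [(s, seq) for s, (_, seq) in zip(structures, records)]

    n_columns = len(ordered[0][1])
    column_maps: dict[str, dict[int, int]] = {}
    for s, gapped in ordered:
        if len(gapped) != n_columns:
            raise MappingError(f"ragged MSA: sequence for {s.name!r} has "
                               f"{len(gapped)} columns, expected {n_columns}")
        degapped = gapped.replace("-", "")
        if degapped != s.sequence:
            pos = next((i for i, (a, b) in enumerate(zip(degapped, s.sequence))
                        if a != b), min(len(degapped), len(s.sequence)))
            raise MappingError(
                f"sequence/structure mismatch for {s.name!r} at ungapped position "
                f"{pos + 1}: MSA has "
                f"{degapped[pos] if pos < len(degapped) else 'end'!r}, structure has "
                f"{s.sequence[pos] if pos < len(s.sequence) else 'end'!r}")
        cmap: dict[int, int] = {}
        k = 0
        for c, ch in enumerate(gapped):
            if ch != "-":
                cmap[c] = k
                k += 1
        column_maps[s.name] = cmap
    ungapped = sorted(set.intersection(*(set(m) for m in column_maps.values())))
    return AlignmentMap(n_columns, column_maps, ungapped)


def trivial_alignment(structures: Sequence[Structure]) -> AlignmentMap:
    """Gap-free AlignmentMap for equal-length structures (identity mapping)."""
    n = len(structures[0])
    if any(len(s) != n for s in structures):
        raise MappingError("trivial alignment requires equal-length structures")
    ident = {c: c for c in range(n)}
    return AlignmentMap(n, {s.name: dict(ident) for s in structures}, list(range(n)))


def corrected_subset(full: Structure, truncated: Structure,
                     amap: AlignmentMap) -> Structure:
    """Residues of ``full`` at alignment columns shared with ``truncated``.

    This is the matched-residue subset used to compare a full-length enzyme
    with its CBM-truncated form on equal footing: x_cFL = x_FL − (x_FL − x_T).
    """
    for s in (full, truncated):
        if s.name not in amap.column_maps:
            raise MappingError(f"structure {s.name!r} not present in the alignment")
    shared = sorted(amap.occupied(full.name) & amap.occupied(truncated.name))
    if not shared:
        raise MappingError("full and truncated sequences share no alignment columns")
    fmap = amap.column_maps[full.name]
    return full.subset([fmap[c] for c in shared], name=f"{full.name}_corrected")
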