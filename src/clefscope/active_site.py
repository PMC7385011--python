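"""Active-site residue set algebra and amino-acid class composition.

Candidate active-site residues of an endoglucanase arrive from three
independent analyses: residues that dock cellulose oligomers favourably
(``Dock``), residues lining cavities and grooves (``CvG``), and residues of
inter-domain interaction surfaces (``IS``).  The consolidated active-site
set is the intersection Dock ∩ CvG, expected (and checked, not enforced) to
lie inside IS.

Composition statistics use the amino-acid classes customary for
carbohydrate-binding sites:

    AAA  = {W, F, Y}          aromatic (stacking with glucopyranose rings)
    P    = {P}                proline
    RKNQ = {R, K, N, Q}       basic/amide hydrogen-bond donors
    ST   = {S, T}             hydroxyl
    HSC  = {L, I, V, A, M}    hydrophobic side chains
    CAT  = {D, E, C, H}       catalytic-type residues (acid/base/nucleophile)

The classes are disjoint; glycine and any other residues are untracked, so
the six fractions sum to ≤ 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import PreconditionError, ResidueParseError

__all__ = [
    "ResidueSet",
    "CompositionStats",
    "AA_CLASSES",
    "parse_residue_list",
    "combine_active_site",
    "composition",
]

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

AA_CLASSES: dict[str, frozenset[str]] = {
    "AAA": frozenset("WFY"),
    "P": frozenset("P"),
    "RKNQ": frozenset("RKNQ"),
    "ST": frozenset("ST"),
    "HSC": frozenset("LIVAM"),
    "CAT": frozenset("DECH"),
}

_TOKEN = re.compile(r"^([A-Za-z])(\d+)$")


@dataclass
class ResidueSet:
    """A set of (res_id, one-letter code) pairs with a provenance label."""

    members: frozenset[tuple[int, str]]
    provenance: str = ""  # Dock | CvG | IS | Combined

    def __post_init__(self):
        ids = [rid for rid, _ in self.members]
        if len(set(ids)) != len(ids):
            raise PreconditionError("duplicate res_ids in residue set")
        bad = [aa for _, aa in self.members if aa not in VALID_AA]
        if bad:
            raise PreconditionError(f"invalid amino-acid code {bad[0]!r}")

    def __len__(self) -> int:
        return len(self.members)

    @property
    def res_ids(self) -> set[int]:
        return {rid for rid, _ in self.members}


@dataclass
class CompositionStats:
    """Class fractions over a residue set (counts / total)."""

    fractions: dict[str, float]
    counts: dict[str, int]
    total: int

    def __getitem__(self, cls: str) -> float:
        return self.fractions[cls]


def parse_residue_list(text: str, provenance: str = "") -> ResidueSet:
    """Parse a printed residue list like ``"L60, Q64, A67"``.

    Tokens are one-letter code + author residue number, separated by commas
    and/or whitespace.  Duplicated residue numbers are rejected.
    """
    members: list[tuple[int, str]] = []
    seen: set[int] = set()
    for pos, token in enumerate(t for t in re.split(r"[,\s]+", text.strip()) if t):
        m = _TOKEN.match(token)
        if not m:
            raise ResidueParseError(f"malformed residue token {token!r} "
                                    f"(position {pos + 1})")
        aa, rid = m.group(1).upper(), int(m.group(2))
        if aa not in VALID_AA:
            raise ResidueParseError(f"invalid amino-acid code in {token!r} "
                                    f"(position {pos + 1})")
        if rid in seen:
            raise ResidueParseError(f"duplicate residue {token!r} "
                                    f"(position {pos + 1})")
        seen.add(rid)
        members.append((rid, aa))
    if not members:
        raise ResidueParseError("empty residue list")
    return ResidueSet(frozenset(members), provenance)


def combine_active_site(dock: ResidueSet, cvg: ResidueSet, is_: ResidueSet
                        ) -> tuple[ResidueSet, list[tuple[int, str]]]:
    """Consolidated active-site set Dock ∩ CvG, with an IS containment report.

    Returns (combined set, flags) where ``flags`` lists combined members
    absent from the interaction-surface set — the expected containment
    (Dock ∩ CvG) ⊂ IS is reported when violated, never silently enforced.
    """
    combined = frozenset(dock.members & cvg.members)
    flags = sorted(combined - is_.members)
    return ResidueSet(combined, "Combined"), flags


def composition(rs: ResidueSet) -> CompositionStats:
    """Amino-acid class composition of a residue set."""
    if len(rs) == 0:
        raise PreconditionError("composition of an empty residue set is undefined")
    counts = {cls: sum(1 for _, aa in rs.members if aa in members)
              for cls, members in AA_CLASSES.items()}
    total = len(rs)
    return CompositionStats({cls: c / total for cls, c in counts.items()},
                            counts, total)
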