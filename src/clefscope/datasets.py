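"""Bundled reference tables for plant class C GH9 endoglucanases.

Three small published tables ship with the package so the cylinder model
and the active-site set algebra can be exercised on real numbers without
any external download:

* ``characterised_grooves`` — observed groove area/volume pairs (A_o, V_o)
  and published cylinder parameters for the four laboratory-characterised
  enzymes (UniProt Q5NAT0, Q8LJP6, Q93WY9, Q9ZSP9);
* ``putative_grooves`` — published cylinder (r, h, l) values for the GH9 and
  CBM49 grooves of 39 putative class C enzymes (one lacks a CBM49 groove);
* ``active_site_residues`` — the published candidate ligand-interacting
  residue list of each characterised enzyme, in ``L60, Q64, …`` notation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .active_site import ResidueSet, parse_residue_list

__all__ = [
    "load_characterised_grooves",
    "load_putative_grooves",
    "load_active_site_lists",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("clefscope.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_characterised_grooves() -> pd.DataFrame:
    """Groove observations (A_o Å², V_o Å³) and published cylinder values
    (r, h, l, A_c, V_c, dA=∅, dV=β) for the four characterised enzymes."""
    return _read("characterised_grooves.tsv")


def load_putative_grooves() -> pd.DataFrame:
    """Published cylinder (r, h, l) for GH9 and CBM49 grooves of 39 putative
    class C enzymes; CBM49 columns are NaN where no groove was reported."""
    return _read("putative_grooves.tsv")


def load_active_site_lists() -> dict[str, ResidueSet]:
    """Published ligand-interacting residue sets keyed by UniProt accession."""
    df = _read("active_site_residues.tsv")
    return {row.seq_id: parse_residue_list(row.residues, provenance="Dock")
            for row in df.itertuples()}
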