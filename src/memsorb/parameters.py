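"""Per-residue coarse-grained bead parameters.

The united-residue model reduces each amino acid to one interaction site at
its alpha-carbon.  Each site carries a formal charge, a hydrophobicity scale
value, and Lennard-Jones wall parameters.  Defaults:

* charges: integer formal charges at pH 7 (+1 LYS/ARG, -1 ASP/GLU, HIS and
  everything else 0, termini ignored),
* hydrophobicity: Kyte-Doolittle, shifted to zero mean over the 20 standard
  residues,
* LJ: a single generic sigma = 0.5 nm, epsilon = 0.5 kJ/mol for every
  residue type, overridable per type.

A parameter table is a mapping ``res_name -> {charge, hydrophobicity,
sigma, epsilon}`` and can be loaded from YAML or JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import yaml

DEFAULT_CHARGES: dict[str, int] = {"LYS": 1, "ARG": 1, "ASP": -1, "GLU": -1}

# Kyte & Doolittle hydropathy index.
_KD_RAW: dict[str, float] = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}
_KD_MEAN = sum(_KD_RAW.values()) / len(_KD_RAW)
KYTE_DOOLITTLE_CENTERED: dict[str, float] = {
    k: v - _KD_MEAN for k, v in _KD_RAW.items()
}

DEFAULT_BEAD_SIGMA_NM = 0.5
DEFAULT_BEAD_EPSILON_KJ = 0.5

STANDARD_RESIDUES = tuple(sorted(_KD_RAW))


def default_param_table() -> dict[str, dict[str, float]]:
    """Full default table covering the 20 standard residues."""
    return {
        res: {
            "charge": float(DEFAULT_CHARGES.get(res, 0)),
            "hydrophobicity": KYTE_DOOLITTLE_CENTERED[res],
            "sigma": DEFAULT_BEAD_SIGMA_NM,
            "epsilon": DEFAULT_BEAD_EPSILON_KJ,
        }
        for res in STANDARD_RESIDUES
    }


def load_param_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Load a residue parameter table from YAML or JSON.

    Entries override the defaults; residues absent from the file keep their
    default parameters.  A special key ``"*"`` provides a fallback entry for
    residue types not otherwise covered.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"parameter table in {path} is not a mapping")
    table = default_param_table()
    for res, entry in data.items():
        base = dict(table.get(res, {"charge": 0.0, "hydrophobicity": 0.0,
                                    "sigma": DEFAULT_BEAD_SIGMA_NM,
                                    "epsilon": DEFAULT_BEAD_EPSILON_KJ}))
        base.update(entry)
        table[res] = base
    return table
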