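"""Amino-acid residue tables: 3-to-1 letter codes and side-chain chi counts.

Only side chains with at least one chi torsion produce Ringer profiles;
glycine and alanine never appear in Ringer output and carry chi count 0 here
for completeness.
"""

from __future__ import annotations

# Standard residues. Non-standard names fall through to 'X'.
THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "U", "PYL": "O",
}

ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

# Number of chi dihedrals per residue type (chi1..chi4; chi5 of Arg ignored,
# matching the chi1-4 convention of Ringer output).
CHI_COUNTS: dict[str, int] = {
    "GLY": 0, "ALA": 0,
    "SER": 1, "CYS": 1, "THR": 1, "VAL": 1,
    "ASP": 2, "ASN": 2, "HIS": 2, "ILE": 2, "LEU": 2,
    "PHE": 2, "PRO": 2, "TRP": 2, "TYR": 2,
    "GLU": 3, "GLN": 3, "MET": 3,
    "ARG": 4, "LYS": 4,
    "MSE": 3,
}

#: residue types that produce at least one Ringer profile
ROTAMERIC = sorted(k for k, v in CHI_COUNTS.items() if v > 0 and k != "MSE")


def one_letter(res_name: str) -> str:
    """Map a three-letter residue name to its one-letter code ('X' if unknown)."""
    return THREE_TO_ONE.get(res_name.strip().upper(), "X")


def chi_count(res_name: str) -> int:
    """Number of chi angles for a residue type; 0 if unknown/non-rotameric."""
    return CHI_COUNTS.get(res_name.strip().upper(), 0)
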