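"""Amino-acid alphabet and standard background frequencies.

All likelihoods in this package are defined over the 20 standard amino
acid types.  Non-standard letters (B, Z, U, O, J) and unknowns are mapped
to 'X' on input and contribute nothing to any count.
"""
from __future__ import annotations

import numpy as np

#: Canonical residue order used by every 20-vector in the package.
AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
N_AA = 20

#: Letters silently coerced to 'X' (ambiguity/rare codes).
NONSTANDARD = set("BZUOJ")

# Robinson & Robinson amino-acid background frequencies, the standard
# null model for protein profile scoring, re-ordered to AA.
_RR = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

BACKGROUND = np.array([_RR[a] for a in AA])
BACKGROUND = BACKGROUND / BACKGROUND.sum()


def clean_residues(s: str) -> str:
    """Uppercase a residue string and map non-standard letters to 'X'."""
    out = []
    for ch in s.upper():
        if ch in AA_INDEX or ch == "X":
            out.append(ch)
        elif ch in NONSTANDARD:
            out.append("X")
        else:
            raise ValueError(f"illegal residue character {ch!r}")
    return "".join(out)


def encode(s: str) -> np.ndarray:
    """Encode residues as integer indices; 'X' becomes -1."""
    return np.array([AA_INDEX.get(ch, -1) for ch in s], dtype=np.int64)
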