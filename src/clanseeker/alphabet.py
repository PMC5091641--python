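"""Amino-acid alphabet and background frequencies.

The 20 standard residues in fixed (alphabetical one-letter) order; every
frequency vector in the package indexes into this order.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

# Robinson & Robinson style background composition (relative frequencies of
# the 20 residues in a large protein database), renormalized to sum to 1.
_ROBINSON = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

ROBINSON_BACKGROUND = np.array([_ROBINSON[a] for a in AMINO_ACIDS])
ROBINSON_BACKGROUND = ROBINSON_BACKGROUND / ROBINSON_BACKGROUND.sum()

UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)

# Secondary-structure state codes: helix, sheet, loop.
SS_STATES = "HEC"
SS_INDEX = {"H": 0, "E": 1, "C": 2}


def encode_seq(seq: str) -> np.ndarray:
    """Map a residue string to alphabet indices; unknown letters (X etc.)
    are coded as -1 and contribute nothing to profile counts."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)
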