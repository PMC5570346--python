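"""Grantham amino-acid distances.

Grantham (1974, Science 185:862-864) defined a pairwise amino-acid
dissimilarity combining side-chain composition ``c`` (atomic weight ratio of
non-carbon elements), polarity ``p`` and molecular volume ``v``:

    D(i, j) = rho * sqrt(alpha*(c_i-c_j)^2 + beta*(p_i-p_j)^2 + gamma*(v_i-v_j)^2)

with alpha = 1.833, beta = 0.1018, gamma = 0.000399 and rho = 50.723 chosen so
the mean over all pairs is 100.  The matrix is recomputed here from the
published property values; rounded values agree with the printed table
(a couple of extreme pairs, e.g. C-W, differ by 1 due to rounding in the
original publication).
"""

from __future__ import annotations

import numpy as np

ALPHA = 1.833
BETA = 0.1018
GAMMA = 0.000399
RHO = 50.723

COMPOSITION = {
    "A": 0.0, "R": 0.65, "N": 1.33, "D": 1.38, "C": 2.75, "Q": 0.89,
    "E": 0.92, "G": 0.74, "H": 0.58, "I": 0.0, "L": 0.0, "K": 0.33,
    "M": 0.0, "F": 0.0, "P": 0.39, "S": 1.42, "T": 0.71, "W": 0.13,
    "Y": 0.20, "V": 0.0,
}

POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5, "Q": 10.5,
    "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2, "L": 4.9, "K": 11.3,
    "M": 5.7, "F": 5.2, "P": 8.0, "S": 9.2, "T": 8.6, "W": 5.4,
    "Y": 6.2, "V": 5.9,
}

VOLUME = {
    "A": 31.0, "R": 124.0, "N": 56.0, "D": 54.0, "C": 55.0, "Q": 85.0,
    "E": 83.0, "G": 3.0, "H": 96.0, "I": 111.0, "L": 111.0, "K": 119.0,
    "M": 105.0, "F": 132.0, "P": 32.5, "S": 32.0, "T": 61.0, "W": 170.0,
    "Y": 136.0, "V": 84.0,
}

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"


def grantham_distance(ref: str, alt: str) -> float:
    """Grantham distance between two canonical residues, rounded as published.

    Identical residues have distance 0.  Raises ``ValueError`` for
    non-canonical residues (including X).
    """
    for aa in (ref, alt):
        if aa not in COMPOSITION:
            raise ValueError(f"non-canonical residue {aa!r}")
    d = RHO * np.sqrt(
        ALPHA * (COMPOSITION[ref] - COMPOSITION[alt]) ** 2
        + BETA * (POLARITY[ref] - POLARITY[alt]) ** 2
        + GAMMA * (VOLUME[ref] - VOLUME[alt]) ** 2
    )
    return float(round(d))


def grantham_matrix():
    """Full 20x20 Grantham matrix as a pandas DataFrame."""
    import pandas as pd

    aas = list(AMINO_ACIDS)
    m = [[grantham_distance(a, b) for b in aas] for a in aas]
    return pd.DataFrame(m, index=aas, columns=aas)
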