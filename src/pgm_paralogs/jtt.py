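"""Jones-Taylor-Thornton (JTT) empirical amino-acid substitution model.

The JTT model (Jones, Taylor & Thornton 1992, CABIOS 8:275-282) is a general
reversible Markov model of amino-acid replacement estimated from a large set
of closely related protein pairs.  It is specified by a symmetric
exchangeability matrix ``S`` and equilibrium frequencies ``pi``; the
instantaneous rate matrix is ``Q[i,j] = S[i,j] * pi[j]`` with rows summing to
zero, rescaled so that one unit of branch length equals one expected
substitution per site.

The constants below are the published JTT values in the layout used by
PAML's ``jones.dat`` (lower triangle, row-wise, amino acids in
``ARNDCQEGHILKMFPSTWYV`` order).
"""

from __future__ import annotations

import numpy as np

#: Amino-acid order for all JTT arrays.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Lower triangle (row-wise) of the JTT exchangeability matrix.
_EXCHANGEABILITIES = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

#: JTT equilibrium amino-acid frequencies (order :data:`AA_ORDER`).
EQUILIBRIUM_FREQS = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])
EQUILIBRIUM_FREQS = EQUILIBRIUM_FREQS / EQUILIBRIUM_FREQS.sum()


def exchangeability_matrix() -> np.ndarray:
    """Return the symmetric 20x20 JTT exchangeability matrix."""
    s = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = _EXCHANGEABILITIES[k]
            k += 1
    return s


def rate_matrix() -> np.ndarray:
    """JTT instantaneous rate matrix, normalised to 1 substitution/site.

    ``Q[i, j] = S[i, j] * pi[j]`` for ``i != j``; diagonal set so rows sum to
    zero; the whole matrix scaled so ``-sum_i pi_i Q_ii == 1``.
    """
    pi = EQUILIBRIUM_FREQS
    q = exchangeability_matrix() * pi[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -np.sum(pi * np.diag(q))
    return q / scale


class JttModel:
    """Precomputed spectral form of the JTT rate matrix.

    Because the model is time-reversible, ``D^{1/2} Q D^{-1/2}`` (with
    ``D = diag(pi)``) is symmetric, so transition matrices
    ``P(t) = exp(Qt)`` are obtained from a single symmetric
    eigendecomposition.
    """

    def __init__(self) -> None:
        self.pi = EQUILIBRIUM_FREQS
        self.q = rate_matrix()
        sqrt_pi = np.sqrt(self.pi)
        b = (sqrt_pi[:, None] * self.q) / sqrt_pi[None, :]
        w, u = np.linalg.eigh((b + b.T) / 2.0)
        self._w = w
        self._left = u / sqrt_pi[None, :]      # D^{-1/2} U, rows scaled later
        self._right = (u * sqrt_pi[:, None]).T  # U^T D^{1/2}
        # P(t) = D^{-1/2} U exp(wt) U^T D^{1/2}
        self._dinv_u = u / sqrt_pi[:, None]
        self._ut_d = (u * sqrt_pi[:, None]).T

    def transition_matrix(self, t: float) -> np.ndarray:
        """``P(t) = exp(Qt)``; rows sum to one for any ``t >= 0``."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        p = (self._dinv_u * np.exp(self._w * t)[None, :]) @ self._ut_d
        return np.clip(p, 0.0, None)

    def stationary_index(self, aa: str) -> int:
        return _AA_INDEX[aa]


_MODEL: JttModel | None = None


def default_model() -> JttModel:
    """Shared lazily-built :class:`JttModel` instance."""
    global _MODEL
    if _MODEL is None:
        _MODEL = JttModel()
    return _MODEL


def encode(sequence: str) -> np.ndarray:
    """Map a protein string to JTT state indices (-1 for non-canonical)."""
    return np.array([_AA_INDEX.get(c, -1) for c in sequence], dtype=int)


def decode(states: np.ndarray) -> str:
    return "".join(AA_ORDER[s] for s in states)
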