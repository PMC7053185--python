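"""Four-CpG epiallele pattern arithmetic.

An epiallele is the joint methylation state of four neighbouring CpGs on one
DNA molecule. Patterns are strings over ``{M, U}`` of length 4 and are indexed
0..15 by reading the pattern as a binary number with ``M = 1`` and the leftmost
CpG as the most significant bit, so ``UUUU`` is 0 and ``MMMM`` is 15.
"""

from __future__ import annotations

import numpy as np

N_CPGS = 4
N_PATTERNS = 2**N_CPGS

PATTERNS: tuple[str, ...] = tuple(
    format(i, f"0{N_CPGS}b").replace("1", "M").replace("0", "U")
    for i in range(N_PATTERNS)
)

PATTERN_INDEX: dict[str, int] = {p: i for i, p in enumerate(PATTERNS)}

#: True where the pattern contains both an M and a U (a "discordant" molecule).
DISCORDANT: np.ndarray = np.array(
    ["M" in p and "U" in p for p in PATTERNS], dtype=bool
)

_POPCOUNT = np.array([bin(i).count("1") for i in range(N_PATTERNS)])


def pattern_of_bits(bits: np.ndarray) -> int:
    """Index of the pattern whose CpG states are the 0/1 vector ``bits`` (1=M)."""
    return int(bits[0]) * 8 + int(bits[1]) * 4 + int(bits[2]) * 2 + int(bits[3])


def hamming_matrix() -> np.ndarray:
    """16x16 matrix of Hamming distances between patterns."""
    idx = np.arange(N_PATTERNS)
    return _POPCOUNT[idx[:, None] ^ idx[None, :]]


def flip_transition_matrix(error_rate: float) -> np.ndarray:
    """Transition matrix of independent per-CpG state flips.

    Entry ``[i, j]`` is the probability that a molecule carrying pattern ``i``
    is observed as pattern ``j`` when each CpG state flips independently with
    probability ``error_rate``.
    """
    h = hamming_matrix()
    return error_rate**h * (1.0 - error_rate) ** (N_CPGS - h)


def perturb(probs: np.ndarray, error_rate: float) -> np.ndarray:
    """Pattern distribution after independent per-CpG flips at ``error_rate``."""
    if error_rate == 0.0:
        return np.asarray(probs, dtype=float)
    return np.asarray(probs, dtype=float) @ flip_transition_matrix(error_rate)
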