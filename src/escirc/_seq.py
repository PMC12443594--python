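"""Small shared sequence helpers used across the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Canonical RSS consensus motifs (overridable everywhere they are used).
HEPTAMER_CONSENSUS = "CACAGTG"
NONAMER_CONSENSUS = "ACAAAAACC"

ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform i.i.d. DNA string of length ``n``."""
    return "".join(rng.choice(list(ALPHABET), size=n))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    """Apply i.i.d. substitution errors at ``error_rate`` per base."""
    if error_rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < error_rate)
    for i in hits:
        options = [c for c in ALPHABET if c != chars[i]]
        chars[i] = options[rng.integers(3)]
    return "".join(chars)
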