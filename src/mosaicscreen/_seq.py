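"""Small sequence utilities shared across modules.

All sequences are plain upper-case strings over {A, C, G, T, N}; all
intervals are 0-based half-open unless a file format dictates otherwise.
"""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# Base encoding used by the alignment kernels: A=0 C=1 G=2 T=3, N=4.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A=0, C=1, G=2, T=3, N/other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def check_alphabet(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGTN characters: {sorted(bad)}")
    return seq


def random_seq(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT sequence (used for synthetic loci and tests)."""
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def homopolymer_runs(seq: str):
    """Yield (start, end, base) for every maximal single-base run in seq."""
    start = 0
    n = len(seq)
    while start < n:
        end = start + 1
        while end < n and seq[end] == seq[start]:
            end += 1
        yield start, end, seq[start]
        start = end
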