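"""Shared sequence helpers (DNA-sense canonical alphabet, U/T equivalence)."""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("U")] = _ENCODE[ord("T")]
# N stays 255: never equal to any base, and never equal to another N either
# (a tag N is counted as a mismatch wherever it lands).


def canonical(seq: str) -> str:
    """Uppercase DNA-sense form of ``seq`` (U mapped to T)."""
    return seq.upper().replace("U", "T")


def check_alphabet(seq: str, allow_n: bool = True) -> str:
    """Return the canonical form of ``seq`` or raise ``ValueError``."""
    s = canonical(seq)
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return canonical(seq).translate(COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a canonical sequence into a uint8 array (N -> 255)."""
    return _ENCODE[np.frombuffer(canonical(seq).encode(), dtype=np.uint8)]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y or x == "N" for x, y in zip(canonical(a), canonical(b)))
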