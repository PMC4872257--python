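"""Numeric sequence encoding shared by background counting, word
enumeration and motif scanning.

Bases are encoded A=0, C=1, G=2, T=3; any other symbol (N, IUPAC
ambiguity) becomes 4 and poisons every window that contains it.  k-words
are packed into base-4 integers, most significant digit first, so the
packed code orders words lexicographically.
"""

from __future__ import annotations

import numpy as np

_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i

ALPHABET = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string to a uint8 array (A,C,G,T -> 0..3, else 4)."""
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Pack every length-``k`` window into a base-4 integer.

    Returns ``(packed, valid)`` where ``packed[i]`` encodes the window
    starting at position ``i`` and ``valid[i]`` is False when that window
    contains a non-ACGT symbol.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows < 4).all(axis=1)
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    packed = (windows.astype(np.int64) * weights).sum(axis=1)
    return packed, valid


def decode_word(code: int, k: int) -> str:
    """Inverse of the base-4 packing: integer code -> k-letter word."""
    out = []
    for _ in range(k):
        out.append(ALPHABET[code & 3])
        code >>= 2
    return "".join(reversed(out))


def revcomp_codes(packed: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed word codes (vectorized)."""
    packed = np.asarray(packed, dtype=np.int64)
    out = np.zeros_like(packed)
    rem = packed.copy()
    for _ in range(k):
        base = rem & 3
        out = (out << 2) | (3 - base)
        rem >>= 2
    return out


def canonical_codes(packed: np.ndarray, k: int) -> np.ndarray:
    """Map each word code to min(code, revcomp code): the canonical
    representative of a word / reverse-complement pair."""
    rc = revcomp_codes(packed, k)
    return np.minimum(packed, rc)
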