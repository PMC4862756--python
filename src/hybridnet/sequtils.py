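"""Low-level DNA k-mer encoding helpers shared across modules.

Bases are coded A=0, C=1, G=2, T=3; a k-mer is packed into an integer with
the first base in the most significant base-4 digit, so lexicographic order
of k-mer strings equals numeric order of their codes. Invalid (non-ACGT)
positions are coded 255 and propagate to a window code of -1.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into base codes (uint8; 255 marks non-ACGT)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append(BASES[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def kmer_window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-length windows of a coded sequence.

    Windows touching an invalid base get code -1. Returns an int64 array of
    length ``len(codes) - k + 1``.
    """
    n = codes.shape[0]
    if n < k:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    out = win.astype(np.int64) @ powers
    bad = (win == 255).any(axis=1)
    out[bad] = -1
    return out


def revcomp_codes(kc: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes (vectorized)."""
    kc = np.asarray(kc, dtype=np.int64)
    out = np.zeros_like(kc)
    for i in range(k):
        digit = (kc >> (2 * i)) & 3
        out |= (3 - digit) << (2 * (k - 1 - i))
    return out


def canonical_codes(kc: np.ndarray, k: int) -> np.ndarray:
    """Strand-collapsed codes: elementwise min of a code and its reverse
    complement. Codes of -1 (invalid windows) pass through as -1."""
    kc = np.asarray(kc, dtype=np.int64)
    rc = revcomp_codes(kc, k)
    out = np.minimum(kc, rc)
    out[kc < 0] = -1
    return out
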