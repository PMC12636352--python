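"""Low-level DNA <-> 2-bit integer encoding shared across modules.

Bases map A=0, C=1, G=2, T=3 so that numeric order of encoded k-mers equals
lexicographic order of the strings. Any other character (N, IUPAC codes) is
marked invalid and every k-mer window covering it is dropped.
"""

from __future__ import annotations

import numpy as np

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_CODE[ord(_b)] = _i
    _BASE_TO_CODE[ord(_b.lower())] = _i

_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N kept)."""
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_base_codes(seq: str) -> np.ndarray:
    """Per-base uint8 codes; 255 marks a non-ACGT base."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_TO_CODE[raw]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Encode every stride-1 window of ``seq`` as an int64; -1 for windows with N.

    Returns an array of length ``max(0, len(seq)-k+1)``. Requires k <= 31.
    """
    if not 1 <= k <= 31:
        raise ValueError(f"k must be in [1, 31], got {k}")
    bases = seq_to_base_codes(seq)
    n = bases.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid_base = bases != 255
    safe = np.where(valid_base, bases, 0).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(safe, k)
    codes = windows @ powers
    # a window is valid iff all k bases are ACGT
    ok = np.lib.stride_tricks.sliding_window_view(valid_base, k).all(axis=1)
    return np.where(ok, codes, -1)


def code_to_kmer(code: int, k: int) -> str:
    """Decode an int64 k-mer code back to its string."""
    out = bytearray(k)
    for pos in range(k - 1, -1, -1):
        out[pos] = _CODE_TO_BASE[code & 3]
        code >>= 2
    return out.decode("ascii")


def unique_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Sorted distinct valid k-mer codes of ``seq``."""
    codes = kmer_codes(seq, k)
    codes = codes[codes >= 0]
    return np.unique(codes)


def revcomp_code(code: int, k: int) -> int:
    """Reverse complement in code space."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out
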