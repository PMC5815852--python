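"""Low-level nucleotide utilities shared across the pipeline.

Sequences are handled either as Python strings (I/O boundaries) or as
``numpy.uint8`` arrays with the encoding A=0, C=1, G=2, T=3; any other
character maps to 4 ("ambiguous": it never matches anything, including
another ambiguous base). Code 5 is reserved for padding sentinels inside
concatenated target arrays and likewise matches nothing.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGTNN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

#: code used for inter-record padding in concatenated arrays
SENTINEL = np.uint8(5)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 array (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _DECODE[np.minimum(arr, 5)].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_arr(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-length windows of ``arr``.

    Returns ``(codes, valid)`` where ``codes[i]`` is the base-4 integer of the
    window starting at ``i`` and ``valid[i]`` is False when the window contains
    an ambiguous base or sentinel (its code is then meaningless).
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (win < 4).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ powers
    return codes, valid


def canonical_kmer(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def random_seq(rng: np.random.Generator, length: int) -> str:
    """i.i.d. uniform ACGT sequence."""
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``.

    A substituted base is drawn uniformly from the three alternatives, so the
    realized mismatch fraction equals ``rate`` in expectation.
    """
    if rate <= 0:
        return seq
    arr = encode(seq).copy()
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        shift = rng.integers(1, 4, size=n, dtype=np.uint8)
        arr[hit] = (arr[hit] + shift) % 4
    return decode(arr)
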