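"""Base-level sequence utilities shared across the package.

Bases are handled as small integer codes so that every per-column analysis
can run vectorised: A=0, C=1, G=2, T=3, N=4, and GAP=5 for alignment
columns that consume only one of the two sequences.
"""
from __future__ import annotations

import numpy as np

A, C, G, T, N, GAP = 0, 1, 2, 3, 4, 5

#: alphabet in code order; "-" renders a gap column
ALPHABET = "ACGTN-"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate(ALPHABET):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i

_COMPLEMENT = np.array([T, G, C, A, N, GAP], dtype=np.uint8)
_DECODE = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)

#: transition partner per base (A<->G, C<->T)
TRANSITION_PARTNER = np.array([G, T, A, C], dtype=np.uint8)
#: the two transversion targets per base
TRANSVERSIONS = np.array([[C, T], [A, G], [C, T], [A, G]], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a base string into uint8 codes; unknown characters are rejected
    with their position."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"unknown base {seq[pos]!r} at position {pos}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a base string over {A,C,G,T,N}.

    N is self-complementary.  Characters outside the alphabet are rejected
    with their position.
    """
    codes = encode(seq)
    bad = np.nonzero(codes > N)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(f"unknown base {seq[pos]!r} at position {pos}")
    return decode(_COMPLEMENT[codes][::-1])


def gc_fraction(codes: np.ndarray) -> float:
    """G+C over A+C+G+T; N (and gaps) excluded from the denominator.
    Returns NaN when no unambiguous base is present."""
    codes = np.asarray(codes)
    acgt = np.count_nonzero(codes < 4)
    if acgt == 0:
        return float("nan")
    gc = np.count_nonzero((codes == C) | (codes == G))
    return gc / acgt


def rle(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Run-length encode a 1-d array: (run_values, run_starts, run_lengths)."""
    values = np.asarray(values)
    n = values.size
    if n == 0:
        return values[:0], np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.nonzero(values[1:] != values[:-1])[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    return values[starts], starts, ends - starts
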