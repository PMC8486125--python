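"""Shared test helpers: constructed alignments and brute-force oracles.

The oracles are deliberately simple loop-based implementations, independent
of the vectorised production code they are checked against.
"""
from __future__ import annotations

import numpy as np

from poreprof.align_io import AlignedRead


def make_read(
    ref: str,
    read: str,
    quals=30,
    read_id: str = "r1",
    orientation: str = "forward",
    ref_name: str = "ref",
    ref_start: int = 0,
    clip_left: int = 0,
    clip_right: int = 0,
) -> AlignedRead:
    """Build an AlignedRead from two aligned strings with '-' gaps."""
    assert len(ref) == len(read)
    from poreprof._seq import encode

    ref_codes = encode(ref)
    read_codes = encode(read)
    n = len(ref)
    if np.isscalar(quals):
        q = np.full(n, quals, dtype=np.int16)
    else:
        q = np.asarray(quals, dtype=np.int16)
    q = np.where(read_codes == 5, -1, q).astype(np.int16)
    n_read = int((read_codes != 5).sum())
    return AlignedRead(
        read_id=read_id,
        orientation=orientation,
        ref_name=ref_name,
        ref_start=ref_start,
        ref_codes=ref_codes,
        read_codes=read_codes,
        quals=q,
        clip_left=clip_left,
        clip_right=clip_right,
        read_length=n_read + clip_left + clip_right,
    )


def random_alignment(rng: np.random.Generator, n_cols: int = 40) -> AlignedRead:
    """A random small alignment mixing matches, mismatches and indels."""
    bases = "ACGT"
    ref, read = [], []
    for _ in range(n_cols):
        kind = rng.choice(["match", "mismatch", "ins", "del"], p=[0.7, 0.1, 0.1, 0.1])
        if kind == "match":
            b = bases[rng.integers(4)]
            ref.append(b)
            read.append(b)
        elif kind == "mismatch":
            b = int(rng.integers(4))
            ref.append(bases[b])
            read.append(bases[(b + 1 + int(rng.integers(3))) % 4])
        elif kind == "ins":
            ref.append("-")
            read.append(bases[rng.integers(4)])
        else:
            ref.append(bases[rng.integers(4)])
            read.append("-")
    # avoid the (impossible) all-gap column pairing by construction
    return make_read("".join(ref), "".join(read))


def oracle_classify(read: AlignedRead) -> dict:
    """Column-by-column classification, the slow way."""
    counts = {"matches": 0, "mismatches": 0, "insertions": 0, "deletions": 0}
    for ref_b, read_b, _q in read.columns():
        if ref_b == "-":
            counts["insertions"] += 1
        elif read_b == "-":
            counts["deletions"] += 1
        elif ref_b in "ACGT" and read_b in "ACGT" and ref_b != read_b:
            counts["mismatches"] += 1
        else:
            counts["matches"] += 1
    return counts


def oracle_longest_perfect(read: AlignedRead) -> int:
    """Brute-force maximum over all error-free column windows, extending
    each start position column by column."""
    cols = list(read.columns())
    best = 0
    n = len(cols)
    for i in range(n):
        run = 0
        for ref_b, read_b, _q in cols[i:]:
            if ref_b == read_b and ref_b in "ACGT":
                run += 1
                best = max(best, run)
            else:
                break
    return best


def oracle_homopolymers(s: str) -> set[tuple[str, int, int, int]]:
    out = set()
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        if j - i >= 2 and s[i] in "ACGT":
            out.add((s[i], i, j, j - i))
        i = j
    return out


def oracle_heteropolymers(s: str) -> set[tuple[str, int, int, int]]:
    out = set()
    n = len(s)
    i = 0
    while i < n - 3:
        x, y = s[i], s[i + 1]
        if x == y or x not in "ACGT" or y not in "ACGT":
            i += 1
            continue
        k = 0
        while s[i + 2 * k : i + 2 * k + 2] == x + y:
            k += 1
        if k >= 2:
            # maximal: cannot be extended by a full unit on the left
            if i >= 2 and s[i - 2 : i] == x + y:
                i += 1
                continue
            out.add((x + y, i, i + 2 * k, k))
            i += 2 * k - 1
        else:
            i += 1
    return out


def oracle_trinucleotides(s: str) -> set[tuple[str, int, int, int]]:
    out = set()
    n = len(s)
    for i in range(n - 5):
        unit = s[i : i + 3]
        if len(set(unit)) == 1 or any(b not in "ACGT" for b in unit):
            continue
        k = 0
        while s[i + 3 * k : i + 3 * k + 3] == unit:
            k += 1
        if k < 2:
            continue
        if i >= 3 and s[i - 3 : i] == unit:
            continue  # extendable left: not maximal
        out.add((unit, i, i + 3 * k, k))
    return out
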