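"""Low-complexity repeats: detection, per-read assessment, error attribution.

Three repeat kinds are handled, all defined on the reference:

* homopolymer — k >= 2 consecutive copies of one base;
* heteropolymer — k >= 2 consecutive copies of a two-base unit XY, X != Y
  (total length 2k; a trailing odd base is not part of the occurrence);
* trinucleotide — k >= 2 consecutive copies of a 3-base unit XYZ, excluding
  pure single-base units (which are homopolymers).

An occurrence is correctly sequenced by a read iff the read renders an
identical repeat: same motif, same length, nothing else inside.  Observed
homopolymer lengths are measured as the maximal run of the motif base in the
read overlapping the aligned interval, so insertions the aligner placed at
the repeat boundary (or adjacent same-base read bases) extend the measured
run — the measurement is invariant to where the aligner left-shifted gaps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seq
from ._seq import GAP, decode, encode, rle
from .align_io import AlignedRead, ReferenceGenome

__all__ = [
    "RepeatOccurrence",
    "RepeatAssessment",
    "HomopolymerAttribution",
    "find_repeats",
    "assess_repeat",
    "assess_repeats",
    "repeat_accuracy_by_length",
    "length_deviation_profile",
    "attribute_errors_to_homopolymers",
    "classify_trinucleotide",
    "repeat_length_distribution",
    "homopolymer_intervals",
]

KINDS = ("homopolymer", "heteropolymer", "trinucleotide")


@dataclass(frozen=True)
class RepeatOccurrence:
    kind: str
    motif: str
    start: int
    end: int
    copies: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _find_homopolymers(codes: np.ndarray) -> pd.DataFrame:
    vals, starts, lens = rle(codes)
    sel = (lens >= 2) & (vals < 4)
    vals, starts, lens = vals[sel], starts[sel], lens[sel]
    return pd.DataFrame(
        {
            "motif": [_seq.ALPHABET[v] for v in vals],
            "start": starts,
            "end": starts + lens,
            "copies": lens,
        }
    )


def _find_heteropolymers(codes: np.ndarray) -> pd.DataFrame:
    n = codes.size
    rows = []
    if n >= 4:
        # c[i]: position i continues a period-2 alternating stretch
        c = (
            (codes[:-2] == codes[2:])
            & (codes[:-2] != codes[1:-1])
            & (codes[:-2] < 4)
            & (codes[1:-1] < 4)
        )
        vals, starts, lens = rle(c)
        for v, s, r in zip(vals, starts, lens):
            if not v or r < 2:
                continue
            stretch = r + 2
            copies = stretch // 2
            rows.append(
                {
                    "motif": decode(codes[s : s + 2]),
                    "start": int(s),
                    "end": int(s + 2 * copies),
                    "copies": int(copies),
                }
            )
    return pd.DataFrame(rows, columns=["motif", "start", "end", "copies"])


def _find_trinucleotides(codes: np.ndarray) -> pd.DataFrame:
    n = codes.size
    rows = []
    if n >= 6:
        c = (codes[:-3] == codes[3:]) & (codes[:-3] < 4) & (codes[3:] < 4)
        vals, starts, lens = rle(c)
        for v, s, r in zip(vals, starts, lens):
            if not v or r < 3:
                continue
            stretch = r + 3
            for phase in range(3):
                avail = stretch - phase
                copies = avail // 3
                if copies < 2:
                    continue
                motif = codes[s + phase : s + phase + 3]
                if motif[0] == motif[1] == motif[2]:
                    continue  # homopolymers are excluded
                rows.append(
                    {
                        "motif": decode(motif),
                        "start": int(s + phase),
                        "end": int(s + phase + 3 * copies),
                        "copies": int(copies),
                    }
                )
    df = pd.DataFrame(rows, columns=["motif", "start", "end", "copies"])
    return df.sort_values(["start", "motif"]).reset_index(drop=True)


def find_repeats(
    sequence: str | ReferenceGenome, kind: str, as_frame: bool = False
):
    """All maximal repeat occurrences of one kind on the given strand,
    left to right.

    Returns a list of :class:`RepeatOccurrence`, or with ``as_frame=True`` a
    DataFrame (columns motif/start/end/copies/length) suited to bulk work.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    codes = sequence.codes if isinstance(sequence, ReferenceGenome) else encode(sequence)
    if kind == "homopolymer":
        df = _find_homopolymers(codes)
    elif kind == "heteropolymer":
        df = _find_heteropolymers(codes)
    else:
        df = _find_trinucleotides(codes)
    df = df.reset_index(drop=True)
    df["length"] = df["end"] - df["start"]
    if as_frame:
        return df
    return [
        RepeatOccurrence(kind, r.motif, int(r.start), int(r.end), int(r.copies))
        for r in df.itertuples(index=False)
    ]


def classify_trinucleotide(motif: str) -> str:
    """Group a 3-base motif by its count of strong (S = C/G) bases."""
    if len(motif) != 3 or any(b not in "ACGT" for b in motif.upper()):
        raise ValueError(f"invalid trinucleotide motif {motif!r}")
    n_s = sum(b in "CG" for b in motif.upper())
    return {3: "S-only", 2: "mostly-S", 1: "mostly-W", 0: "W-only"}[n_s]


def canonical_dinucleotide(motif: str) -> str:
    """Pool symmetric dinucleotides (AC and CA report as one class)."""
    alt = motif[1] + motif[0]
    return min(motif, alt)


def repeat_length_distribution(
    reference: ReferenceGenome | str, kind: str
) -> pd.DataFrame:
    """Occurrence counts per (motif class, length) on the forward strand.

    Homopolymers are classed by base; heteropolymers pool symmetric
    dinucleotides; trinucleotides are classed by S/W composition.
    """
    df = find_repeats(reference, kind, as_frame=True)
    if df.empty:
        return pd.DataFrame(columns=["motif_class", "length", "count"])
    if kind == "homopolymer":
        df["motif_class"] = df["motif"]
    elif kind == "heteropolymer":
        df["motif_class"] = df["motif"].map(canonical_dinucleotide)
    else:
        df["motif_class"] = df["motif"].map(classify_trinucleotide)
    out = (
        df.groupby(["motif_class", "length"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["motif_class", "length"])
        .reset_index(drop=True)
    )
    return out


# ---------------------------------------------------------------------------
# per-read assessment


class _ReadIndex:
    """Precomputed per-read lookup structures for repeat assessment."""

    def __init__(self, read: AlignedRead):
        self.read = read
        ref_mask = read.ref_codes != GAP
        read_mask = read.read_codes != GAP
        self.ref_cols = np.nonzero(ref_mask)[0]
        # column index of the ref-consuming column per covered ref offset,
        # extended by one sentinel for interval ends at the span boundary
        self.ref_cols_ext = np.concatenate(
            (self.ref_cols, [read.n_columns])
        )
        # read bases strictly before each column boundary
        self.rb_before = np.concatenate(([0], np.cumsum(read_mask)))
        self.rbases = read.read_codes[read_mask]
        run_vals, run_starts, run_lens = rle(self.rbases)
        self.run_vals = run_vals
        self.run_lens = run_lens
        nrb = self.rbases.size
        self.run_id = (
            np.repeat(np.arange(run_vals.size), run_lens)
            if nrb
            else np.empty(0, dtype=np.int64)
        )
        self.run_len_at = (
            np.repeat(run_lens, run_lens) if nrb else np.empty(0, dtype=np.int64)
        )
        # per-base cumulative counts for each of the four bases
        onehot = np.zeros((4, nrb + 1), dtype=np.int64)
        for b in range(4):
            onehot[b, 1:] = np.cumsum(self.rbases == b)
        self.cum_base = onehot
        self.cum_mm = np.concatenate(([0], np.cumsum(read.mismatch_mask)))
        self.cum_ins = np.concatenate(([0], np.cumsum(read.insertion_mask)))
        self.cum_del = np.concatenate(([0], np.cumsum(read.deletion_mask)))


def _segment_bounds(idx: _ReadIndex, s_off: np.ndarray, e_off: np.ndarray):
    """Column and read-base bounds of the aligned segments for occurrence
    offsets [s_off, e_off) relative to the read's ref span.

    The segment runs from the ref-consuming column of the first repeat base
    through any insertion columns anchored at the last repeat base (i.e. up
    to, excluding, the ref-consuming column of the base after the repeat).
    """
    c0 = idx.ref_cols_ext[s_off]
    c1 = idx.ref_cols_ext[e_off]
    return c0, c1, idx.rb_before[c0], idx.rb_before[c1]


def _assess_homopolymers_one(
    idx: _ReadIndex, starts: np.ndarray, ends: np.ndarray, bases: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorised assessment of many homopolymer occurrences in one read."""
    read = idx.read
    s_off = starts - read.ref_start
    e_off = ends - read.ref_start
    c0, c1, i0, i1 = _segment_bounds(idx, s_off, e_off)
    ref_len = ends - starts
    wlen = i1 - i0

    n_b = idx.cum_base[bases, i1] - idx.cum_base[bases, i0]
    all_b = (n_b == wlen) & (wlen > 0)
    # exact rendering: segment is the motif base repeated ref_len times and
    # the containing read run does not extend beyond the segment
    correct = np.zeros(starts.size, dtype=bool)
    nonempty = wlen > 0
    if nonempty.any():
        rid0 = idx.run_id[np.minimum(i0, idx.rbases.size - 1)]
        correct = (
            all_b
            & (wlen == ref_len)
            & (idx.run_vals[rid0] == bases)
            & (idx.run_lens[rid0] == ref_len)
        )
    # observed length: longest full run of the motif base overlapping segment
    observed = np.zeros(starts.size, dtype=np.int64)
    if nonempty.any():
        max_w = int(wlen.max())
        for off in range(max_w):
            live = off < wlen
            if not live.any():
                break
            pos = i0[live] + off
            v = np.where(
                idx.rbases[pos] == bases[live], idx.run_len_at[pos], 0
            )
            observed[live] = np.maximum(observed[live], v)
    return {
        "start": starts.astype(np.int64),
        "ref_length": ref_len.astype(np.int32),
        "observed_length": observed.astype(np.int32),
        "correct": correct,
        "mismatches": (idx.cum_mm[c1] - idx.cum_mm[c0]).astype(np.int32),
        "insertions": (idx.cum_ins[c1] - idx.cum_ins[c0]).astype(np.int32),
        "deletions": (idx.cum_del[c1] - idx.cum_del[c0]).astype(np.int32),
    }


def _longest_motif_repeat(segment: str, motif: str) -> int:
    """Longest tandem repetition of ``motif`` inside ``segment``, in copies."""
    m = len(motif)
    best = 0
    for i in range(len(segment)):
        k = 0
        while segment[i + m * k : i + m * (k + 1)] == motif:
            k += 1
        best = max(best, k)
    return best


def _assess_generic_one(
    idx: _ReadIndex, occs: pd.DataFrame, ref_start: int
) -> list[dict]:
    rows = []
    s_off = occs["start"].to_numpy() - ref_start
    e_off = occs["end"].to_numpy() - ref_start
    c0, c1, i0, i1 = _segment_bounds(idx, s_off, e_off)
    for j, occ in enumerate(occs.itertuples(index=False)):
        segment = decode(idx.rbases[i0[j] : i1[j]])
        motif = occ.motif
        expected = motif * occ.copies
        copies_obs = _longest_motif_repeat(segment, motif)
        rows.append(
            {
                "start": occ.start,
                "ref_length": occ.end - occ.start,
                "observed_length": copies_obs * len(motif),
                "correct": segment == expected,
                "mismatches": int(idx.cum_mm[c1[j]] - idx.cum_mm[c0[j]]),
                "insertions": int(idx.cum_ins[c1[j]] - idx.cum_ins[c0[j]]),
                "deletions": int(idx.cum_del[c1[j]] - idx.cum_del[c0[j]]),
            }
        )
    return rows


@dataclass
class RepeatAssessment:
    """One read's rendering of one repeat occurrence."""

    occurrence: RepeatOccurrence
    read_id: str
    observed_length: int
    correct: bool
    mismatches: int
    insertions: int
    deletions: int


def assess_repeat(read: AlignedRead, occ: RepeatOccurrence) -> RepeatAssessment | None:
    """Assess a single occurrence; returns None when the read's aligned span
    does not fully cover it (partial overlaps cannot be judged)."""
    if not (read.ref_start <= occ.start and occ.end <= read.ref_end):
        return None
    idx = _ReadIndex(read)
    if occ.kind == "homopolymer":
        res = _assess_homopolymers_one(
            idx,
            np.array([occ.start]),
            np.array([occ.end]),
            np.array([encode(occ.motif)[0]]),
        )
        return RepeatAssessment(
            occ,
            read.read_id,
            int(res["observed_length"][0]),
            bool(res["correct"][0]),
            int(res["mismatches"][0]),
            int(res["insertions"][0]),
            int(res["deletions"][0]),
        )
    occs = pd.DataFrame(
        [{"motif": occ.motif, "start": occ.start, "end": occ.end, "copies": occ.copies}]
    )
    row = _assess_generic_one(idx, occs, read.ref_start)[0]
    return RepeatAssessment(
        occ,
        read.read_id,
        int(row["observed_length"]),
        bool(row["correct"]),
        row["mismatches"],
        row["insertions"],
        row["deletions"],
    )


def _occurrence_arrays(df: pd.DataFrame):
    starts = df["start"].to_numpy(np.int64)
    ends = df["end"].to_numpy(np.int64)
    order = np.argsort(starts, kind="stable")
    return df.iloc[order].reset_index(drop=True), starts[order], ends[order]


def assess_repeats(
    reads: Sequence[AlignedRead],
    reference: ReferenceGenome,
    kind: str,
) -> pd.DataFrame:
    """Assess every occurrence of one repeat kind fully covered by each read.

    Occurrences are detected on both oriented genome copies so that reads
    aligned against the reverse-complemented genome are scored against the
    repeats as they were sequenced.  Returns one row per (occurrence, read)
    with columns orientation/start/motif/ref_length/observed_length/correct
    and the per-type error counts inside the aligned interval.
    """
    occ = {
        "forward": _occurrence_arrays(find_repeats(reference, kind, as_frame=True)),
        "reverse": _occurrence_arrays(
            find_repeats(reference.reverse_complement(), kind, as_frame=True)
        ),
    }
    parts: list[pd.DataFrame] = []
    for read_idx, read in enumerate(reads):
        df, starts, ends = occ[read.orientation]
        if starts.size == 0 or read.n_columns == 0:
            continue
        lo = np.searchsorted(starts, read.ref_start, "left")
        hi = np.searchsorted(starts, read.ref_end, "left")
        if hi <= lo:
            continue
        sel = np.nonzero(ends[lo:hi] <= read.ref_end)[0] + lo
        if sel.size == 0:
            continue
        idx = _ReadIndex(read)
        sub = df.iloc[sel]
        if kind == "homopolymer":
            bases = encode("".join(sub["motif"]))
            res = _assess_homopolymers_one(
                idx, starts[sel], ends[sel], bases
            )
            part = pd.DataFrame(res)
            part["motif"] = pd.Categorical(
                sub["motif"].to_numpy(), categories=list("ACGT")
            )
        else:
            part = pd.DataFrame(_assess_generic_one(idx, sub, read.ref_start))
            part["motif"] = sub["motif"].to_numpy()
        part["orientation"] = pd.Categorical(
            [read.orientation] * len(part), categories=["forward", "reverse"]
        )
        part["read_index"] = np.int32(read_idx)
        parts.append(part)
    if not parts:
        return pd.DataFrame(
            columns=[
                "start", "ref_length", "observed_length", "correct",
                "mismatches", "insertions", "deletions", "motif",
                "orientation", "read_index",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def repeat_accuracy_by_length(
    assessments: pd.DataFrame,
    min_count: int = 1,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Fraction of correctly sequenced occurrences per reference length,
    optionally stratified (e.g. by ``motif``); strata with fewer than
    ``min_count`` assessed occurrences are suppressed."""
    if assessments.empty:
        cols = ["ref_length", "accuracy", "n"]
        if stratify_by:
            cols.insert(1, stratify_by)
        return pd.DataFrame(columns=cols)
    keys = ["ref_length"] + ([stratify_by] if stratify_by else [])
    g = (
        assessments.groupby(keys, observed=True)
        .agg(accuracy=("correct", "mean"), n=("correct", "size"))
        .reset_index()
    )
    return g[g["n"] >= min_count].reset_index(drop=True)


def length_deviation_profile(assessments: pd.DataFrame) -> pd.DataFrame:
    """Distribution of observed-minus-reference length per reference length:
    quartiles and extremes, semi-log friendly."""
    if assessments.empty:
        return pd.DataFrame(
            columns=["ref_length", "n", "min", "q1", "median", "q3", "max"]
        )
    dev = assessments["observed_length"] - assessments["ref_length"]
    df = assessments.assign(deviation=dev)
    g = (
        df.groupby("ref_length")["deviation"]
        .agg(
            n="size",
            min="min",
            q1=lambda x: x.quantile(0.25),
            median="median",
            q3=lambda x: x.quantile(0.75),
            max="max",
        )
        .reset_index()
    )
    return g


# ---------------------------------------------------------------------------
# error attribution


def homopolymer_intervals(reference: ReferenceGenome) -> dict[str, np.ndarray]:
    """Boolean per-position homopolymer masks for both oriented genome
    copies; positions inside any run of length >= 2."""
    out = {}
    for orientation, genome in (
        ("forward", reference),
        ("reverse", reference.reverse_complement()),
    ):
        mask = np.zeros(genome.length, dtype=bool)
        occ = find_repeats(genome, "homopolymer", as_frame=True)
        for s, e in zip(occ["start"], occ["end"]):
            mask[s:e] = True
        out[orientation] = mask
    return out


@dataclass
class HomopolymerAttribution:
    """Errors inside homopolymeric reference regions (H) vs all errors (A)."""

    h_mismatches: int
    h_insertions: int
    h_deletions: int
    a_mismatches: int
    a_insertions: int
    a_deletions: int

    @property
    def h_global(self) -> int:
        return self.h_mismatches + self.h_insertions + self.h_deletions

    @property
    def a_global(self) -> int:
        return self.a_mismatches + self.a_insertions + self.a_deletions

    def ratio_percent(self, error_type: str = "global") -> float:
        h = getattr(self, f"h_{error_type}")
        a = getattr(self, f"a_{error_type}")
        return 100.0 * h / a if a else float("nan")

    def to_frame(self) -> pd.DataFrame:
        cols = ["mismatches", "insertions", "deletions", "global"]
        return pd.DataFrame(
            {
                c: [
                    getattr(self, f"h_{c}"),
                    getattr(self, f"a_{c}"),
                    self.ratio_percent(c),
                ]
                for c in cols
            },
            index=["H: Homopol.", "A: All errors", "Ratio H/A (%)"],
        )


def attribute_errors_to_homopolymers(
    reads: Sequence[AlignedRead], reference: ReferenceGenome
) -> HomopolymerAttribution:
    """Mark errors whose reference anchor lies in a homopolymer (k >= 2).

    Mismatches and deletions are attributed by their anchored base;
    insertions are attributed when anchored strictly inside or at either
    boundary base of a run (aligners place them ambiguously at run edges).
    """
    masks = homopolymer_intervals(reference)
    # insertion mask: dilate one base to the left so gaps opened just before
    # the first repeat base are attributed too
    ins_masks = {}
    for orientation, m in masks.items():
        im = m.copy()
        im[:-1] |= m[1:]
        ins_masks[orientation] = im
    h = {"mismatches": 0, "insertions": 0, "deletions": 0}
    a = {"mismatches": 0, "insertions": 0, "deletions": 0}
    for r in reads:
        anchors = r.anchors()
        mask = masks[r.orientation]
        ins_mask = ins_masks[r.orientation]
        for key, cols in (
            ("mismatches", r.mismatch_mask),
            ("deletions", r.deletion_mask),
        ):
            a[key] += int(np.count_nonzero(cols))
            h[key] += int(np.count_nonzero(mask[anchors[cols]]))
        ins = r.insertion_mask
        a["insertions"] += int(np.count_nonzero(ins))
        h["insertions"] += int(np.count_nonzero(ins_mask[anchors[ins]]))
    return HomopolymerAttribution(
        h["mismatches"], h["insertions"], h["deletions"],
        a["mismatches"], a["insertions"], a["deletions"],
    )
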