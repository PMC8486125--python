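"""Error decomposition, substitution bias, genome-window and GC analyses.

Error rates are ratios of differences (mismatches, insertions, deletions)
between aligned base pairs over the total alignment length; indel runs are
counted column-wise (a 3-base deletion contributes 3 deletion errors).
Because reads are profiled in sequencing orientation, a substitution is
always labelled (oriented genome base -> read base).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._seq import GAP
from .align_io import AlignedRead, ReferenceGenome

__all__ = [
    "ErrorCounts",
    "TransitionTestResult",
    "decompose_errors",
    "pooled_errors",
    "per_read_error_table",
    "substitution_matrix",
    "relative_substitution_abundance",
    "transition_transversion_test",
    "genome_window_error",
    "error_vs_gc",
    "relative_coverage_by_gc",
    "region_error_rates",
    "read_bed",
]

_BASES = list("ACGT")


@dataclass(frozen=True)
class ErrorCounts:
    """Match/mismatch/insertion/deletion tallies over alignment columns."""

    matches: int
    mismatches: int
    insertions: int
    deletions: int

    @property
    def alignment_length(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    def _rate(self, n: int) -> float:
        if self.alignment_length == 0:
            raise ValueError("error rates undefined for an empty alignment")
        return n / self.alignment_length

    @property
    def mismatch_rate(self) -> float:
        return self._rate(self.mismatches)

    @property
    def insertion_rate(self) -> float:
        return self._rate(self.insertions)

    @property
    def deletion_rate(self) -> float:
        return self._rate(self.deletions)

    @property
    def global_error_rate(self) -> float:
        return self._rate(self.mismatches + self.insertions + self.deletions)

    def __add__(self, other: "ErrorCounts") -> "ErrorCounts":
        return ErrorCounts(
            self.matches + other.matches,
            self.mismatches + other.mismatches,
            self.insertions + other.insertions,
            self.deletions + other.deletions,
        )

    def as_dict(self) -> dict:
        return {
            "matches": self.matches,
            "mismatches": self.mismatches,
            "insertions": self.insertions,
            "deletions": self.deletions,
            "alignment_length": self.alignment_length,
            "mismatch_rate": self.mismatch_rate,
            "insertion_rate": self.insertion_rate,
            "deletion_rate": self.deletion_rate,
            "global_error_rate": self.global_error_rate,
        }


def decompose_errors(read: AlignedRead) -> ErrorCounts:
    """Classify every alignment column of a read.

    Columns pairing an N with a base count in the alignment length but are
    not errors (no defined base identity), so they land with the matches.
    """
    n = read.n_columns
    if n == 0:
        raise ValueError(f"read {read.read_id}: empty alignment")
    mm = int(np.count_nonzero(read.mismatch_mask))
    ins = int(np.count_nonzero(read.insertion_mask))
    dele = int(np.count_nonzero(read.deletion_mask))
    return ErrorCounts(n - mm - ins - dele, mm, ins, dele)


def pooled_errors(reads: Sequence[AlignedRead]) -> ErrorCounts:
    """Column-pooled counts over many reads (Table-2-style global rates)."""
    total = ErrorCounts(0, 0, 0, 0)
    for r in reads:
        total = total + decompose_errors(r)
    return total


def per_read_error_table(reads: Sequence[AlignedRead]) -> pd.DataFrame:
    rows = []
    for r in reads:
        c = decompose_errors(r)
        rows.append(
            {
                "read_id": r.read_id,
                "orientation": r.orientation,
                "read_length": r.read_length,
                "clip_left": r.clip_left,
                "clip_right": r.clip_right,
                "matches": c.matches,
                "mismatches": c.mismatches,
                "insertions": c.insertions,
                "deletions": c.deletions,
                "global_error_rate": c.global_error_rate,
                "gc_percent": r.read_gc_percent,
                "mean_quality": r.mean_quality(),
            }
        )
    return pd.DataFrame(rows)


def _empty_matrix() -> pd.DataFrame:
    return pd.DataFrame(
        np.zeros((4, 4), dtype=np.int64), index=_BASES, columns=_BASES
    )


def substitution_matrix(
    reads: Sequence[AlignedRead],
    modification_calls: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Tally mismatch columns by (oriented genome base, read base).

    Returns a dict of 4x4 count frames (rows: genome base, columns: read
    base; the diagonal stays zero).  Stratum ``"all"`` is always present.
    When ``modification_calls`` is given — columns ``read_id``, ``read_pos``
    (0-based position in the original read, sequencing orientation),
    ``mod_type`` — mismatches whose read base carries a call are tallied
    under ``"modified:<type>"`` and the rest under ``"unmodified"``.
    """
    strata: dict[str, np.ndarray] = {"all": np.zeros((4, 4), dtype=np.int64)}
    calls_by_read: dict[str, dict[int, str]] = {}
    if modification_calls is not None and len(modification_calls):
        read_lengths = {r.read_id: r.read_length for r in reads}
        for rec in modification_calls.itertuples(index=False):
            rl = read_lengths.get(rec.read_id)
            if rl is not None and not (0 <= rec.read_pos < rl):
                raise ValueError(
                    f"modification call for read {rec.read_id!r} addresses "
                    f"position {rec.read_pos} beyond read length {rl}"
                )
            calls_by_read.setdefault(rec.read_id, {})[int(rec.read_pos)] = str(
                rec.mod_type
            )
        strata["unmodified"] = np.zeros((4, 4), dtype=np.int64)

    for r in reads:
        mm = r.mismatch_mask
        if not mm.any():
            continue
        refs = r.ref_codes[mm]
        obs = r.read_codes[mm]
        np.add.at(strata["all"], (refs, obs), 1)
        if modification_calls is None:
            continue
        calls = calls_by_read.get(r.read_id, {})
        read_idx = np.cumsum(r.read_codes != GAP) - 1
        positions = r.clip_left + read_idx[mm]
        for ref_b, read_b, pos in zip(refs, obs, positions):
            mod = calls.get(int(pos))
            key = f"modified:{mod}" if mod is not None else "unmodified"
            strata.setdefault(key, np.zeros((4, 4), dtype=np.int64))[
                ref_b, read_b
            ] += 1

    return {
        k: pd.DataFrame(v, index=_BASES, columns=_BASES) for k, v in strata.items()
    }


def relative_substitution_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Off-diagonal relative abundances (sums to 1 for a non-empty stratum)."""
    total = matrix.values.sum()
    if total == 0:
        return matrix.astype(float)
    return matrix / total


@dataclass
class TransitionTestResult:
    comparison: str
    statistic: float | None
    pvalue: float | None
    n_reads: int
    flagged: bool = False
    note: str = ""


_AG = {(0, 2), (2, 0)}
_CT = {(1, 3), (3, 1)}


def transition_transversion_test(
    reads: Sequence[AlignedRead],
) -> list[TransitionTestResult]:
    """Welch two-sample t-tests of transition vs transversion substitution
    frequency, with the read as the sampling unit.

    For each read carrying at least one substitution, the mean per-pair
    A<->G (resp. C<->T) fraction of its substitutions (2 substitution
    pairs) is compared against the mean per-pair transversion fraction
    (8 pairs); per-pair normalisation makes pair-uniform substitution the
    null of the test.
    """
    f_ag, f_ct, f_tv = [], [], []
    for r in reads:
        mm = r.mismatch_mask
        n = int(np.count_nonzero(mm))
        if n == 0:
            continue
        pairs = list(zip(r.ref_codes[mm].tolist(), r.read_codes[mm].tolist()))
        n_ag = sum(p in _AG for p in pairs)
        n_ct = sum(p in _CT for p in pairs)
        n_tv = n - n_ag - n_ct
        f_ag.append(n_ag / (2 * n))
        f_ct.append(n_ct / (2 * n))
        f_tv.append(n_tv / (8 * n))
    n_reads = len(f_tv)
    if n_reads < 2:
        note = "fewer than 2 reads with substitutions; no test performed"
        return [
            TransitionTestResult("A-G vs transversions", None, None, n_reads, True, note),
            TransitionTestResult("C-T vs transversions", None, None, n_reads, True, note),
        ]
    out = []
    for label, vals in (("A-G vs transversions", f_ag), ("C-T vs transversions", f_ct)):
        stat, p = sps.ttest_ind(vals, f_tv, equal_var=False)
        out.append(TransitionTestResult(label, float(stat), float(p), n_reads))
    return out


def _per_position_counts(
    reads: Sequence[AlignedRead], genome_length: int
) -> dict[str, np.ndarray]:
    """Per-forward-position tallies of anchored columns and error types."""
    cols = np.zeros(genome_length, dtype=np.int64)
    mm = np.zeros(genome_length, dtype=np.int64)
    ins = np.zeros(genome_length, dtype=np.int64)
    dele = np.zeros(genome_length, dtype=np.int64)
    for r in reads:
        lo, hi = r.forward_interval(genome_length)
        cols[lo:hi] += 1  # one ref-consuming column per covered position
        fa = r.forward_anchors(genome_length)
        im = r.insertion_mask
        if im.any():
            np.add.at(cols, fa[im], 1)
            np.add.at(ins, fa[im], 1)
        m = r.mismatch_mask
        if m.any():
            np.add.at(mm, fa[m], 1)
        d = r.deletion_mask
        if d.any():
            np.add.at(dele, fa[d], 1)
    return {"columns": cols, "mismatch": mm, "insertion": ins, "deletion": dele}


def genome_window_error(
    reads: Sequence[AlignedRead],
    reference: ReferenceGenome,
    window_fraction: float = 0.01,
) -> pd.DataFrame:
    """Per-type error rates in windows tiling the forward genome.

    The window size is ``ceil(window_fraction * genome length)``; every error
    is anchored to a forward-genome position (insertions at the preceding
    reference base).  Windows without any anchored column get NaN rates.
    """
    L = reference.length
    w = max(1, int(np.ceil(window_fraction * L)))
    counts = _per_position_counts(reads, L)
    n_win = int(np.ceil(L / w))
    pad = n_win * w - L

    def winsum(a: np.ndarray) -> np.ndarray:
        return np.pad(a, (0, pad)).reshape(n_win, w).sum(axis=1)

    cols = winsum(counts["columns"]).astype(float)
    out = pd.DataFrame(
        {
            "window_start": np.arange(n_win) * w,
            "window_end": np.minimum(np.arange(1, n_win + 1) * w, L),
            "columns": cols.astype(np.int64),
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        for key in ("mismatch", "insertion", "deletion"):
            out[f"{key}_rate"] = np.where(cols > 0, winsum(counts[key]) / cols, np.nan)
    return out


def error_vs_gc(
    reads: Sequence[AlignedRead], min_support: int = 1
) -> pd.DataFrame:
    """Mean per-read error rates binned by integer read GC percent.

    GC is computed on the aligned read bases (N excluded); bins supported by
    fewer than ``min_support`` reads are suppressed.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    tbl = per_read_error_table(reads)
    if tbl.empty:
        return pd.DataFrame(
            columns=["gc_percent", "mismatch", "insertion", "deletion", "global", "n_reads"]
        )
    tbl = tbl.dropna(subset=["gc_percent"]).copy()
    tbl["gc_bin"] = tbl["gc_percent"].round().astype(int)
    tbl["mismatch"] = tbl["mismatches"] / (
        tbl[["matches", "mismatches", "insertions", "deletions"]].sum(axis=1)
    )
    tbl["insertion"] = tbl["insertions"] / (
        tbl[["matches", "mismatches", "insertions", "deletions"]].sum(axis=1)
    )
    tbl["deletion"] = tbl["deletions"] / (
        tbl[["matches", "mismatches", "insertions", "deletions"]].sum(axis=1)
    )
    g = (
        tbl.groupby("gc_bin")
        .agg(
            mismatch=("mismatch", "mean"),
            insertion=("insertion", "mean"),
            deletion=("deletion", "mean"),
            **{"global": ("global_error_rate", "mean")},
            n_reads=("read_id", "size"),
        )
        .reset_index()
        .rename(columns={"gc_bin": "gc_percent"})
    )
    return g[g["n_reads"] >= min_support].reset_index(drop=True)


def relative_coverage_by_gc(
    reads: Sequence[AlignedRead],
    reference: ReferenceGenome,
    window: int = 100,
    min_windows: int = 1000,
) -> pd.DataFrame:
    """Relative depth of coverage binned by integer window GC percent.

    The genome is tiled into non-overlapping windows; window depth is the
    mean per-base aligned read-base depth, normalised by the genome-wide
    mean depth (1.0 means no coverage bias).  Bins with fewer than
    ``min_windows`` windows are suppressed.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = reference.length
    depth = np.zeros(L, dtype=np.int64)
    for r in reads:
        lo, hi = r.forward_interval(L)
        depth[lo:hi] += 1
        d = r.deletion_mask
        if d.any():
            np.subtract.at(depth, r.forward_anchors(L)[d], 1)
    mean_depth = depth.mean()
    if mean_depth == 0:
        raise ValueError("no aligned coverage; relative coverage undefined")
    n_win = L // window
    if n_win == 0:
        raise ValueError("genome shorter than one window")
    trimmed = depth[: n_win * window].reshape(n_win, window)
    win_depth = trimmed.mean(axis=1) / mean_depth
    codes = reference.codes[: n_win * window].reshape(n_win, window)
    gc = ((codes == 1) | (codes == 2)).sum(axis=1)
    acgt = (codes < 4).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        win_gc = np.where(acgt > 0, np.round(100.0 * gc / acgt), np.nan)
    df = pd.DataFrame({"gc_percent": win_gc, "relative_coverage": win_depth}).dropna()
    df["gc_percent"] = df["gc_percent"].astype(int)
    g = (
        df.groupby("gc_percent")
        .agg(relative_coverage=("relative_coverage", "mean"), n_windows=("relative_coverage", "size"))
        .reset_index()
    )
    return g[g["n_windows"] >= min_windows].reset_index(drop=True)


def read_bed(path: str | Path) -> list[tuple[int, int]]:
    """Parse 0-based half-open intervals from a BED file; malformed intervals
    are rejected with their line number."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED fields")
            start, end = int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: malformed interval {start}-{end}")
            intervals.append((start, end))
    return intervals


def region_error_rates(
    reads: Sequence[AlignedRead],
    regions: Sequence[tuple[int, int]],
    reference: ReferenceGenome,
) -> ErrorCounts:
    """Pool all columns whose forward-genome anchor lies in any of the given
    0-based half-open intervals and decompose them."""
    L = reference.length
    mask = np.zeros(L, dtype=bool)
    for start, end in regions:
        if end <= start:
            raise ValueError(f"malformed interval {start}-{end}")
        mask[max(0, start) : min(L, end)] = True
    mm = ins = dele = cols = 0
    for r in reads:
        inside = mask[r.forward_anchors(L)]
        cols += int(np.count_nonzero(inside))
        mm += int(np.count_nonzero(r.mismatch_mask & inside))
        ins += int(np.count_nonzero(r.insertion_mask & inside))
        dele += int(np.count_nonzero(r.deletion_mask & inside))
    return ErrorCounts(cols - mm - ins - dele, mm, ins, dele)
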