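"""Translocation speed from per-reference-base event counts, and
error-vs-speed profiles.

The module consumes the event table a signal resquiggler emits (one row per
read and reference base with the number of raw-current samples assigned to
that base); raw-signal segmentation itself is out of scope.  With a sampling
rate R and E samples over N bases, the translocation speed is S = N/E * R;
the nominal value for current chemistry is about 450 bases per second.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .align_io import AlignedRead

__all__ = [
    "EventTable",
    "translocation_speed",
    "load_event_table",
    "error_vs_speed",
]

DEFAULT_SAMPLING_RATE = 4000.0


def translocation_speed(
    n_bases: float, n_samples: float, sampling_rate: float = DEFAULT_SAMPLING_RATE
):
    """S = N/E * R in bases per second."""
    n_bases = np.asarray(n_bases, dtype=float)
    n_samples = np.asarray(n_samples, dtype=float)
    if np.any(n_samples <= 0):
        raise ValueError("sample count must be positive")
    if np.any(n_bases < 1):
        raise ValueError("need at least one base")
    if sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    s = n_bases / n_samples * sampling_rate
    return float(s) if s.ndim == 0 else s


@dataclass
class EventTable:
    """Per-(read, forward reference base) raw-signal sample counts."""

    table: pd.DataFrame  # columns: read_id, ref_pos, n_samples
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        required = {"read_id", "ref_pos", "n_samples"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        if (self.table["n_samples"] < 1).any():
            raise ValueError("event sample counts must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")

    def by_read(self) -> dict[str, pd.DataFrame]:
        return {rid: g for rid, g in self.table.groupby("read_id")}


def load_event_table(
    path: str | Path, sampling_rate: float = DEFAULT_SAMPLING_RATE
) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(df, sampling_rate)


def error_vs_speed(
    reads: Sequence[AlignedRead],
    events: EventTable,
    genome_length: int,
    window: int = 25,
    speed_bin_width: float = 50.0,
    min_support: int = 1,
) -> pd.DataFrame:
    """Per-type error rates binned by local translocation speed.

    Each read's reference span is tiled into ``window``-base windows
    (reference-anchored: deleted bases count toward N even though they carry
    no read base); a window's speed comes from its summed sample counts, its
    error rates from the read's columns anchored inside it.  Windows lacking
    full event coverage are skipped.
    """
    by_read = events.by_read()
    speeds, mm_r, ins_r, del_r = [], [], [], []
    for read in reads:
        ev = by_read.get(read.read_id)
        if ev is None:
            continue
        lo, hi = read.forward_interval(genome_length)
        span = hi - lo
        if span < window:
            continue
        samples = np.zeros(span, dtype=np.int64)
        pos = ev["ref_pos"].to_numpy(np.int64) - lo
        ok = (pos >= 0) & (pos < span)
        samples[pos[ok]] = ev["n_samples"].to_numpy(np.int64)[ok]

        fa = read.forward_anchors(genome_length) - lo
        cols = np.zeros(span, dtype=np.int64)
        mm = np.zeros(span, dtype=np.int64)
        ins = np.zeros(span, dtype=np.int64)
        dele = np.zeros(span, dtype=np.int64)
        np.add.at(cols, fa, 1)
        np.add.at(mm, fa[read.mismatch_mask], 1)
        np.add.at(ins, fa[read.insertion_mask], 1)
        np.add.at(dele, fa[read.deletion_mask], 1)

        n_win = span // window
        shape = (n_win, window)
        w_samples = samples[: n_win * window].reshape(shape).sum(axis=1)
        covered = (samples[: n_win * window].reshape(shape) > 0).all(axis=1)
        if not covered.any():
            continue
        w_cols = cols[: n_win * window].reshape(shape).sum(axis=1).astype(float)
        good = covered & (w_cols > 0)
        if not good.any():
            continue
        speeds.append(
            translocation_speed(window, w_samples[good], events.sampling_rate)
        )
        mm_r.append(mm[: n_win * window].reshape(shape).sum(axis=1)[good] / w_cols[good])
        ins_r.append(ins[: n_win * window].reshape(shape).sum(axis=1)[good] / w_cols[good])
        del_r.append(dele[: n_win * window].reshape(shape).sum(axis=1)[good] / w_cols[good])

    if not speeds:
        return pd.DataFrame(
            columns=["speed", "mismatch", "insertion", "deletion", "global", "support"]
        )
    speed = np.concatenate(speeds)
    df = pd.DataFrame(
        {
            "bin": np.floor(speed / speed_bin_width) * speed_bin_width
            + speed_bin_width / 2,
            "mismatch": np.concatenate(mm_r),
            "insertion": np.concatenate(ins_r),
            "deletion": np.concatenate(del_r),
        }
    )
    df["global"] = df["mismatch"] + df["insertion"] + df["deletion"]
    g = (
        df.groupby("bin")
        .agg(
            mismatch=("mismatch", "mean"),
            insertion=("insertion", "mean"),
            deletion=("deletion", "mean"),
            **{"global": ("global", "mean")},
            support=("mismatch", "size"),
        )
        .reset_index()
        .rename(columns={"bin": "speed"})
    )
    return g[g["support"] >= min_support].reset_index(drop=True)
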