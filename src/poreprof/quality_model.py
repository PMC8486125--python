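"""Phred quality handling, quality-vs-error calibration and read retention.

Basecaller quality scores are Phred-encoded (Q = -10*log10(P)) but are not
guaranteed to be calibrated; this module measures the observed error rate as
a function of the reported quality on sliding read windows, fits the
quadratic trend on the percent scale, and quantifies the threshold/retention
trade-off when filtering reads by mean quality.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import GAP
from .align_io import AlignedRead

__all__ = [
    "phred_to_error_probability",
    "error_probability_to_phred",
    "QualityErrorModel",
    "window_quality_error",
    "fit_quality_error_model",
    "read_retention_by_threshold",
    "retention_tradeoff",
]


def phred_to_error_probability(q):
    """P = 10**(-Q/10).  Q must be non-negative."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("Phred scores must be non-negative")
    p = 10.0 ** (-q / 10.0)
    return float(p) if p.ndim == 0 else p


def error_probability_to_phred(p):
    """Inverse map; P = 0 is rejected (infinite quality)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("error probability must be in (0, 1]")
    q = -10.0 * np.log10(p)
    return float(q) if q.ndim == 0 else q


@dataclass
class QualityErrorModel:
    """E = a*Q^2 + b*Q + c with E in percent, fitted over [q_lo, q_hi]."""

    a: float
    b: float
    c: float
    r_squared: float
    q_lo: float
    q_hi: float

    def predict_percent(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return self.a * q**2 + self.b * q + self.c

    def to_json(self) -> str:
        return json.dumps(
            {
                "a": self.a,
                "b": self.b,
                "c": self.c,
                "r_squared": self.r_squared,
                "fit_range": [self.q_lo, self.q_hi],
            },
            sort_keys=True,
        )


def _read_windows(
    read: AlignedRead, window: int, stride: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-window (mean quality, error rate) for one read.

    Windows span ``window`` consecutive read bases; deletion columns strictly
    between the window's first and last read base contribute to its error
    count and alignment length but carry no quality.
    """
    read_mask = read.read_codes != GAP
    n_rb = int(read_mask.sum())
    if n_rb == 0:
        return None
    qv = read.quals[read_mask].astype(float)
    if np.any(qv < 0):
        return None  # no quality information
    col_of_rb = np.nonzero(read_mask)[0]
    err = read.error_mask.astype(np.int64)
    cum_err = np.concatenate(([0], np.cumsum(err)))
    cum_q = np.concatenate(([0.0], np.cumsum(qv)))

    if n_rb <= window:
        starts = np.array([0])
        w = n_rb
    else:
        starts = np.arange(0, n_rb - window + 1, stride)
        w = window
    c0 = col_of_rb[starts]
    c1 = col_of_rb[starts + w - 1] + 1
    n_cols = (c1 - c0).astype(float)
    n_err = cum_err[c1] - cum_err[c0]
    mean_q = (cum_q[starts + w] - cum_q[starts]) / w
    return mean_q, n_err / n_cols


def window_quality_error(
    reads: Sequence[AlignedRead],
    window: int = 100,
    stride: int = 25,
) -> pd.DataFrame:
    """Observed error rate vs mean reported quality on sliding read windows.

    Mean quality is the arithmetic mean of per-base Phred values, rounded to
    the first decimal; windows are aggregated per rounded quality with their
    support.  A stride of 1 recovers full base-by-base sliding; the default
    of 25 trades resolution for runtime without materially changing bin
    means.  Reads shorter than the window contribute one whole-read window.
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    qs, rs = [], []
    for r in reads:
        out = _read_windows(r, window, stride)
        if out is not None:
            qs.append(out[0])
            rs.append(out[1])
    if not qs:
        return pd.DataFrame(columns=["quality", "error_rate", "support", "sd"])
    q = np.round(np.concatenate(qs), 1)
    rate = np.concatenate(rs)
    df = pd.DataFrame({"quality": q, "error_rate": rate})
    g = (
        df.groupby("quality")
        .agg(error_rate=("error_rate", "mean"), support=("error_rate", "size"), sd=("error_rate", "std"))
        .reset_index()
    )
    g["sd"] = g["sd"].fillna(0.0)
    return g


def fit_quality_error_model(
    points: pd.DataFrame, fit_range: tuple[float, float] = (7.0, 30.0)
) -> QualityErrorModel:
    """Weighted least-squares quadratic fit of error percent on quality.

    ``points`` is the frame produced by :func:`window_quality_error`;
    weights are the per-point supports.  At least three distinct quality
    values inside the fit range are required.
    """
    q_lo, q_hi = fit_range
    sel = points[(points["quality"] >= q_lo) & (points["quality"] <= q_hi)]
    if sel["quality"].nunique() < 3:
        raise ValueError(
            f"need >= 3 distinct quality values in [{q_lo}, {q_hi}], "
            f"got {sel['quality'].nunique()}"
        )
    q = sel["quality"].to_numpy(float)
    y = 100.0 * sel["error_rate"].to_numpy(float)
    w = sel["support"].to_numpy(float)
    a, b, c = np.polyfit(q, y, 2, w=np.sqrt(w))
    pred = a * q**2 + b * q + c
    ybar = np.average(y, weights=w)
    ss_res = np.sum(w * (y - pred) ** 2)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return QualityErrorModel(float(a), float(b), float(c), float(r2), q_lo, q_hi)


def read_retention_by_threshold(
    reads: Sequence[AlignedRead],
    thresholds: Sequence[float] = (7, 8, 9, 10, 11, 12),
    quality_mode: str = "arithmetic",
) -> pd.DataFrame:
    """Reads kept and their mean error when filtering by mean read quality.

    ``reads_kept`` is reported relative to the lowest threshold.  The kept
    fraction is non-increasing in the threshold by construction.
    """
    thresholds = sorted(thresholds)
    mq = np.array([r.mean_quality(quality_mode) for r in reads])
    err = np.array([r.global_error_rate for r in reads])
    base = int(np.count_nonzero(mq >= thresholds[0]))
    rows = []
    for t in thresholds:
        keep = mq >= t
        n = int(np.count_nonzero(keep))
        rows.append(
            {
                "threshold": t,
                "n_kept": n,
                "reads_kept": n / base if base else float("nan"),
                "mean_error": float(err[keep].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class RetentionTradeoff:
    """Loss pair between two quality thresholds: read loss is the drop in
    read count relative to the lower threshold; error loss is the simple
    difference in mean error rates."""

    t_low: float
    t_high: float
    read_loss: float
    error_loss: float


def retention_tradeoff(
    reads: Sequence[AlignedRead], t_low: float = 7.0, t_high: float = 10.0
) -> RetentionTradeoff:
    tbl = read_retention_by_threshold(reads, [t_low, t_high])
    n_lo, n_hi = tbl["n_kept"].tolist()
    e_lo, e_hi = tbl["mean_error"].tolist()
    read_loss = (n_lo - n_hi) / n_lo if n_lo else float("nan")
    return RetentionTradeoff(t_low, t_high, read_loss, e_lo - e_hi)
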