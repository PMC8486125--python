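"""End-to-end run orchestration: configuration, stage execution, reports.

Every analysis stage writes deterministic TSV/JSON artifacts into the output
directory; a run summary (global rates, homopolymer attribution, perfect
k-mer statistics, retention) lands in ``summary.json``.  Timing and record
counts go to the logger, never into the artifacts, so identical inputs
reproduce identical report bytes.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import error_profile as ep
from . import kmer_analysis as ka
from . import low_complexity as lc
from . import quality_model as qm
from . import signal_analysis as sa
from .align_io import RunBundle, load_run

logger = logging.getLogger(__name__)

ALL_STAGES = ("profile", "gc", "quality", "repeats", "kmers", "signal", "regions")

_FLOAT = "%.6g"


@dataclass
class RunConfig:
    """Paths, analysis toggles and parameters for one pipeline run."""

    reference: str = ""
    forward_sam: str = ""
    reverse_sam: str = ""
    out_dir: str = "poreprof_out"
    bed: str | None = None
    mod_calls: str | None = None
    events: str | None = None
    species: str = ""
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))

    max_clip_fraction: float = 0.5
    min_qscore: float = 10.0
    window_fraction: float = 0.01
    quality_window: int = 100
    quality_stride: int = 25
    fit_q_lo: float = 7.0
    fit_q_hi: float = 30.0
    retention_thresholds: list[float] = field(
        default_factory=lambda: [7, 8, 9, 10, 11, 12]
    )
    coverage_window: int = 100
    min_coverage_windows: int = 1000
    gc_min_support: int = 10
    kmer_k: int = 5
    kmer_top: int = 10
    automaton_min_weight: int = 4
    repeat_min_count: int = 1
    signal_window: int = 25
    speed_bin_width: float = 50.0
    seed_confidences: list[float] = field(default_factory=lambda: [0.95, 0.99])

    def validate(self) -> None:
        for name in ("reference", "forward_sam", "reverse_sam"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name}: missing input file {p!r}")
        for name in ("bed", "mod_calls", "events"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: missing input file {p!r}")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if not 0 < self.max_clip_fraction <= 1:
            raise ValueError("max_clip_fraction must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _write(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT)


def _stage_profile(cfg, bundle, reads, out, summary):
    pooled = ep.pooled_errors(reads)
    summary["global"] = {
        k: (round(v, 10) if isinstance(v, float) else v)
        for k, v in pooled.as_dict().items()
    }
    summary["global"]["error_rate_percent"] = round(
        100.0 * pooled.global_error_rate, 6
    )
    _write(ep.per_read_error_table(reads), out / "per_read_errors.tsv")

    mod = None
    if cfg.mod_calls:
        import pandas as pd

        mod = pd.read_csv(cfg.mod_calls, sep="\t")
    mats = ep.substitution_matrix(reads, mod)
    rows = []
    for stratum, mat in sorted(mats.items()):
        rel = ep.relative_substitution_abundance(mat)
        for ref_b in mat.index:
            for read_b in mat.columns:
                if ref_b == read_b:
                    continue
                rows.append(
                    {
                        "stratum": stratum,
                        "ref_base": ref_b,
                        "read_base": read_b,
                        "count": int(mat.loc[ref_b, read_b]),
                        "relative": float(rel.loc[ref_b, read_b]),
                    }
                )
    import pandas as pd

    _write(pd.DataFrame(rows), out / "substitution_matrix.tsv")

    tests = ep.transition_transversion_test(reads)
    summary["transition_tests"] = [
        {
            "comparison": t.comparison,
            "statistic": t.statistic,
            "pvalue": t.pvalue,
            "n_reads": t.n_reads,
            "flagged": t.flagged,
        }
        for t in tests
    ]
    _write(
        ep.genome_window_error(reads, bundle.reference, cfg.window_fraction),
        out / "window_errors.tsv",
    )


def _stage_gc(cfg, bundle, reads, out, summary):
    _write(ep.error_vs_gc(reads, cfg.gc_min_support), out / "read_gc_error.tsv")
    try:
        cov = ep.relative_coverage_by_gc(
            reads, bundle.reference, cfg.coverage_window, cfg.min_coverage_windows
        )
        _write(cov, out / "gc_relative_coverage.tsv")
    except ValueError as exc:
        logger.warning("relative coverage skipped: %s", exc)


def _stage_quality(cfg, bundle, reads, out, summary):
    points = qm.window_quality_error(reads, cfg.quality_window, cfg.quality_stride)
    _write(points, out / "quality_error_points.tsv")
    try:
        model = qm.fit_quality_error_model(points, (cfg.fit_q_lo, cfg.fit_q_hi))
        (out / "quality_model.json").write_text(model.to_json() + "\n")
        summary["quality_model"] = json.loads(model.to_json())
    except ValueError as exc:
        logger.warning("quality model fit skipped: %s", exc)


def _stage_repeats(cfg, bundle, reads, out, summary):
    ref = bundle.reference
    for kind in lc.KINDS:
        _write(
            lc.repeat_length_distribution(ref, kind),
            out / f"{kind}_length_distribution.tsv",
        )
    hp = lc.assess_repeats(reads, ref, "homopolymer")
    _write(
        lc.repeat_accuracy_by_length(hp, cfg.repeat_min_count, stratify_by="motif"),
        out / "homopolymer_accuracy_by_base.tsv",
    )
    _write(
        lc.repeat_accuracy_by_length(hp, cfg.repeat_min_count),
        out / "homopolymer_accuracy.tsv",
    )
    _write(lc.length_deviation_profile(hp), out / "homopolymer_deviation.tsv")

    het = lc.assess_repeats(reads, ref, "heteropolymer")
    _write(
        lc.repeat_accuracy_by_length(het, cfg.repeat_min_count),
        out / "heteropolymer_accuracy.tsv",
    )
    _write(lc.length_deviation_profile(het), out / "heteropolymer_deviation.tsv")

    tri = lc.assess_repeats(reads, ref, "trinucleotide")
    if not tri.empty:
        tri = tri.assign(group=tri["motif"].map(lc.classify_trinucleotide))
        _write(
            lc.repeat_accuracy_by_length(tri, cfg.repeat_min_count, stratify_by="group"),
            out / "trinucleotide_accuracy.tsv",
        )
    attribution = lc.attribute_errors_to_homopolymers(reads, ref)
    attribution.to_frame().to_csv(
        out / "homopolymer_attribution.tsv", sep="\t", float_format=_FLOAT
    )
    summary["homopolymer_attribution"] = {
        "ratio_percent": {
            t: attribution.ratio_percent(t)
            for t in ("mismatches", "insertions", "deletions", "global")
        }
    }


def _stage_kmers(cfg, bundle, reads, out, summary):
    lengths = ka.perfect_kmer_lengths(reads)
    curve, stats = ka.perfect_kmer_distribution(lengths)
    _write(curve, out / "perfect_kmer_curve.tsv")
    seeds = {
        f"{c:g}": ka.seed_size_at_confidence(lengths, c)
        for c in cfg.seed_confidences
    }
    summary["perfect_kmers"] = {
        "mode": stats.mode,
        "mean": stats.mean,
        "median": stats.median,
        "sd": stats.sd,
        "scp_mode": stats.scp_mode,
        "scp_median": stats.scp_median,
        "seed_size_at_confidence": seeds,
        "n_reads": stats.n,
    }
    import pandas as pd

    rows = []
    tables = []
    for error_type in ka.ERROR_TYPES:
        for side in ka.SIDES:
            t = ka.harmful_kmers(
                reads,
                error_type,
                side,
                k=cfg.kmer_k,
                top=cfg.kmer_top,
                exclude_homopolymeric=True,
                reference=bundle.reference,
                gc_class=bundle.gc_class,
            )
            tables.append(t)
            for row in t.entries.itertuples(index=False):
                rows.append(
                    {
                        "error_type": error_type,
                        "side": side,
                        "kmer": row.kmer,
                        "count": int(getattr(row, bundle.gc_class)),
                    }
                )
    _write(pd.DataFrame(rows), out / "harmful_kmers.tsv")
    deletion_before = next(
        t for t in tables if t.error_type == "deletion" and t.side == "before"
    )
    if not deletion_before.entries.empty:
        auto = ka.build_automaton(deletion_before)
        (out / "harmful_kmer_automaton.json").write_text(auto.to_json() + "\n")
        pruned = auto.prune(cfg.automaton_min_weight)
        (out / "harmful_kmer_automaton.dot").write_text(pruned.to_dot() + "\n")
        pcm = ka.position_count_matrix(deletion_before)
        pcm.to_csv(out / "harmful_kmer_logo_counts.tsv", sep="\t")


def _stage_signal(cfg, bundle, reads, out, summary):
    if not cfg.events:
        logger.info("no event table given; signal stage skipped")
        return
    events = sa.load_event_table(cfg.events)
    prof = sa.error_vs_speed(
        reads,
        events,
        bundle.reference.length,
        window=cfg.signal_window,
        speed_bin_width=cfg.speed_bin_width,
    )
    _write(prof, out / "speed_error.tsv")
    if len(prof):
        summary["signal"] = {
            "modal_speed": float(prof.loc[prof["support"].idxmax(), "speed"])
        }


def _stage_regions(cfg, bundle, reads, out, summary):
    if not cfg.bed:
        return
    regions = ep.read_bed(cfg.bed)
    if not regions:
        logger.warning("empty region set; region stage skipped")
        return
    counts = ep.region_error_rates(reads, regions, bundle.reference)
    summary["region_errors"] = counts.as_dict()
    (out / "region_errors.json").write_text(
        json.dumps(counts.as_dict(), sort_keys=True) + "\n"
    )


_STAGE_FN = {
    "profile": _stage_profile,
    "gc": _stage_gc,
    "quality": _stage_quality,
    "repeats": _stage_repeats,
    "kmers": _stage_kmers,
    "signal": _stage_signal,
    "regions": _stage_regions,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Reads failing the soft-clip filter are discarded; reads below the mean
    quality threshold are excluded from analyses but kept in the retention
    report.  Per-record parse failures are logged, counted and skipped.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    bundle = load_run(
        cfg.reference,
        cfg.forward_sam,
        cfg.reverse_sam,
        species=cfg.species,
        max_clip_fraction=cfg.max_clip_fraction,
    )
    logger.info(
        "loaded %d reads (%d rejected records, %d clipped away) in %.1fs",
        len(bundle.reads),
        bundle.stats.rejected if bundle.stats else 0,
        bundle.discarded_clipped,
        time.perf_counter() - t0,
    )

    retention = qm.read_retention_by_threshold(
        bundle.reads, cfg.retention_thresholds
    )
    _write(retention, out / "retention.tsv")
    analysed = [
        r for r in bundle.reads if r.mean_quality() >= cfg.min_qscore
    ]
    summary: dict = {
        "species": cfg.species,
        "gc_class": bundle.gc_class,
        "reference_gc_percent": bundle.reference.gc_percent,
        "reference_length": bundle.reference.length,
        "reads_loaded": len(bundle.reads),
        "reads_analysed": len(analysed),
        "reads_discarded_clipped": bundle.discarded_clipped,
        "records_rejected": bundle.stats.rejected if bundle.stats else 0,
        "min_qscore": cfg.min_qscore,
    }
    if not analysed:
        logger.warning("no reads pass the quality threshold; stages skipped")
    else:
        for stage in ALL_STAGES:
            if stage not in cfg.stages:
                continue
            t1 = time.perf_counter()
            _STAGE_FN[stage](cfg, bundle, analysed, out, summary)
            logger.info("stage %s done in %.1fs", stage, time.perf_counter() - t1)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        return obj

    (out / "summary.json").write_text(
        json.dumps(_clean(summary), sort_keys=True, indent=2) + "\n"
    )
    return summary
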