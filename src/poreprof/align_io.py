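"""Reference/alignment input and per-column alignment reconstruction.

Reads are profiled in their sequencing orientation: a run is aligned twice,
once against the forward reference genome and once against its reverse
complement, with read reverse-complementing disabled in the aligner.  This
module parses both SAM/BAM files, expands each record's CIGAR into aligned
columns against the oriented genome, keeps the better of the two alignments
per read, and filters reads that are mostly soft-clipped.

Internal coordinates are 0-based, half-open.  SAM's 1-based coordinates are
handled only at the I/O boundary (by pysam).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from pyfaidx import Fasta

from . import _seq
from ._seq import GAP, N, decode, encode, gc_fraction, reverse_complement

__all__ = [
    "ReferenceGenome",
    "AlignedRead",
    "RunBundle",
    "ParseStats",
    "AlignmentParseError",
    "reverse_complement",
    "read_reference",
    "parse_alignments",
    "select_best_strand",
    "filter_softclipped",
    "load_run",
]

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"

# BAM op codes: M=0 I=1 D=2 N=3 S=4 H=5 P=6 ==7 X=8
_IS_COLUMN = np.array([1, 1, 1, 1, 0, 0, 0, 1, 1], dtype=bool)
_READ_COL = np.array([1, 1, 0, 0, 0, 0, 0, 1, 1], dtype=bool)
_REF_COL = np.array([1, 0, 1, 1, 0, 0, 0, 1, 1], dtype=bool)


class AlignmentParseError(ValueError):
    """A single alignment record could not be expanded into columns."""


@dataclass
class ReferenceGenome:
    """A reference sequence over {A,C,G,T,N}, upper-cased on construction."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        codes = encode(self.sequence)
        if np.any(codes > N):
            raise ValueError("reference may only contain A,C,G,T,N")
        self._codes = codes

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return self.length

    @property
    def gc_percent(self) -> float:
        return 100.0 * gc_fraction(self._codes)

    @property
    def gc_class(self) -> str:
        """"low" below 50% GC, else "high"."""
        return "low" if self.gc_percent < 50.0 else "high"

    def reverse_complement(self) -> "ReferenceGenome":
        return ReferenceGenome(self.name, reverse_complement(self.sequence))


@dataclass
class AlignedRead:
    """One read's expanded per-column alignment against an oriented genome.

    ``ref_codes``/``read_codes`` hold one entry per alignment column
    (insertion columns have ``ref_codes == GAP``; deletion columns have
    ``read_codes == GAP``).  ``quals`` holds the Phred quality per column,
    -1 where the column carries no read base.  ``ref_start`` is a 0-based
    offset into the *oriented* genome (forward genome, or its reverse
    complement for ``orientation == "reverse"``).
    """

    read_id: str
    orientation: str
    ref_name: str
    ref_start: int
    ref_codes: np.ndarray
    read_codes: np.ndarray
    quals: np.ndarray
    clip_left: int
    clip_right: int
    read_length: int

    @property
    def n_columns(self) -> int:
        return self.ref_codes.size

    @property
    def span(self) -> int:
        """Number of reference bases covered."""
        return int(np.count_nonzero(self.ref_codes != GAP))

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.span

    @property
    def insertion_mask(self) -> np.ndarray:
        return self.ref_codes == GAP

    @property
    def deletion_mask(self) -> np.ndarray:
        return self.read_codes == GAP

    @property
    def mismatch_mask(self) -> np.ndarray:
        """Columns where both bases are unambiguous (A,C,G,T) and differ.

        Columns pairing an N with anything are counted neither as mismatch
        nor error (no defined base identity)."""
        return (
            (self.ref_codes < 4)
            & (self.read_codes < 4)
            & (self.ref_codes != self.read_codes)
        )

    @property
    def match_mask(self) -> np.ndarray:
        """Strict matches: both bases unambiguous and equal."""
        return (self.ref_codes < 4) & (self.ref_codes == self.read_codes)

    @property
    def error_mask(self) -> np.ndarray:
        return self.mismatch_mask | self.insertion_mask | self.deletion_mask

    @property
    def global_error_rate(self) -> float:
        if self.n_columns == 0:
            raise ValueError(f"read {self.read_id}: empty alignment")
        return float(np.count_nonzero(self.error_mask)) / self.n_columns

    def anchors(self) -> np.ndarray:
        """Oriented-genome reference position anchoring each column.

        Ref-consuming columns anchor at their own position; insertion columns
        anchor at the preceding reference base (leftmost convention), clamped
        to ``ref_start`` for insertions before the first aligned base.
        """
        csum = np.cumsum(self.ref_codes != GAP)
        return np.maximum(self.ref_start - 1 + csum, self.ref_start)

    def forward_anchors(self, genome_length: int) -> np.ndarray:
        """Anchors mapped to forward-genome coordinates (p -> L-1-p for
        reads aligned against the reverse-complemented genome)."""
        a = self.anchors()
        if self.orientation == REVERSE:
            return genome_length - 1 - a
        return a

    def forward_interval(self, genome_length: int) -> tuple[int, int]:
        """Forward-genome half-open interval covered by ref-consuming columns."""
        if self.orientation == REVERSE:
            return genome_length - self.ref_end, genome_length - self.ref_start
        return self.ref_start, self.ref_end

    def aligned_read_seq(self) -> str:
        return decode(self.read_codes[self.read_codes != GAP])

    def aligned_ref_seq(self) -> str:
        return decode(self.ref_codes[self.ref_codes != GAP])

    @property
    def read_gc_percent(self) -> float:
        return 100.0 * gc_fraction(self.read_codes[self.read_codes != GAP])

    def mean_quality(self, mode: str = "arithmetic") -> float:
        """Mean per-base Phred quality of the aligned read bases.

        ``arithmetic`` averages Phred values; ``probability`` averages error
        probabilities and converts back (the convention of basecaller
        read-level scores).
        """
        q = self.quals[self.quals >= 0].astype(float)
        if q.size == 0:
            return float("nan")
        if mode == "arithmetic":
            return float(q.mean())
        if mode == "probability":
            return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))
        raise ValueError(f"unknown mean-quality mode {mode!r}")

    @property
    def clip_fraction(self) -> float:
        if self.read_length <= 0:
            raise ValueError(f"read {self.read_id}: non-positive read length")
        return (self.clip_left + self.clip_right) / self.read_length

    def columns(self) -> Iterable[tuple[str, str, int]]:
        """Iterate (ref_base, read_base, quality) per column — test/debug aid."""
        for r, d, q in zip(self.ref_codes, self.read_codes, self.quals):
            yield _seq.ALPHABET[r], _seq.ALPHABET[d], int(q)


@dataclass
class ParseStats:
    """Bookkeeping for one parsing pass."""

    parsed: int = 0
    skipped_secondary: int = 0
    skipped_unmapped: int = 0
    rejected: int = 0
    rejection_reasons: list = field(default_factory=list)


def _expand_record(
    rec: pysam.AlignedSegment, reference: ReferenceGenome, orientation: str
) -> AlignedRead:
    ct = rec.cigartuples
    if not ct:
        raise AlignmentParseError(f"{rec.query_name}: missing CIGAR")
    qseq = rec.query_sequence
    if not qseq:
        raise AlignmentParseError(f"{rec.query_name}: missing read sequence")

    soft_left = hard_left = 0
    i = 0
    while i < len(ct) and ct[i][0] in (4, 5):
        if ct[i][0] == 4:
            soft_left += ct[i][1]
        else:
            hard_left += ct[i][1]
        i += 1
    soft_right = hard_right = 0
    j = len(ct)
    while j > i and ct[j - 1][0] in (4, 5):
        if ct[j - 1][0] == 4:
            soft_right += ct[j - 1][1]
        else:
            hard_right += ct[j - 1][1]
        j -= 1
    core = ct[i:j]
    if not core:
        raise AlignmentParseError(f"{rec.query_name}: alignment is all clips")

    ops = np.fromiter((o for o, _ in core), dtype=np.int64, count=len(core))
    lens = np.fromiter((l for _, l in core), dtype=np.int64, count=len(core))
    if np.any(ops > 8) or np.any(~_IS_COLUMN[ops]):
        raise AlignmentParseError(
            f"{rec.query_name}: unsupported CIGAR op inside alignment"
        )

    col_ops = np.repeat(ops, lens)
    read_mask = _READ_COL[col_ops]
    ref_mask = _REF_COL[col_ops]
    n_cols = col_ops.size
    n_read = int(read_mask.sum())
    n_ref = int(ref_mask.sum())

    if soft_left + soft_right + n_read != len(qseq):
        raise AlignmentParseError(
            f"{rec.query_name}: CIGAR consumes {soft_left + soft_right + n_read} "
            f"read bases but sequence has {len(qseq)}"
        )
    start = rec.reference_start
    if start is None or start < 0 or start + n_ref > reference.length:
        raise AlignmentParseError(
            f"{rec.query_name}: alignment [{start}, {start}+{n_ref}) exceeds "
            f"reference of length {reference.length}"
        )

    ref_codes = np.full(n_cols, GAP, dtype=np.uint8)
    ref_codes[ref_mask] = reference.codes[start : start + n_ref]
    read_codes = np.full(n_cols, GAP, dtype=np.uint8)
    aligned_q = qseq[soft_left : len(qseq) - soft_right or None]
    read_codes[read_mask] = encode(aligned_q)

    quals = np.full(n_cols, -1, dtype=np.int16)
    qq = rec.query_qualities
    if qq is not None:
        quals[read_mask] = np.asarray(qq, dtype=np.int16)[
            soft_left : len(qseq) - soft_right or None
        ]

    return AlignedRead(
        read_id=rec.query_name,
        orientation=orientation,
        ref_name=reference.name,
        ref_start=int(start),
        ref_codes=ref_codes,
        read_codes=read_codes,
        quals=quals,
        clip_left=soft_left + hard_left,
        clip_right=soft_right + hard_right,
        read_length=len(qseq) + hard_left + hard_right,
    )


def _iter_sam_records(path: Path, reference: ReferenceGenome, stats: ParseStats):
    """Yield pysam records, skipping malformed lines in text SAM input.

    Text SAM is parsed line-by-line through ``AlignedSegment.fromstring`` so
    that a single malformed record does not abort the run; BAM goes through
    pysam's native iterator.
    """
    if str(path).endswith(".bam"):
        with pysam.AlignmentFile(str(path), "rb", check_sq=False) as fh:
            yield from fh
        return
    header = pysam.AlignmentHeader.from_references(
        [reference.name], [reference.length]
    )
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            try:
                yield pysam.AlignedSegment.fromstring(line.rstrip("\n"), header)
            except ValueError as exc:
                stats.rejected += 1
                stats.rejection_reasons.append(f"line {lineno}: {exc}")
                logger.warning("skipping malformed SAM line %d: %s", lineno, exc)


def parse_alignments(
    path: str | Path,
    reference: ReferenceGenome,
    orientation: str = FORWARD,
    stats: ParseStats | None = None,
) -> list[AlignedRead]:
    """Expand primary alignment records from a SAM/BAM file into
    :class:`AlignedRead` objects.

    ``reference`` must be the oriented genome copy the records were aligned
    against (the reverse-complemented genome for ``orientation="reverse"``).
    Secondary, supplementary and unmapped records are skipped; records whose
    CIGAR is inconsistent with the read sequence are rejected with
    diagnostics recorded in ``stats``.
    """
    if orientation not in (FORWARD, REVERSE):
        raise ValueError(f"orientation must be forward/reverse, got {orientation!r}")
    stats = stats if stats is not None else ParseStats()
    out: list[AlignedRead] = []
    for rec in _iter_sam_records(Path(path), reference, stats):
        if rec.is_unmapped:
            stats.skipped_unmapped += 1
            continue
        if rec.is_secondary or rec.is_supplementary:
            stats.skipped_secondary += 1
            continue
        try:
            out.append(_expand_record(rec, reference, orientation))
            stats.parsed += 1
        except AlignmentParseError as exc:
            stats.rejected += 1
            stats.rejection_reasons.append(str(exc))
            logger.warning("rejecting record: %s", exc)
    return out


def select_best_strand(
    forward: Sequence[AlignedRead], reverse: Sequence[AlignedRead]
) -> list[AlignedRead]:
    """Keep one alignment per read id: the one with the lower global error
    rate; ties break toward the forward orientation.  Reads present in only
    one input keep that alignment."""
    best: dict[str, AlignedRead] = {}
    for r in forward:
        cur = best.get(r.read_id)
        if cur is None or r.global_error_rate < cur.global_error_rate:
            best[r.read_id] = r
    for r in reverse:
        cur = best.get(r.read_id)
        if cur is None or r.global_error_rate < cur.global_error_rate:
            best[r.read_id] = r
    return list(best.values())


def filter_softclipped(
    reads: Sequence[AlignedRead], max_clip_fraction: float = 0.5
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Partition reads into (kept, discarded): a read is discarded iff its
    total clipped length exceeds ``max_clip_fraction`` of the original read
    length.  Hard clips count like soft clips (both are unaligned read
    sequence)."""
    kept: list[AlignedRead] = []
    discarded: list[AlignedRead] = []
    for r in reads:
        (discarded if r.clip_fraction > max_clip_fraction else kept).append(r)
    return kept, discarded


@dataclass
class RunBundle:
    """One sequencing run: a reference plus the selected best alignment per
    read, with run-level metadata."""

    reference: ReferenceGenome
    reads: list[AlignedRead]
    species: str = ""
    stats: ParseStats | None = None
    discarded_clipped: int = 0

    @property
    def gc_class(self) -> str:
        return self.reference.gc_class


def read_reference(path: str | Path) -> ReferenceGenome:
    """Read the first sequence from a FASTA file."""
    fa = Fasta(str(path), rebuild=False, build_index=True)
    names = list(fa.keys())
    if not names:
        raise ValueError(f"{path}: no sequences in FASTA")
    if len(names) > 1:
        logger.warning("%s: multiple sequences; using %r", path, names[0])
    return ReferenceGenome(names[0], str(fa[names[0]][:]))


def load_run(
    reference_fasta: str | Path,
    forward_sam: str | Path,
    reverse_sam: str | Path,
    species: str = "",
    max_clip_fraction: float = 0.5,
) -> RunBundle:
    """Load a full dual-strand run: parse both alignment files, keep the best
    strand per read, and apply the soft-clip filter."""
    reference = read_reference(reference_fasta)
    rev_ref = reference.reverse_complement()
    stats = ParseStats()
    fwd = parse_alignments(forward_sam, reference, FORWARD, stats)
    rev = parse_alignments(reverse_sam, rev_ref, REVERSE, stats)
    best = select_best_strand(fwd, rev)
    kept, discarded = filter_softclipped(best, max_clip_fraction)
    return RunBundle(
        reference=reference,
        reads=kept,
        species=species,
        stats=stats,
        discarded_clipped=len(discarded),
    )
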