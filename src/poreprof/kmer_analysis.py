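"""Perfect k-mer statistics and sequence-specific error (harmful k-mer)
mining, with a layered-automaton representation of the mined contexts.

A *perfect k-mer* is a read stretch aligned without any error; the per-read
maximum bounds the seed sizes usable by mapping algorithms.  A *harmful
k-mer* is the fixed-length read context immediately before or after an
error position, over-represented for a given error type.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _seq
from ._seq import GAP, decode, rle
from .align_io import AlignedRead, ReferenceGenome
from .low_complexity import homopolymer_intervals

__all__ = [
    "PerfectKmerStats",
    "HarmfulKmerTable",
    "HarmfulKmerAutomaton",
    "longest_perfect_kmer",
    "perfect_kmer_lengths",
    "perfect_kmer_distribution",
    "scp_mode",
    "scp_median",
    "seed_size_at_confidence",
    "harmful_kmers",
    "merge_harmful_tables",
    "position_count_matrix",
    "build_automaton",
]

ERROR_TYPES = ("mismatch", "insertion", "deletion")
SIDES = ("before", "after")


def longest_perfect_kmer(read: AlignedRead) -> int:
    """Length of the longest run of consecutive strict-match columns (no
    mismatch or indel column inside; clipped ends are never part of the
    alignment)."""
    if read.n_columns == 0:
        raise ValueError(f"read {read.read_id}: empty alignment")
    m = read.match_mask
    vals, _, lens = rle(m)
    good = lens[vals.astype(bool)]
    return int(good.max()) if good.size else 0


def perfect_kmer_lengths(reads: Sequence[AlignedRead]) -> np.ndarray:
    return np.array([longest_perfect_kmer(r) for r in reads], dtype=np.int64)


def scp_mode(mean: float, mode: float, sd: float) -> float:
    """Pearson skewness coefficient with respect to the mode."""
    if sd <= 0:
        raise ValueError("skewness undefined for zero standard deviation")
    return (mean - mode) / sd


def scp_median(mean: float, median: float, sd: float) -> float:
    """Pearson skewness coefficient with respect to the median."""
    if sd <= 0:
        raise ValueError("skewness undefined for zero standard deviation")
    return 3.0 * (mean - median) / sd


@dataclass
class PerfectKmerStats:
    """Summary of the per-read longest perfect stretch distribution.

    The mode is the most frequent binned length (default bin width 1,
    smallest value on ties); SCPs are flagged undefined (None) when the
    standard deviation is zero.
    """

    mode: float
    mean: float
    median: float
    sd: float
    scp_mode: float | None
    scp_median: float | None
    n: int


def perfect_kmer_distribution(
    lengths: np.ndarray, bin_width: int = 1
) -> tuple[pd.DataFrame, PerfectKmerStats]:
    """Cumulative read ratio vs k, and the distribution summary.

    The curve gives, for each k, the fraction of reads whose longest
    error-free stretch is at least k bases (a non-increasing sigmoid).
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("no reads")
    srt = np.sort(lengths)
    ks = np.arange(0, srt[-1] + 2)
    frac = 1.0 - np.searchsorted(srt, ks, side="left") / srt.size
    curve = pd.DataFrame({"k": ks, "fraction_reads": frac})

    binned = (lengths // bin_width) * bin_width
    vals, counts = np.unique(binned, return_counts=True)
    mode = float(vals[np.argmax(counts)])  # np.argmax takes the smallest tie
    mean = float(lengths.mean())
    median = float(np.median(lengths))
    sd = float(lengths.std(ddof=1)) if lengths.size > 1 else 0.0
    stats = PerfectKmerStats(
        mode=mode,
        mean=mean,
        median=median,
        sd=sd,
        scp_mode=scp_mode(mean, mode, sd) if sd > 0 else None,
        scp_median=scp_median(mean, median, sd) if sd > 0 else None,
        n=int(lengths.size),
    )
    return curve, stats


def seed_size_at_confidence(lengths: np.ndarray, confidence: float) -> int:
    """Largest k such that at least ``confidence`` of reads contain a
    perfect stretch of length >= k (floor convention on the empirical
    (1-confidence) quantile)."""
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("no reads")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    n = lengths.size
    m = int(np.ceil(confidence * n))  # reads that must carry the seed
    return int(np.sort(lengths)[n - m])


# ---------------------------------------------------------------------------
# harmful k-mers


@dataclass
class HarmfulKmerTable:
    """Top error-context k-mers for one (error type, side) combination.

    ``entries`` has columns ``kmer`` and one count column per GC class
    (``count`` when unclassed), sorted by total count descending.
    """

    error_type: str
    side: str
    k: int
    entries: pd.DataFrame

    @property
    def total_weight(self) -> int:
        return int(self.counts().sum())

    def counts(self) -> pd.Series:
        cols = [c for c in self.entries.columns if c != "kmer"]
        return self.entries[cols].sum(axis=1)

    def weights(self) -> dict[str, dict[str, int]]:
        """kmer -> {gc_class: count}."""
        cols = [c for c in self.entries.columns if c != "kmer"]
        return {
            row.kmer: {c: int(getattr(row, c)) for c in cols}
            for row in self.entries.itertuples(index=False)
        }


def _event_sites(read: AlignedRead, error_type: str) -> tuple[np.ndarray, np.ndarray]:
    """(first column, column-after-last) per event; consecutive indel columns
    form one context-extraction site (one gap event)."""
    if error_type == "mismatch":
        cols = np.nonzero(read.mismatch_mask)[0]
        return cols, cols + 1
    mask = read.insertion_mask if error_type == "insertion" else read.deletion_mask
    vals, starts, lens = rle(mask)
    sel = vals.astype(bool)
    return starts[sel], starts[sel] + lens[sel]


def harmful_kmers(
    reads: Sequence[AlignedRead],
    error_type: str,
    side: str,
    k: int = 5,
    top: int = 10,
    exclude_homopolymeric: bool = False,
    reference: ReferenceGenome | None = None,
    gc_class: str | None = None,
    source: str = "read",
) -> HarmfulKmerTable:
    """Count the k read bases immediately before/after each error event.

    Gap columns carry no read base and are skipped by construction; for a
    deletion the context is the flanking read bases around the gap.
    Contexts truncated by the read ends are skipped.  With
    ``exclude_homopolymeric`` (requires ``reference``), events anchored
    inside a homopolymer run (k >= 2) of the oriented genome are ignored.
    ``source="reference"`` takes the context from the aligned reference
    bases instead of the read.
    """
    if error_type not in ERROR_TYPES:
        raise ValueError(f"error_type must be one of {ERROR_TYPES}")
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if exclude_homopolymeric:
        if reference is None:
            raise ValueError("exclude_homopolymeric requires the reference")
        hp_masks = homopolymer_intervals(reference)

    packed: list[np.ndarray] = []
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    for read in reads:
        c0, c1 = _event_sites(read, error_type)
        if c0.size == 0:
            continue
        if exclude_homopolymeric:
            anchors = read.anchors()
            keep = ~hp_masks[read.orientation][anchors[c0]]
            c0, c1 = c0[keep], c1[keep]
            if c0.size == 0:
                continue
        if source == "read":
            base_mask = read.read_codes != GAP
            bases = read.read_codes[base_mask]
        else:
            base_mask = read.ref_codes != GAP
            bases = read.ref_codes[base_mask]
        before_count = np.concatenate(([0], np.cumsum(base_mask)))
        if side == "before":
            # index just past the last base strictly before the event
            p = before_count[c0]
            starts = p - k
        else:
            p = before_count[c1]
            starts = p
        # for a mismatch the error base itself is excluded from the context
        if error_type == "mismatch" and side == "after" and source == "read":
            pass  # c1 already steps past the mismatch column
        valid = (starts >= 0) & (starts + k <= bases.size)
        if not valid.any():
            continue
        win = bases[starts[valid, None] + np.arange(k)[None, :]]
        good = (win < 4).all(axis=1)
        if good.any():
            packed.append(win[good].astype(np.int64) @ weights)
    if packed:
        codes, counts = np.unique(np.concatenate(packed), return_counts=True)
        order = np.argsort(-counts, kind="stable")
        codes, counts = codes[order][:top], counts[order][:top]
        kmers = [
            "".join(_seq.ALPHABET[(c >> (2 * (k - 1 - i))) & 3] for i in range(k))
            for c in codes
        ]
    else:
        kmers, counts = [], np.array([], dtype=np.int64)
    col = gc_class if gc_class else "count"
    entries = pd.DataFrame({"kmer": kmers, col: counts.astype(np.int64)})
    return HarmfulKmerTable(error_type, side, k, entries)


def merge_harmful_tables(tables: Sequence[HarmfulKmerTable]) -> HarmfulKmerTable:
    """Merge per-dataset tables (same error type/side/k) into one table with
    per-GC-class count columns."""
    if not tables:
        raise ValueError("no tables to merge")
    k = tables[0].k
    et, side = tables[0].error_type, tables[0].side
    for t in tables:
        if t.k != k or t.error_type != et or t.side != side:
            raise ValueError("tables disagree on k/error type/side")
    frames = [t.entries.set_index("kmer") for t in tables]
    merged = pd.concat(frames, axis=1).fillna(0).astype(np.int64)
    merged = merged.T.groupby(level=0).sum().T  # sum duplicate class columns
    merged = merged.loc[merged.sum(axis=1).sort_values(ascending=False).index]
    return HarmfulKmerTable(et, side, k, merged.reset_index())


def position_count_matrix(table: HarmfulKmerTable) -> pd.DataFrame:
    """k x 4 base-count matrix of the retained k-mers, weighted by their
    counts — the numeric content of a sequence logo.  Every position column
    sums to the table's total weight."""
    if table.entries.empty:
        raise ValueError("empty harmful k-mer table")
    mat = np.zeros((table.k, 4), dtype=np.int64)
    counts = table.counts().to_numpy()
    for kmer, w in zip(table.entries["kmer"], counts):
        for i, ch in enumerate(kmer):
            mat[i, "ACGT".index(ch)] += int(w)
    return pd.DataFrame(mat, index=range(1, table.k + 1), columns=list("ACGT"))


# ---------------------------------------------------------------------------
# layered automaton


@dataclass
class AutomatonNode:
    node_id: int
    layer: int
    weight: int  # total incoming weight (total k-mer weight for the initial)
    final: bool = False


@dataclass
class AutomatonEdge:
    source: int
    target: int
    letter: str
    weights: dict[str, int] = field(default_factory=dict)

    @property
    def weight(self) -> int:
        return sum(self.weights.values())


@dataclass
class HarmfulKmerAutomaton:
    """Minimal deterministic layered letter-graph over a set of k-mers.

    States with identical residual suffix sets (right languages) are merged,
    yielding the minimal acyclic automaton over the fixed-length language;
    edges carry the number of supporting k-mers per GC class.
    """

    k: int
    nodes: list[AutomatonNode]
    edges: list[AutomatonEdge]
    initial: int

    def node(self, node_id: int) -> AutomatonNode:
        return self.nodes[node_id]

    def accepts(self, word: str) -> bool:
        if len(word) != self.k:
            return False
        out: dict[tuple[int, str], int] = {
            (e.source, e.letter): e.target for e in self.edges
        }
        state = self.initial
        for ch in word:
            nxt = out.get((state, ch))
            if nxt is None:
                return False
            state = nxt
        return self.nodes[state].final

    def layer_weight(self, layer: int) -> int:
        """Sum of edge weights entering the given layer (1..k)."""
        return sum(
            e.weight for e in self.edges if self.nodes[e.target].layer == layer
        )

    def prune(self, min_node_weight: int = 4) -> "HarmfulKmerAutomaton":
        """Copy with nodes of total weight below the threshold removed along
        with their incident edges (display/export convention; the full
        automaton is retained)."""
        keep = {
            n.node_id
            for n in self.nodes
            if n.weight >= min_node_weight or n.node_id == self.initial
        }
        edges = [e for e in self.edges if e.source in keep and e.target in keep]
        nodes = [n for n in self.nodes if n.node_id in keep]
        return HarmfulKmerAutomaton(self.k, nodes, edges, self.initial)

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "initial": self.initial,
                "nodes": [
                    {
                        "id": n.node_id,
                        "layer": n.layer,
                        "weight": n.weight,
                        "final": n.final,
                    }
                    for n in self.nodes
                ],
                "edges": [
                    {
                        "source": e.source,
                        "target": e.target,
                        "letter": e.letter,
                        "weights": e.weights,
                    }
                    for e in self.edges
                ],
            },
            sort_keys=True,
        )

    def to_dot(self) -> str:
        lines = ["digraph harmful_kmers {", "  rankdir=LR;"]
        for n in self.nodes:
            shape = "doublecircle" if n.final else "circle"
            lines.append(
                f'  n{n.node_id} [label="{n.weight}", shape={shape}];'
            )
        for e in self.edges:
            detail = "+".join(str(v) for v in e.weights.values())
            lines.append(
                f'  n{e.source} -> n{e.target} [label="{e.letter} ({detail})"];'
            )
        lines.append("}")
        return "\n".join(lines)


def build_automaton(
    tables: Sequence[HarmfulKmerTable] | HarmfulKmerTable,
) -> HarmfulKmerAutomaton:
    """Build the minimal layered automaton accepting exactly the retained
    k-mers, with per-GC-class edge weights.

    Prefixes with identical residual suffix sets share a state (suffix
    sharing); before any pruning the edge weights entering each layer sum to
    the total k-mer weight.
    """
    if isinstance(tables, HarmfulKmerTable):
        tables = [tables]
    if not tables:
        raise ValueError("no tables")
    k = tables[0].k
    weights: dict[str, dict[str, int]] = {}
    for t in tables:
        if t.k != k:
            raise ValueError(f"inconsistent k: {t.k} != {k}")
        for kmer, per_class in t.weights().items():
            acc = weights.setdefault(kmer, {})
            for cls, w in per_class.items():
                acc[cls] = acc.get(cls, 0) + w
    if not weights:
        raise ValueError("no k-mers to build from")

    kmers = sorted(weights)
    residual: dict[str, frozenset] = {}  # prefix -> residual suffix set
    prefixes_by_layer: list[list[str]] = [[] for _ in range(k + 1)]
    seen = set()
    for kmer in kmers:
        for i in range(k + 1):
            p = kmer[:i]
            if p not in seen:
                seen.add(p)
                prefixes_by_layer[i].append(p)
                residual[p] = frozenset()
    for p in seen:
        residual[p] = frozenset(km[len(p) :] for km in kmers if km.startswith(p))

    node_of_class: dict[tuple[int, frozenset], int] = {}
    nodes: list[AutomatonNode] = []

    def get_node(layer: int, res: frozenset) -> int:
        key = (layer, res)
        if key not in node_of_class:
            nid = len(nodes)
            node_of_class[key] = nid
            nodes.append(AutomatonNode(nid, layer, 0, final=(layer == k)))
        return node_of_class[key]

    initial = get_node(0, residual[""])
    edge_acc: dict[tuple[int, int, str], dict[str, int]] = {}
    for layer in range(k):
        for p in prefixes_by_layer[layer]:
            src = get_node(layer, residual[p])
            for letter in "ACGT":
                child = p + letter
                if child not in residual:
                    continue
                dst = get_node(layer + 1, residual[child])
                acc = edge_acc.setdefault((src, dst, letter), {})
                for kmer, per_class in weights.items():
                    if kmer.startswith(child):
                        for cls, w in per_class.items():
                            acc[cls] = acc.get(cls, 0) + w

    edges = [
        AutomatonEdge(s, t, letter, dict(sorted(w.items())))
        for (s, t, letter), w in sorted(edge_acc.items())
    ]
    total = sum(sum(v.values()) for v in weights.values())
    nodes[initial].weight = total
    for n in nodes:
        if n.node_id != initial:
            n.weight = sum(e.weight for e in edges if e.target == n.node_id)
    return HarmfulKmerAutomaton(k, nodes, edges, initial)
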