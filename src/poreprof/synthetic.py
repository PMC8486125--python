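"""Synthetic references, reads and alignments with exact ground truth.

The generator emulates the measured biases of nanopore sequencing so every
analysis module can be exercised offline: per-column substitution /
insertion / deletion errors with a transition bias, GC-dependent error
scaling, homopolymer length resampling, qualities tied to the per-base error
probability, optional per-base event counts with speed coupling in deleted
stretches, and the dual-strand alignment protocol (reverse-strand reads are
emitted against the reverse-complemented reference, never read
reverse-complemented).

Error placement follows the analyzable convention: background errors are
i.i.d. per column except inside homopolymer runs long enough to trigger the
length model, where that model overrides them.  With the override active,
background errors are suppressed inside every run of length >=
``hp_min_resample_length`` (plus one flanking base so boundary errors cannot
alter the rendered run), and the run's observed length is resampled with a
closed-form exactness probability (see
:func:`homopolymer_correctness_curve`), a bias toward underestimation, and a
geometric overshoot tail.  Such runs cover well under 1% of a typical
genome, so the realized genome-wide error rates stay at the nominal model
rates.  Shorter homopolymers keep ordinary background errors, as in real
data.  Everything is deterministic under a fixed seed, byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import _seq
from ._seq import GAP, TRANSITION_PARTNER, TRANSVERSIONS, decode, rle
from .align_io import ReferenceGenome

__all__ = [
    "ErrorModelSpec",
    "SimulatedRun",
    "generate_reference",
    "simulate_reads",
    "homopolymer_correctness_curve",
    "pooled_truth_rates",
    "truth_comparison",
]


@dataclass
class ErrorModelSpec:
    """Generative error model parameters (per-column probabilities).

    ``gc_error_slope`` adds to the total per-read error rate per GC-percent
    deviation of the read from 50%.  ``quality_offset`` shifts emitted Phred
    scores away from the identity map (positive values overstate accuracy).
    """

    substitution_rate: float = 0.02
    insertion_rate: float = 0.015
    deletion_rate: float = 0.025
    transition_multiplier: float = 4.0
    gc_error_slope: float = 0.0004
    read_rate_sigma: float = 0.35
    base_rate_jitter: float = 0.10
    quality_offset: float = 0.0
    quality_grid: bool = False
    repeat_override: bool = True
    hp_min_resample_length: int = 5
    hp_miss_rate: float = 0.3
    hp_under_bias: float = 0.8
    hp_under_scale: float = 0.25
    hp_over_p: float = 0.55
    speed_coupling: float = 2.0
    mean_translocation_speed: float = 450.0
    sampling_rate: float = 4000.0
    clip_length: int = 0
    mod_call_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.total_rate >= 1.0:
            raise ValueError("per-column error probabilities must sum below 1")
        if self.transition_multiplier <= 0:
            raise ValueError("transition multiplier must be positive")
        if self.hp_min_resample_length < 2:
            raise ValueError("homopolymer resampling starts at length >= 2")

    @property
    def total_rate(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


def homopolymer_correctness_curve(model: ErrorModelSpec, lengths) -> np.ndarray:
    """Probability that a homopolymer of the given reference length is
    emitted at exactly its true length, under the generative model
    (point mass at zero deviation below the resampling threshold)."""
    L = np.asarray(lengths, dtype=float)
    p = np.ones_like(L)
    beyond = L >= model.hp_min_resample_length
    p[beyond] = np.exp(
        -model.hp_miss_rate * (L[beyond] - model.hp_min_resample_length + 1)
    )
    return p


def generate_reference(
    length: int,
    gc_fraction: float = 0.5,
    repeat_spec: list[dict] | None = None,
    gc_block_length: int = 20000,
    gc_block_sd: float = 0.08,
    seed: int = 0,
    name: str = "synthetic_ref",
) -> ReferenceGenome:
    """An i.i.d. reference with block-wise GC variation and optionally
    planted repeats.

    GC is drawn per block from a clipped normal around ``gc_fraction`` so
    that reads sample a realistic spread of local GC.  ``repeat_spec`` is a
    list of ``{"motif": str, "copies": int, "count": int}`` dicts; planted
    repeats overwrite the background sequence at random positions.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(length / gc_block_length))
    gcs = np.clip(rng.normal(gc_fraction, gc_block_sd, n_blocks), 0.05, 0.95)
    gpos = np.repeat(gcs, gc_block_length)[:length]
    u = rng.random(length)
    t_a = (1.0 - gpos) / 2.0
    t_c = t_a + gpos / 2.0
    t_g = t_c + gpos / 2.0
    codes = (
        (u >= t_a).astype(np.uint8)
        + (u >= t_c).astype(np.uint8)
        + (u >= t_g).astype(np.uint8)
    )
    for spec in repeat_spec or []:
        unit = _seq.encode(spec["motif"])
        block = np.tile(unit, int(spec["copies"]))
        if block.size > length:
            raise ValueError(
                f"planted repeat {spec['motif']}x{spec['copies']} exceeds genome"
            )
        for _ in range(int(spec["count"])):
            pos = int(rng.integers(0, length - block.size + 1))
            codes[pos : pos + block.size] = block
    return ReferenceGenome(name, decode(codes))


@dataclass
class SimulatedRun:
    """Handle to one simulated fixture: file paths plus in-memory truth."""

    reference: ReferenceGenome
    model: ErrorModelSpec
    paths: dict[str, Path]
    truth_reads: pd.DataFrame
    truth_repeats: pd.DataFrame
    n_reads: int
    total_columns: int


class _Strand:
    """Per-orientation precomputation for the simulator."""

    def __init__(self, genome: ReferenceGenome, model: ErrorModelSpec):
        self.codes = genome.codes
        L = genome.length
        is_gc = (self.codes == 1) | (self.codes == 2)
        self.gc_cum = np.concatenate(([0], np.cumsum(is_gc)))
        self.acgt_cum = np.concatenate(([0], np.cumsum(self.codes < 4)))
        vals, starts, lens = rle(self.codes)
        sel = (lens >= model.hp_min_resample_length) & (vals < 4)
        self.run_starts = starts[sel]
        self.run_ends = starts[sel] + lens[sel]
        self.run_lens = lens[sel]
        self.run_bases = vals[sel]
        mask = np.zeros(L + 1, dtype=np.int64)
        np.add.at(mask, self.run_starts, 1)
        np.add.at(mask, self.run_ends, -1)
        m = np.cumsum(mask[:-1]) > 0
        dil = m.copy()
        dil[:-1] |= m[1:]
        dil[1:] |= m[:-1]
        self.suppress = dil
        self.suppressed_fraction = float(dil.mean())

    def slice_gc_percent(self, start: int, n: int) -> float:
        acgt = self.acgt_cum[start + n] - self.acgt_cum[start]
        if acgt == 0:
            return float("nan")
        return 100.0 * (self.gc_cum[start + n] - self.gc_cum[start]) / acgt

    def runs_within(self, start: int, end: int):
        lo = np.searchsorted(self.run_starts, start, "left")
        hi = np.searchsorted(self.run_starts, end, "left")
        sel = slice(lo, hi)
        keep = self.run_ends[sel] <= end
        return (
            self.run_starts[sel][keep],
            self.run_ends[sel][keep],
            self.run_lens[sel][keep],
            self.run_bases[sel][keep],
        )


def _draw_lengths(
    rng: np.random.Generator,
    n: int,
    median: float,
    sigma: float,
    lo: int,
    hi: int,
    genome_length: int,
) -> np.ndarray:
    raw = rng.lognormal(np.log(median), sigma, n)
    return np.clip(raw, lo, min(hi, genome_length)).astype(np.int64)


def simulate_reads(
    reference: ReferenceGenome,
    model: ErrorModelSpec,
    out_dir: str | Path,
    *,
    n_reads: int | None = None,
    coverage: float | None = None,
    read_length_median: float = 10000.0,
    read_length_sigma: float = 0.55,
    read_length_range: tuple[int, int] = (500, 100000),
    emit_events: bool = False,
    emit_mod_calls: bool = False,
    seed: int | None = None,
    prefix: str = "sim",
) -> SimulatedRun:
    """Simulate a full run and write FASTA/FASTQ/SAM plus truth tables.

    Either ``n_reads`` or a target mean ``coverage`` must be given.  Two SAM
    files are produced, mirroring the dual-strand protocol: each read is
    reported against the genome copy it was drawn from (forward, or the
    reverse complement), in sequencing orientation, with a correct CIGAR.
    """
    if (n_reads is None) == (coverage is None):
        raise ValueError("give exactly one of n_reads or coverage")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    L = reference.length

    strands = {
        "forward": _Strand(reference, model),
        "reverse": _Strand(reference.reverse_complement(), model),
    }

    lo, hi = read_length_range
    lo = max(1, min(lo, L))
    if n_reads is not None:
        lengths = _draw_lengths(
            rng, n_reads, read_length_median, read_length_sigma, lo, hi, L
        )
    else:
        target = coverage * L
        chunks = []
        total = 0
        while total < target:
            c = _draw_lengths(
                rng, 256, read_length_median, read_length_sigma, lo, hi, L
            )
            csum = np.cumsum(c)
            need = int(np.searchsorted(csum, target - total)) + 1
            chunks.append(c[:need])
            total += int(csum[min(need, len(c)) - 1])
            if need < len(c):
                break
        lengths = np.concatenate(chunks)
    n = lengths.size
    starts = rng.integers(0, L - lengths + 1)
    is_reverse = rng.random(n) < 0.5

    paths = {
        "reference": out_dir / f"{prefix}_reference.fasta",
        "fastq": out_dir / f"{prefix}_reads.fastq",
        "forward_sam": out_dir / f"{prefix}_fwd.sam",
        "reverse_sam": out_dir / f"{prefix}_rev.sam",
        "truth_reads": out_dir / f"{prefix}_truth_reads.tsv",
        "truth_repeats": out_dir / f"{prefix}_truth_repeats.tsv",
    }
    with open(paths["reference"], "w") as fh:
        fh.write(f">{reference.name}\n")
        for i in range(0, L, 70):
            fh.write(reference.sequence[i : i + 70] + "\n")

    header = f"@HD\tVN:1.6\tSO:unknown\n@SQ\tSN:{reference.name}\tLN:{L}\n"
    fq = open(paths["fastq"], "w")
    sam = {
        "forward": open(paths["forward_sam"], "w"),
        "reverse": open(paths["reverse_sam"], "w"),
    }
    for fh in sam.values():
        fh.write(header)

    base_total = model.total_rate
    if base_total > 0:
        shares = (
            np.array(
                [model.substitution_rate, model.deletion_rate, model.insertion_rate]
            )
            / base_total
        )
    else:
        shares = np.zeros(3)
    hpmin = model.hp_min_resample_length
    truth_rows = []
    hp_rows = []
    event_rows = []
    mod_rows = []
    total_columns = 0

    for ridx in range(n):
        orientation = "reverse" if is_reverse[ridx] else "forward"
        st = strands[orientation]
        start = int(starts[ridx])
        m_len = int(lengths[ridx])
        sl = st.codes[start : start + m_len]

        gc = st.slice_gc_percent(start, m_len)
        mult = 1.0
        if model.read_rate_sigma > 0:
            mult = float(
                np.exp(
                    rng.normal(0.0, model.read_rate_sigma)
                    - model.read_rate_sigma**2 / 2.0
                )
            )
        total = base_total * mult + model.gc_error_slope * (gc - 50.0)
        total = float(np.clip(total, 1e-4, 0.4))
        if model.quality_grid:
            # FASTQ carries integer Phred scores only; snapping the read's
            # expected per-column error rate onto the integer-Phred grid
            # makes the identity quality emission exact (calibration
            # fixtures).  Insertion events add alignment columns, so the
            # column rate is total/(1 + total*ins_share); invert that map.
            s_i = float(shares[2])
            r_raw = total / (1.0 + total * s_i)
            q_grid = float(np.rint(-10.0 * np.log10(r_raw)))
            r = 10.0 ** (-q_grid / 10.0)
            total = float(r / (1.0 - r * s_i))
        p_sub, p_del, p_ins = total * shares

        if model.base_rate_jitter > 0 and not model.quality_grid:
            jit = np.exp(
                rng.normal(0.0, model.base_rate_jitter, m_len)
                - model.base_rate_jitter**2 / 2.0
            )
        else:
            jit = np.ones(m_len)
        psub_i = p_sub * jit
        pdel_i = p_del * jit
        pins_i = p_ins * jit

        u = rng.random(m_len)
        sub = u < psub_i
        dele = (~sub) & (u < psub_i + pdel_i)
        ins = rng.random(m_len) < pins_i
        # emitted quality encodes the expected per-column error probability
        # of the background model (insertion columns dilute the per-base
        # probability by 1 + p_ins), which is what alignment-based error
        # measurement estimates
        p_col = (psub_i + pdel_i + pins_i) / (1.0 + pins_i)
        with np.errstate(divide="ignore"):
            q_raw = np.where(p_col > 0, -10.0 * np.log10(np.maximum(p_col, 1e-12)), 60.0)
        qpos = np.clip(np.rint(q_raw) + model.quality_offset, 1, 60).astype(np.int16)

        hp_ins_events: list[tuple[int, int, int]] = []
        if model.repeat_override:
            sup = st.suppress[start : start + m_len]
            sub &= ~sup
            dele &= ~sup
            ins &= ~sup
            rs, re, rl, rb = st.runs_within(start, start + m_len)
            observed = rl.astype(np.int64).copy()
            correct = np.ones(rl.size, dtype=bool)
            if rl.size:
                Lr = rl.astype(float)
                pz = np.exp(-model.hp_miss_rate * (Lr - hpmin + 1))
                nz = rng.random(rl.size) >= pz
                neg = rng.random(rl.size) < model.hp_under_bias
                magn = 1 + rng.poisson(model.hp_under_scale * (Lr - hpmin + 1))
                magn = np.minimum(magn, rl)
                magp = rng.geometric(model.hp_over_p, rl.size)
                delta = np.where(nz, np.where(neg, -magn, magp), 0)
                for j, d_j in enumerate(delta):
                    if d_j == 0:
                        continue
                    le = int(re[j] - start)
                    if d_j < 0:
                        dele[le + int(d_j) : le] = True
                    else:
                        hp_ins_events.append((le - 1, int(d_j), int(rb[j])))
                    observed[j] += int(d_j)
                    correct[j] = False
            if rl.size:
                hp_rows.append(
                    pd.DataFrame(
                        {
                            "read_index": ridx,
                            "orientation": orientation,
                            "start": rs,
                            "ref_length": rl,
                            "motif": [_seq.ALPHABET[b] for b in rb],
                            "observed_length": observed,
                            "correct": correct,
                        }
                    )
                )

        # substitution targets with transition bias
        n_sub = int(sub.sum())
        refs = sl[sub]
        p_transition = model.transition_multiplier / (model.transition_multiplier + 2)
        v = rng.random(n_sub)
        tv_pick = rng.integers(0, 2, n_sub)
        targets = np.where(
            v < p_transition,
            TRANSITION_PARTNER[refs],
            TRANSVERSIONS[refs, tv_pick],
        ).astype(np.uint8)

        inscnt = ins.astype(np.int64)
        for pos, cnt, _b in hp_ins_events:
            inscnt[pos] += cnt
        offsets = np.concatenate(([0], np.cumsum(inscnt)))
        total_ins = int(offsets[-1])
        insbases = np.empty(total_ins, dtype=np.uint8)
        bg_pos = np.nonzero(ins)[0]
        insbases[offsets[bg_pos]] = rng.integers(0, 4, bg_pos.size)
        for pos, cnt, b in hp_ins_events:
            o = offsets[pos] + (1 if ins[pos] else 0)
            insbases[o : o + cnt] = b

        # assemble alignment columns
        percol = 1 + inscnt
        colpos = np.repeat(np.arange(m_len), percol)
        ncols = colpos.size
        first = np.concatenate(([0], np.cumsum(percol)[:-1]))
        opcode = np.ones(ncols, dtype=np.uint8)  # I
        opcode[first] = np.where(dele, 2, 0)  # D / M
        read_col = np.empty(ncols, dtype=np.uint8)
        ref_read = sl.copy()
        ref_read[sub] = targets
        read_col[first] = np.where(dele, GAP, ref_read)
        read_col[opcode == 1] = insbases
        read_mask = opcode != 2
        read_bases = read_col[read_mask]
        read_quals = qpos[colpos[read_mask]]

        # CIGAR
        ops_r, _, lens_r = rle(opcode)
        cig = "".join(f"{l}{'MID'[o]}" for o, l in zip(ops_r, lens_r))
        clip = model.clip_length
        seq_codes = read_bases
        quals = read_quals
        if clip > 0:
            left = rng.integers(0, 4, clip).astype(np.uint8)
            right = rng.integers(0, 4, clip).astype(np.uint8)
            seq_codes = np.concatenate((left, read_bases, right))
            quals = np.concatenate(
                (np.full(clip, 5, np.int16), read_quals, np.full(clip, 5, np.int16))
            )
            cig = f"{clip}S{cig}{clip}S"

        read_id = f"read{ridx:06d}"
        seq = decode(seq_codes)
        qual_str = (quals.astype(np.uint8) + 33).tobytes().decode("latin-1")
        fq.write(f"@{read_id}\n{seq}\n+\n{qual_str}\n")
        sam[orientation].write(
            f"{read_id}\t0\t{reference.name}\t{start + 1}\t60\t{cig}\t*\t0\t0\t"
            f"{seq}\t{qual_str}\n"
        )

        n_del = int(dele.sum())
        truth_rows.append(
            {
                "read_id": read_id,
                "orientation": orientation,
                "ref_start": start,
                "span": m_len,
                "columns": ncols,
                "substitutions": n_sub,
                "insertions": total_ins,
                "deletions": n_del,
                "gc_percent": gc,
                "rate_multiplier": mult,
                "total_rate": total,
            }
        )
        total_columns += ncols

        if emit_events:
            sp_base = model.sampling_rate / model.mean_translocation_speed
            lam = np.full(m_len, sp_base)
            lam[dele] = sp_base / model.speed_coupling
            samples = np.maximum(rng.poisson(lam), 1)
            pos = np.arange(start, start + m_len)
            if orientation == "reverse":
                pos = L - 1 - pos
            event_rows.append(
                pd.DataFrame(
                    {"read_id": read_id, "ref_pos": pos, "n_samples": samples}
                )
            )
        if emit_mod_calls and model.mod_call_rate > 0:
            is_c = read_bases == 1
            called = is_c & (rng.random(read_bases.size) < model.mod_call_rate)
            idx = np.nonzero(called)[0]
            if idx.size:
                mod_rows.append(
                    pd.DataFrame(
                        {
                            "read_id": read_id,
                            "read_pos": idx + clip,
                            "mod_type": "5mC",
                            "probability": np.round(
                                0.6 + 0.4 * rng.random(idx.size), 3
                            ),
                        }
                    )
                )

    fq.close()
    for fh in sam.values():
        fh.close()

    truth_reads = pd.DataFrame(truth_rows)
    truth_repeats = (
        pd.concat(hp_rows, ignore_index=True)
        if hp_rows
        else pd.DataFrame(
            columns=[
                "read_index", "orientation", "start", "ref_length",
                "motif", "observed_length", "correct",
            ]
        )
    )
    truth_reads.to_csv(paths["truth_reads"], sep="\t", index=False)
    truth_repeats.to_csv(paths["truth_repeats"], sep="\t", index=False)
    if emit_events:
        paths["events"] = out_dir / f"{prefix}_events.tsv"
        ev = (
            pd.concat(event_rows, ignore_index=True)
            if event_rows
            else pd.DataFrame(columns=["read_id", "ref_pos", "n_samples"])
        )
        ev.to_csv(paths["events"], sep="\t", index=False)
    if emit_mod_calls:
        paths["mod_calls"] = out_dir / f"{prefix}_mod_calls.tsv"
        mc = (
            pd.concat(mod_rows, ignore_index=True)
            if mod_rows
            else pd.DataFrame(columns=["read_id", "read_pos", "mod_type", "probability"])
        )
        mc.to_csv(paths["mod_calls"], sep="\t", index=False)

    return SimulatedRun(
        reference=reference,
        model=model,
        paths=paths,
        truth_reads=truth_reads,
        truth_repeats=truth_repeats,
        n_reads=n,
        total_columns=total_columns,
    )


def pooled_truth_rates(truth_reads: pd.DataFrame) -> dict[str, float]:
    """Column-pooled true error rates of a simulated run."""
    cols = float(truth_reads["columns"].sum())
    if cols == 0:
        raise ValueError("empty truth table")
    return {
        "substitution_rate": float(truth_reads["substitutions"].sum()) / cols,
        "insertion_rate": float(truth_reads["insertions"].sum()) / cols,
        "deletion_rate": float(truth_reads["deletions"].sum()) / cols,
    }


def truth_comparison(
    truth: Mapping[str, float],
    estimates: Mapping[str, float],
    tolerances: Mapping[str, float],
) -> pd.DataFrame:
    """Machine-readable recovery report: truth vs estimate per statistic,
    with absolute deviation checked against the stated tolerance."""
    missing = set(truth) - set(estimates)
    if missing:
        raise ValueError(f"estimates missing statistics: {sorted(missing)}")
    rows = []
    for key in truth:
        t, e = float(truth[key]), float(estimates[key])
        tol = float(tolerances.get(key, 0.0))
        dev = abs(e - t)
        rows.append(
            {
                "statistic": key,
                "truth": t,
                "estimate": e,
                "abs_deviation": dev,
                "rel_deviation": dev / abs(t) if t else float("nan"),
                "tolerance": tol,
                "passed": dev <= tol,
            }
        )
    return pd.DataFrame(rows)
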