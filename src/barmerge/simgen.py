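"""Synthetic paired-read generation with a recorded error truth.

Two fixture families are produced:

* Illumina-like short pairs: 2x250 bp reads drawn from fragments whose
  lengths are Normal(400, 10) (rounded, redrawn while out of bounds so the
  pair always overlaps), with per-base Phred scores from a MiSeq-like
  monotone curve (mean 37 at cycle 1 decaying to 30 at cycle 250, Gaussian
  jitter sd 3, floor 2) and substitutions injected at the quality-implied
  probability ``10**(-q/10)``; optional single-base insertions/deletions at
  a flat per-base rate.

* Sanger-like long pairs: one forward and one reverse read of 500-700 bp
  covering a 400-900 bp template from opposite ends, with a low-high-low
  quality ramp so end trimming is exercised, and N injected at sub-threshold
  positions.

Every injected error is recorded per read as an event list; replaying the
events onto the fragment reproduces the emitted read byte-exactly
(:func:`replay_read`), which is what the truth-tracking tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io_seq import Read, ReadPair, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_OTHER = {  # substitution targets per original base
    "A": "CGT",
    "C": "AGT",
    "G": "ACT",
    "T": "ACG",
    "N": "ACGT",
}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the Illumina-like simulation."""

    n_pairs: int = 1000
    read_length: int = 250
    frag_mean: float = 400.0
    frag_sd: float = 10.0
    sub_rate_scale: float = 1.0
    indel_rate: float = 0.0001
    qual_start: float = 37.0
    qual_end: float = 30.0
    qual_jitter_sd: float = 3.0
    qual_floor: int = 2
    qual_cap: int = 40
    min_overlap_floor: int = 25
    rng_seed: int = 0


@dataclass(frozen=True)
class PairTruth:
    """Ground truth for one simulated pair.

    ``errors_fwd``/``errors_rev`` are ordered event tuples:
    ``("del", t)`` skip template position t; ``("ins", t, base)`` insert
    before template position t; ``("sub", out_pos, base)`` substitute the
    finished read at out_pos.  Template coordinates are on the read's own
    strand (the fragment for R1, its reverse complement for R2).
    """

    frag_start: int
    frag_len: int
    fragment: str
    true_overlap: int
    errors_fwd: Tuple
    errors_rev: Tuple


@dataclass
class SimTruth:
    pairs: List[PairTruth] = field(default_factory=list)


def random_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random nucleotides at the requested GC content."""
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _quality_curve(p: SimParams, n: int, rng: np.random.Generator) -> np.ndarray:
    mean = np.linspace(p.qual_start, p.qual_end, n)
    q = np.rint(mean + rng.normal(0.0, p.qual_jitter_sd, n))
    return np.clip(q, p.qual_floor, p.qual_cap).astype(int)


def _apply_indels(template: str, events: List[Tuple]) -> str:
    """Assemble the indel-mutated sequence (del/ins events, by template pos)."""
    out: List[str] = []
    ev = [e for e in events if e[0] in ("del", "ins")]
    k = 0
    for t in range(len(template) + 1):
        while k < len(ev) and ev[k][0] == "ins" and ev[k][1] == t:
            out.append(ev[k][2])
            k += 1
        if t == len(template):
            break
        if k < len(ev) and ev[k][0] == "del" and ev[k][1] == t:
            k += 1
            continue
        out.append(template[t])
    return "".join(out)


def _mutate_read(
    template: str,
    quals: np.ndarray,
    sub_rate_scale: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> Tuple[str, List[int], List[Tuple]]:
    """Emit one read from a template strand; returns (seq, quals, events)."""
    n = len(quals)
    events: List[Tuple] = []
    if indel_rate > 0:
        span = min(len(template), n + 8)  # slack so deletions still fill the read
        u = rng.random(span)
        for t in np.flatnonzero(u < indel_rate):
            if u[t] < indel_rate / 2:
                events.append(("del", int(t)))
            else:
                base = str(rng.choice(_BASES).decode())
                events.append(("ins", int(t), base))
        seq = _apply_indels(template, events) if events else template
    else:
        seq = template
    seq = seq[:n]
    out_quals = list(int(q) for q in quals[: len(seq)])

    if sub_rate_scale > 0:
        err_p = np.power(10.0, -np.asarray(out_quals) / 10.0) * sub_rate_scale
        hits = np.flatnonzero(rng.random(len(seq)) < err_p)
        if hits.size:
            chars = list(seq)
            for pos in hits:
                choices = _OTHER[chars[pos]]
                new = choices[rng.integers(len(choices))]
                events.append(("sub", int(pos), new))
                chars[pos] = new
            seq = "".join(chars)
    return seq, out_quals, events


def replay_read(template: str, events: Sequence[Tuple], read_length: int) -> str:
    """Reproduce a simulated read from its template and error events."""
    seq = _apply_indels(template, list(events))[:read_length]
    chars = list(seq)
    for e in events:
        if e[0] == "sub":
            chars[e[1]] = e[2]
    return "".join(chars)


def _draw_fragment_length(p: SimParams, rng: np.random.Generator) -> int:
    lo = p.read_length
    hi = 2 * p.read_length - p.min_overlap_floor
    if lo > hi:
        raise ValueError("read_length/min_overlap_floor leave no valid fragment size")
    while True:
        length = int(round(rng.normal(p.frag_mean, p.frag_sd)))
        if lo <= length <= hi:
            return length


def simulate_pairs(ref: str, p: SimParams) -> Tuple[List[ReadPair], SimTruth]:
    """Simulate ``n_pairs`` overlapping read pairs from ``ref`` with truth.

    R1 is the fragment's first ``read_length`` bases; R2 is the reverse
    complement of its last ``read_length`` bases, so the pair overlaps by
    ``2*read_length - fragment_length`` error-free columns.
    """
    rng = np.random.default_rng(p.rng_seed)
    max_frag = 2 * p.read_length - p.min_overlap_floor
    if len(ref) <= max_frag:
        raise ValueError("reference shorter than the largest possible fragment")
    pairs: List[ReadPair] = []
    truth = SimTruth()
    for idx in range(p.n_pairs):
        frag_len = _draw_fragment_length(p, rng)
        start = int(rng.integers(0, len(ref) - frag_len + 1))
        fragment = ref[start : start + frag_len]
        t_fwd = fragment
        t_rev = reverse_complement(Read("t", fragment, [0] * frag_len)).seq

        q1 = _quality_curve(p, p.read_length, rng)
        s1, ql1, ev1 = _mutate_read(t_fwd, q1, p.sub_rate_scale, p.indel_rate, rng)
        q2 = _quality_curve(p, p.read_length, rng)
        s2, ql2, ev2 = _mutate_read(t_rev, q2, p.sub_rate_scale, p.indel_rate, rng)

        pairs.append(
            ReadPair(
                Read(f"sim{idx}/1", s1, ql1),
                Read(f"sim{idx}/2", s2, ql2),
            )
        )
        truth.pairs.append(
            PairTruth(
                frag_start=start,
                frag_len=frag_len,
                fragment=fragment,
                true_overlap=2 * p.read_length - frag_len,
                errors_fwd=tuple(ev1),
                errors_rev=tuple(ev2),
            )
        )
    return pairs, truth


# ---------------------------------------------------------------------------
# Sanger-like long pairs (trace-derived FASTQ emulation)

@dataclass(frozen=True)
class SangerParams:
    """Fixture definition for Sanger-like barcode read pairs.

    ``clean=True`` yields flat maximum-quality, error-free reads covering
    the whole template from each end, so QC+merge must reproduce the
    template exactly.
    """

    read_len_range: Tuple[int, int] = (500, 700)
    q_peak: int = 40
    q_end: int = 8
    ramp: int = 40
    jitter_sd: float = 2.0
    n_below: int = 20
    n_prob: float = 0.2
    sub_rate_scale: float = 1.0
    clean: bool = False


def _sanger_quals(n: int, sp: SangerParams, rng: np.random.Generator) -> np.ndarray:
    if sp.clean:
        return np.full(n, sp.q_peak, dtype=int)
    ramp = min(sp.ramp, n // 2)
    curve = np.full(n, float(sp.q_peak))
    if ramp > 0:
        curve[:ramp] = np.linspace(sp.q_end, sp.q_peak, ramp)
        curve[n - ramp :] = np.linspace(sp.q_peak, sp.q_end, ramp)
    q = np.rint(curve + rng.normal(0.0, sp.jitter_sd, n))
    return np.clip(q, 2, sp.q_peak).astype(int)


def simulate_sanger_pair(
    template: str,
    sp: SangerParams = SangerParams(),
    rng: Optional[np.random.Generator] = None,
    pair_id: str = "sanger0",
) -> ReadPair:
    """One long forward/reverse pair covering a 400-900 bp template.

    The forward read covers the template's 5' portion; the reverse read is
    the reverse complement of the 3' portion.  Drawn read lengths are
    capped at the template length (a short amplicon is read end to end).
    Substitutions follow the quality-implied rate; below ``n_below``
    quality, bases are additionally replaced by N with ``n_prob``.
    """
    if not (400 <= len(template) <= 900):
        raise ValueError("template must be 400-900 bp")
    if rng is None:
        rng = np.random.default_rng(0)
    lo, hi = sp.read_len_range

    def one_read(strand_template: str, name: str) -> Read:
        n = min(int(rng.integers(lo, hi + 1)), len(strand_template))
        seq = strand_template[:n]
        quals = _sanger_quals(n, sp, rng)
        if not sp.clean:
            chars = list(seq)
            err_p = np.power(10.0, -quals / 10.0) * sp.sub_rate_scale
            for pos in np.flatnonzero(rng.random(n) < err_p):
                choices = _OTHER[chars[pos]]
                chars[pos] = choices[rng.integers(len(choices))]
            low = np.flatnonzero(quals < sp.n_below)
            for pos in low[rng.random(low.size) < sp.n_prob]:
                chars[pos] = "N"
            seq = "".join(chars)
        return Read(name, seq, [int(q) for q in quals])

    rc = reverse_complement(Read("t", template, [0] * len(template))).seq
    return ReadPair(
        one_read(template, f"{pair_id}/1"),
        one_read(rc, f"{pair_id}/2"),
    )


def write_truth_tsv(truth: SimTruth, path) -> None:
    """Serialize the per-pair truth as TSV (events as op:pos[:base] lists)."""

    def fmt(events: Tuple) -> str:
        return ";".join(":".join(str(x) for x in e) for e in events) or "."

    with open(path, "w") as out:
        out.write(
            "pair\tfrag_start\tfrag_len\ttrue_overlap\terrors_fwd\terrors_rev\n"
        )
        for i, t in enumerate(truth.pairs):
            out.write(
                f"sim{i}\t{t.frag_start}\t{t.frag_len}\t{t.true_overlap}\t"
                f"{fmt(t.errors_fwd)}\t{fmt(t.errors_rev)}\n"
            )
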