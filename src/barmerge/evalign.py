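"""Evaluate merged sequences by local alignment back to a reference.

A native local aligner (match +1, mismatch -1, gap open -2, gap extend
-0.5) stands in for an external BLAST search; on near-identical sequences
this approximates megablast behaviour, but absolute mismatch/gap counts
from other aligners may differ slightly — the report header discloses the
scoring.  Candidate loci are found with an exact k-mer index so each
alignment only runs against a short reference window; both strands are
tried.  Summary statistics mirror a merger benchmark table: percentage of
pairs merged, mean/SD of merged length and identity, mean mismatches and
mean gap openings per merged sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align

from .io_seq import Read, reverse_complement
from .merge_core import MergeOutcome

_SCORING_NOTE = (
    "native local aligner: match +1, mismatch -1, gap open -2, gap extend -0.5"
)


@dataclass(frozen=True)
class AlignmentResult:
    identity_pct: float
    mismatches: int
    gap_openings: int
    columns: int
    strand: str


@dataclass(frozen=True)
class AlignmentStats:
    n_input_pairs: int
    n_merged: int
    pct_merged: float
    mean_len: float
    sd_len: float
    mean_identity_pct: float
    sd_identity: float
    mean_mismatches: float
    mean_gap_openings: float
    n_unaligned: int = 0

    def __post_init__(self):
        if not (0.0 <= self.pct_merged <= 100.0) or self.n_merged > self.n_input_pairs:
            raise ValueError("inconsistent merge counts")


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


class ReferenceIndex:
    """Exact k-mer lookup used to pre-locate a query on the reference."""

    def __init__(self, ref: str, k: int = 20):
        self.ref = ref
        self.k = k
        index = {}
        for i in range(len(ref) - k + 1):
            kmer = ref[i : i + k]
            if kmer not in index:  # first position suffices for locating
                index[kmer] = i
        self._index = index

    def locate(self, seq: str, probe_step: int = 24) -> Optional[int]:
        """Reference start implied by the first query k-mer that hits."""
        for off in range(0, max(1, len(seq) - self.k + 1), probe_step):
            pos = self._index.get(seq[off : off + self.k])
            if pos is not None:
                return pos - off
        return None


def _alignment_counts(alignment) -> Tuple[int, int, int, int]:
    """(matches, mismatches, gap_openings, columns) of a Bio alignment."""
    t_blocks, q_blocks = alignment.aligned
    target, query = alignment.target, alignment.query
    matches = mismatches = gap_openings = columns = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t_end is not None:
            if ts > prev_t_end:  # gap in query
                gap_openings += 1
                columns += ts - prev_t_end
            if qs > prev_q_end:  # gap in target
                gap_openings += 1
                columns += qs - prev_q_end
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
            else:
                mismatches += 1
        columns += te - ts
        prev_t_end, prev_q_end = te, qe
    return matches, mismatches, gap_openings, columns


def align_merged(
    merged: Read,
    ref: "str | ReferenceIndex",
    min_score: float = 20.0,
    margin: int = 60,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> Optional[AlignmentResult]:
    """Best local alignment of one merged sequence against either strand.

    Returns None (to be counted as unaligned) when no k-mer seed hits or
    the best alignment scores below ``min_score``.
    """
    index = ref if isinstance(ref, ReferenceIndex) else ReferenceIndex(ref)
    if aligner is None:
        aligner = _make_aligner()

    best: Optional[Tuple[float, str, object]] = None
    for strand, seq in (("+", merged.seq), ("-", reverse_complement(merged).seq)):
        start = index.locate(seq)
        if start is None:
            continue
        lo = max(0, start - margin)
        hi = min(len(index.ref), start + len(seq) + margin)
        window = index.ref[lo:hi]
        score = aligner.score(window, seq)
        if score < min_score:
            continue
        if best is None or score > best[0]:
            best = (score, strand, aligner.align(window, seq)[0])
    if best is None:
        return None
    _, strand, alignment = best
    matches, mismatches, gap_openings, columns = _alignment_counts(alignment)
    identity = 100.0 * matches / columns if columns else 0.0
    return AlignmentResult(identity, mismatches, gap_openings, columns, strand)


def summarize(
    outcomes: Sequence[MergeOutcome],
    alignments: Sequence[Optional[AlignmentResult]],
) -> AlignmentStats:
    """Benchmark-table statistics; means/SDs are over merged pairs only."""
    n_input = len(outcomes)
    merged = [o for o in outcomes if o.merged]
    n_merged = len(merged)
    lengths = np.array([len(o.consensus) for o in merged], dtype=float)
    aligned = [a for a in alignments if a is not None]
    n_unaligned = sum(1 for a in alignments if a is None)
    ident = np.array([a.identity_pct for a in aligned], dtype=float)
    mism = np.array([a.mismatches for a in aligned], dtype=float)
    gaps = np.array([a.gap_openings for a in aligned], dtype=float)

    def mean(x):
        return float(x.mean()) if x.size else float("nan")

    def sd(x):
        return float(x.std(ddof=1)) if x.size > 1 else 0.0

    return AlignmentStats(
        n_input_pairs=n_input,
        n_merged=n_merged,
        pct_merged=100.0 * n_merged / n_input if n_input else 0.0,
        mean_len=mean(lengths),
        sd_len=sd(lengths),
        mean_identity_pct=mean(ident),
        sd_identity=sd(ident),
        mean_mismatches=mean(mism),
        mean_gap_openings=mean(gaps),
        n_unaligned=n_unaligned,
    )


def stats_table(stats: AlignmentStats) -> str:
    """Render the statistics as a TSV block with a scoring disclosure."""
    lines = [
        f"# {_SCORING_NOTE}",
        "metric\tvalue",
        f"n_input_pairs\t{stats.n_input_pairs}",
        f"n_merged\t{stats.n_merged}",
        f"pct_merged\t{stats.pct_merged:.2f}",
        f"mean_len\t{stats.mean_len:.2f}",
        f"sd_len\t{stats.sd_len:.2f}",
        f"mean_identity_pct\t{stats.mean_identity_pct:.2f}",
        f"sd_identity\t{stats.sd_identity:.2f}",
        f"mean_mismatches\t{stats.mean_mismatches:.2f}",
        f"mean_gap_openings\t{stats.mean_gap_openings:.2f}",
        f"n_unaligned\t{stats.n_unaligned}",
    ]
    if stats.n_merged == 0:
        lines.append("# warning: zero merged pairs; means are undefined")
    return "\n".join(lines) + "\n"
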