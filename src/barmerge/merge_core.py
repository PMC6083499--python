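"""Seed-based paired-end overlap merging with indel tolerance.

The algorithm anchors the two reads with a short exact seed taken from the
3' end of the forward read, lays the oriented reverse read out against it,
and scans the implied overlap column by column.  A mismatching column is
accepted as a substitution only when the next ``tolerance`` columns all
match; otherwise single gap columns are inserted (in either read, up to
``repeat`` per site) until the look-ahead matches, and the whole site is
rolled back to a plain mismatch if it never does.  A merge is accepted when
the overlap spans at least ``min_overlap`` alignment columns with identity
at least ``min_identity`` and at most ``max_gap_openings`` gap openings;
consecutive gap columns inserted at one site count as a single opening.

Consensus construction keeps both non-overlapped tails.  Inside the
overlap, agreeing bases keep the higher of the two qualities, a true
mismatch is resolved in favour of the higher-quality base (forward read on
ties), a base beats a gap, and an N defers to the other read's base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .io_seq import Read, ReadPair, reverse_complement

STATUS_MERGED = "merged"
STATUS_NO_SEED = "no_seed"
STATUS_SHORT_OVERLAP = "short_overlap"
STATUS_LOW_IDENTITY = "low_identity"
STATUS_TOO_MANY_GAPS = "too_many_gaps"


@dataclass(frozen=True)
class MergeParams:
    """All tunables of the overlap merger.

    Defaults: 25 bp minimum overlap, 90% minimum identity, at most 5 gap
    openings; seed of 16 bp slid in 12 bp steps; 5-column look-ahead
    tolerance with up to 4 gap-insertion retries per mismatch site.
    """

    min_overlap: int = 25
    min_identity: float = 0.90
    max_gap_openings: int = 5
    seed_length: int = 16
    seed_step: int = 12
    tolerance: int = 5
    repeat: int = 4
    orient_reverse: bool = True
    consensus_suffix: str = "_merged"

    def __post_init__(self):
        if self.seed_length < 1 or self.seed_step < 1:
            raise ValueError("seed_length and seed_step must be >= 1")
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must be in (0, 1]")
        if self.tolerance < 1 or self.repeat < 0:
            raise ValueError("tolerance must be >= 1 and repeat >= 0")


@dataclass(frozen=True)
class OverlapAnchor:
    """Exact seed shared by the two reads, fixing their relative offset."""

    seed_start_fwd: int
    seed_start_rev: int
    seed_length: int

    @property
    def offset(self) -> int:
        """Forward-read position aligned with reverse-read position 0."""
        return self.seed_start_fwd - self.seed_start_rev


@dataclass(frozen=True)
class OverlapScore:
    identity_count: int
    mismatch_count: int
    gap_openings: int
    overlap_columns: int

    def __post_init__(self):
        if self.identity_count + self.mismatch_count > self.overlap_columns:
            raise ValueError("identity + mismatch cannot exceed columns")

    @property
    def identity_fraction(self) -> float:
        if self.overlap_columns == 0:
            return 0.0
        return self.identity_count / self.overlap_columns


@dataclass(frozen=True)
class OverlapAlignment:
    """Column-by-column layout of the scanned overlap.

    ``columns`` holds ``(i, j)`` index pairs into the forward and oriented
    reverse reads; a ``None`` marks a gap on that side.  ``fwd_start`` /
    ``rev_start`` are where the overlap begins on each read and
    ``fwd_end`` / ``rev_end`` where the scan stopped (half-open).
    """

    columns: Tuple
    fwd_start: int
    rev_start: int
    fwd_end: int
    rev_end: int


@dataclass(frozen=True)
class MergeOutcome:
    status: str
    consensus: Optional[Read] = None
    score: Optional[OverlapScore] = None
    anchor: Optional[OverlapAnchor] = None
    alignment: Optional[OverlapAlignment] = None
    reverse_complemented: bool = True

    def __post_init__(self):
        if (self.status == STATUS_MERGED) != (self.consensus is not None):
            raise ValueError("consensus present exactly when status is merged")

    @property
    def merged(self) -> bool:
        return self.status == STATUS_MERGED


def find_anchor(
    fwd: Read, rev_oriented: Read, p: MergeParams
) -> Optional[OverlapAnchor]:
    """Slide a seed from the forward read's 3' end and look it up exactly.

    The first seed window ends at the 3' terminus; on a miss the window
    moves ``seed_step`` toward the 5' end until it would leave the read.
    The leftmost occurrence in the oriented reverse read is used.
    """
    k = p.seed_length
    if len(fwd) < k or len(rev_oriented) < k:
        return None
    for start in range(len(fwd) - k, -1, -p.seed_step):
        seed = fwd.seq[start : start + k]
        pos = rev_oriented.seq.find(seed)
        if pos != -1:
            return OverlapAnchor(start, pos, k)
    return None


def _bases_match(a: str, b: str) -> bool:
    # N is compatible with anything: the consensus stage resolves it to the
    # other read's base, so scanning does not penalise it.
    return a == b or a == "N" or b == "N"


def scan_overlap(
    fwd: Read, rev_oriented: Read, anchor: OverlapAnchor, p: MergeParams
) -> Tuple[OverlapScore, OverlapAlignment]:
    """Column scan of the full implied overlap with gap-insertion repair."""
    fs, rs = fwd.seq, rev_oriented.seq
    d = anchor.offset
    i0, j0 = (d, 0) if d >= 0 else (0, -d)
    i, j = i0, j0
    nf, nr = len(fs), len(rs)
    tol = p.tolerance

    def lookahead_ok(i2: int, j2: int) -> bool:
        # Compare up to `tol` columns; near the overlap end only the
        # remaining columns are compared, and all of them must match.
        n = min(tol, nf - i2, nr - j2)
        for t in range(n):
            if not _bases_match(fs[i2 + t], rs[j2 + t]):
                return False
        return True

    columns: List[Tuple] = []
    identity = mismatch = gap_openings = 0
    while i < nf and j < nr:
        if _bases_match(fs[i], rs[j]):
            identity += 1
            columns.append((i, j))
            i += 1
            j += 1
            continue
        if lookahead_ok(i + 1, j + 1):
            mismatch += 1
            columns.append((i, j))
            i += 1
            j += 1
            continue
        placed = False
        for g in range(1, p.repeat + 1):
            # Gap in the reverse read: forward bases face gap columns.
            if lookahead_ok(i + g, j):
                columns.extend((i + t, None) for t in range(g))
                identity += g  # a base aligned to a gap scores as a hit
                gap_openings += 1  # one site, however many columns
                i += g
                placed = True
                break
            if lookahead_ok(i, j + g):
                columns.extend((None, j + t) for t in range(g))
                identity += g
                gap_openings += 1
                j += g
                placed = True
                break
        if not placed:
            # Roll back: no insertion count satisfied the look-ahead, so
            # the site is charged as a single substitution.
            mismatch += 1
            columns.append((i, j))
            i += 1
            j += 1
    score = OverlapScore(identity, mismatch, gap_openings, len(columns))
    aln = OverlapAlignment(tuple(columns), i0, j0, i, j)
    return score, aln


def accept(score: OverlapScore, p: MergeParams) -> Tuple[bool, Optional[str]]:
    """Inclusive threshold test; returns (accepted, rejection_reason)."""
    if score.overlap_columns < p.min_overlap:
        return False, STATUS_SHORT_OVERLAP
    if score.identity_fraction < p.min_identity:
        return False, STATUS_LOW_IDENTITY
    if score.gap_openings > p.max_gap_openings:
        return False, STATUS_TOO_MANY_GAPS
    return True, None


def build_consensus(
    fwd: Read,
    rev_oriented: Read,
    alignment: OverlapAlignment,
    consensus_id: str,
) -> Read:
    """Quality-aware consensus over the overlap plus both unmerged tails."""
    fs, rs = fwd.seq, rev_oriented.seq
    fq, rq = fwd.quals, rev_oriented.quals
    seq: List[str] = []
    quals: List[int] = []

    # Left tail: whichever read starts before the overlap.
    if alignment.fwd_start > 0:
        seq.append(fs[: alignment.fwd_start])
        quals.extend(fq[: alignment.fwd_start])
    elif alignment.rev_start > 0:
        seq.append(rs[: alignment.rev_start])
        quals.extend(rq[: alignment.rev_start])

    for fi, rj in alignment.columns:
        if rj is None:
            seq.append(fs[fi])
            quals.append(fq[fi])
        elif fi is None:
            seq.append(rs[rj])
            quals.append(rq[rj])
        else:
            a, b = fs[fi], rs[rj]
            qa, qb = fq[fi], rq[rj]
            if a == b:
                seq.append(a)
                quals.append(max(qa, qb))
            elif a == "N":
                seq.append(b)
                quals.append(qb)
            elif b == "N":
                seq.append(a)
                quals.append(qa)
            elif qa >= qb:  # quality tie resolves to the forward base
                seq.append(a)
                quals.append(qa)
            else:
                seq.append(b)
                quals.append(qb)

    # Right tail: whatever the scan did not consume.
    if alignment.rev_end < len(rs):
        seq.append(rs[alignment.rev_end :])
        quals.extend(rq[alignment.rev_end :])
    elif alignment.fwd_end < len(fs):
        seq.append(fs[alignment.fwd_end :])
        quals.extend(fq[alignment.fwd_end :])

    return Read(consensus_id, "".join(seq), quals)


def merge_pair(pair: ReadPair, p: MergeParams = MergeParams()) -> MergeOutcome:
    """Run the full merge on one pair: orient, anchor, scan, accept, build.

    The reverse read is reverse-complemented first when ``orient_reverse``
    is set; if no seed is found in that orientation, anchoring is retried
    against the un-complemented reverse read.
    """
    fwd = pair.forward
    candidates = []
    if p.orient_reverse:
        candidates.append((reverse_complement(pair.reverse), True))
        candidates.append((pair.reverse, False))
    else:
        candidates.append((pair.reverse, False))

    anchor = None
    rev_oriented = candidates[0][0]
    flipped = candidates[0][1]
    for cand, was_flipped in candidates:
        a = find_anchor(fwd, cand, p)
        if a is not None:
            anchor, rev_oriented, flipped = a, cand, was_flipped
            break
    if anchor is None:
        return MergeOutcome(STATUS_NO_SEED, reverse_complemented=flipped)

    score, aln = scan_overlap(fwd, rev_oriented, anchor, p)
    ok, reason = accept(score, p)
    if not ok:
        return MergeOutcome(
            reason, score=score, anchor=anchor, alignment=aln,
            reverse_complemented=flipped,
        )
    consensus = build_consensus(
        fwd, rev_oriented, aln, fwd.id + p.consensus_suffix
    )
    return MergeOutcome(
        STATUS_MERGED,
        consensus=consensus,
        score=score,
        anchor=anchor,
        alignment=aln,
        reverse_complemented=flipped,
    )
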