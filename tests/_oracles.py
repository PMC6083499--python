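"""Independent oracles and constructors shared by the test suite.

These deliberately avoid the code paths they check: the trimming oracle is
a transparent brute-force scan over every window position, the alignment
oracle is edlib's optimal unit-cost dynamic programming, and the instance
constructors build read pairs from a known template with injected,
well-separated errors so the optimal alignment is unique.
"""

from __future__ import annotations

import re
from typing import List, Sequence, Tuple

import numpy as np

from barmerge.io_seq import Read, ReadPair, reverse_complement
from barmerge.merge_core import OverlapAnchor

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# QC: brute-force window-scan oracle

def _window_mean(quals: Sequence[int], i: int, j: int) -> float:
    return sum(quals[i:j]) / (j - i)


def oracle_trim_interval(quals: Sequence[int], window: int, thr: float) -> Tuple[int, int]:
    """Surviving (start, stop) by scanning every window position (step 1).

    5' cut: the first position whose window (truncated at the end) reaches
    the threshold.  3' cut: the mirror-image scan on the remainder.
    """
    n = len(quals)
    a = n
    for i in range(n):
        if _window_mean(quals, i, min(i + window, n)) >= thr:
            a = i
            break
    if a >= n:
        return n, n
    rest = quals[a:]
    m = len(rest)
    b = m
    for i in range(m):
        if _window_mean(rest, max(0, m - i - window), m - i) >= thr:
            b = i
            break
    return a, a + (m - b)


# ---------------------------------------------------------------------------
# Alignment: edlib dynamic-programming oracle

def edlib_counts(a: str, b: str) -> Tuple[int, int]:
    """(substitutions, gap_openings) of the optimal unit-cost alignment."""
    import edlib

    result = edlib.align(a, b, task="path", mode="NW")
    ops = re.findall(r"(\d+)([=XID])", result["cigar"])
    subs = sum(int(n) for n, op in ops if op == "X")
    gap_openings = sum(1 for _, op in ops if op in "ID")
    return subs, gap_openings


# ---------------------------------------------------------------------------
# Constructed overlap instances with known error content

def _low_complexity(window: str) -> bool:
    """Period-1 or period-2 repetition: indel placement is ambiguous there."""
    for i in range(len(window) - 2):
        if window[i] == window[i + 1] == window[i + 2]:
            return True
    for i in range(len(window) - 3):
        if window[i] == window[i + 2] and window[i + 1] == window[i + 3]:
            return True
    return False


def make_overlap_instance(
    rng: np.random.Generator,
    overlap_len: int,
    n_subs: int,
    n_indels: int,
    flank: int = 20,
    min_sep: int = 8,
):
    """A (fwd, rev_oriented, anchor) triple plus the two overlap strings.

    The forward read ends with the overlap template; the oriented reverse
    read starts with a mutated copy of it.  Injected errors are at least
    ``min_sep`` apart and ``min_sep`` from either end, and indels avoid
    low-complexity (tandem-repeat) contexts, so the optimal unit-cost
    alignment is unique, unambiguous and equals the injected error counts.
    """
    n_err = n_subs + n_indels
    while True:
        template = random_seq(rng, overlap_len)
        lo, hi = min_sep, overlap_len - min_sep
        pos = np.sort(rng.choice(np.arange(lo, hi), size=n_err, replace=False))
        if n_err >= 2 and not np.all(np.diff(pos) >= min_sep):
            continue
        kinds = ["sub"] * n_subs + ["indel"] * n_indels
        rng.shuffle(kinds)
        if any(
            kind == "indel" and _low_complexity(template[int(p) - 2 : int(p) + 8])
            for p, kind in zip(pos, kinds)
        ):
            continue
        mutated = list(template)
        ok = True
        for p, kind in sorted(zip(pos, kinds), reverse=True):
            p = int(p)
            if kind == "sub":
                mutated[p] = rng.permuted([b for b in BASES if b != mutated[p]])[0]
            elif rng.random() < 0.5:  # deletion from the reverse copy
                if template[p] == template[p + 1]:
                    ok = False  # divergence would drift into unchecked context
                    break
                del mutated[p]
            else:  # insertion into the reverse copy
                x = BASES[rng.integers(0, 4)]
                if x == template[p]:
                    ok = False
                    break
                mutated.insert(p, x)
        if ok:
            break
    mutated = "".join(mutated)

    fwd = Read("f", random_seq(rng, flank) + template, [40] * (flank + overlap_len))
    rev = Read("r", mutated + random_seq(rng, flank), [40] * (len(mutated) + flank))
    anchor = OverlapAnchor(seed_start_fwd=flank, seed_start_rev=0, seed_length=min_sep)
    return fwd, rev, anchor, template, mutated


def make_pair_with_overlap(
    rng: np.random.Generator,
    overlap_len: int,
    identity: float,
    read_len: int = 150,
) -> ReadPair:
    """A read pair whose true overlap has the given length and identity.

    The last 16 bases of the overlap are kept identical so the default
    seed anchors (unless the overlap itself is shorter than a seed); the
    rest of the overlap matches independently with probability
    ``identity``.  The reverse mate is stored on the opposite strand.
    """
    fwd_tail = random_seq(rng, read_len - overlap_len)
    overlap_f = random_seq(rng, overlap_len)
    seed_keep = min(16, overlap_len)
    overlap_r = [
        c if (i >= overlap_len - seed_keep or rng.random() < identity)
        else rng.permuted([b for b in BASES if b != c])[0]
        for i, c in enumerate(overlap_f)
    ]
    rev_oriented = Read(
        "r", "".join(overlap_r) + random_seq(rng, read_len - overlap_len),
        [40] * read_len,
    )
    fwd = Read("f", fwd_tail + overlap_f, [40] * read_len)
    return ReadPair(fwd, reverse_complement(rev_oriented))


def shares_kmer(a: str, b: str, k: int) -> bool:
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


# ---------------------------------------------------------------------------
# ORF: clean coding sequence embedded in stop-bounded flanks

def _revcomp_str(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _longest_run_len(aa: str) -> int:
    return max(len(run) for run in aa.split("*"))


def frame_runs(seq: str, table) -> dict:
    """Longest stop-free run length per frame, by direct translation."""
    rc = _revcomp_str(seq)
    return {
        f: _longest_run_len(table.translate((seq if f > 0 else rc)[abs(f) - 1 :]))
        for f in (1, 2, 3, -1, -2, -3)
    }


def make_cds_in_flanks(rng: np.random.Generator, table, n_codons: int = 80,
                       flank_max: int = 60):
    """(sequence, cds_aa, frame) with a sense-codon CDS bounded by stops.

    Rejection-sampled so that the CDS's own frame holds the strictly
    longest stop-free run of all six frames (a shifted reading of random
    sense codons is itself stop-free a few percent of the time, which
    would make the fixture ambiguous).
    """
    sense = sorted(set(table.codon_map) - {c for c, a in table.codon_map.items()
                                           if a == "*"})
    stops = sorted(c for c, a in table.codon_map.items() if a == "*")
    while True:
        codons = [sense[i] for i in rng.integers(0, len(sense), n_codons)]
        cds = "".join(codons)
        left = random_seq(rng, int(rng.integers(0, flank_max))) if flank_max else ""
        right = random_seq(rng, int(rng.integers(0, flank_max))) if flank_max else ""
        stop_l = stops[rng.integers(0, len(stops))]
        stop_r = stops[rng.integers(0, len(stops))]
        seq = left + stop_l + cds + stop_r + right
        frame = (len(left) + 3) % 3 + 1
        runs = frame_runs(seq, table)
        others = max(v for f, v in runs.items() if f != frame)
        if runs[frame] >= n_codons and runs[frame] > others:
            aa = "".join(table.codon_map[c] for c in codons)
            return seq, aa, frame
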