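"""Quality trimming, filtering and per-run quality reporting.

Trimming removes low-quality read ends with a sliding mean-quality window
(default: 10 bp window, 1 bp step, mean Phred threshold 20), first from the
5' end and then from the 3' end of the remainder; a pass stops at the first
window whose arithmetic mean reaches the threshold.  When fewer than
``window`` bases remain, the whole remainder is one window.  Filtering then
discards trimmed reads shorter than 50 bp or with overall mean quality
strictly below Phred 20.  Reads that fail are not silently dropped by the
pipeline: they are diverted to "rejected" files for later inspection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_seq import Read

STATUS_KEPT = "kept"
STATUS_FILTERED_QUALITY = "filtered_quality"
STATUS_FILTERED_LENGTH = "filtered_length"
STATUS_EMPTIED = "emptied_by_trim"


@dataclass(frozen=True)
class TrimParams:
    """Tunables of the trim/filter stage (all Phred/bp units)."""

    window: int = 10
    step: int = 1
    min_window_mean_qual: float = 20.0
    min_mean_qual: float = 20.0
    min_length: int = 50

    def __post_init__(self):
        if self.window < 1 or self.step < 1 or self.min_length < 1:
            raise ValueError("window, step and min_length must be >= 1")


@dataclass(frozen=True)
class QCOutcome:
    """Result of trim+filter for one read.

    ``read`` is present iff ``status == "kept"``; the trim counts record
    how many bases each end lost.
    """

    read: Optional[Read]
    status: str
    trimmed_5p: int
    trimmed_3p: int

    def __post_init__(self):
        if (self.status == STATUS_KEPT) != (self.read is not None):
            raise ValueError("read must be present exactly when status is kept")


def _leading_cut(quals: Sequence[int], p: TrimParams) -> int:
    """Bases to drop from the front: advance by ``step`` while the window
    starting at the cursor has mean quality below the threshold."""
    n = len(quals)
    pos = 0
    while pos < n:
        win = quals[pos : pos + p.window]
        if sum(win) / len(win) >= p.min_window_mean_qual:
            return pos
        pos += p.step
    return n


def trim_points(r: Read, p: TrimParams) -> tuple:
    """(start, stop) of the surviving interval, 0-based half-open."""
    a = _leading_cut(r.quals, p)
    if a >= len(r):
        return len(r), len(r)
    rest = r.quals[a:]
    b = _leading_cut(rest[::-1], p)
    return a, len(r) - b


def trim_read(r: Read, p: TrimParams) -> Read:
    """Sliding-window end trimming; may return an empty read."""
    a, b = trim_points(r, p)
    return r.slice(a, b)


def filter_read(r: Read, p: TrimParams) -> QCOutcome:
    """Classify an already-trimmed read: length check, then mean quality.

    Both thresholds are strict "below" tests, so a 50 bp read with mean
    quality exactly 20.0 is kept.
    """
    if len(r) == 0:
        return QCOutcome(None, STATUS_EMPTIED, 0, 0)
    if len(r) < p.min_length:
        return QCOutcome(None, STATUS_FILTERED_LENGTH, 0, 0)
    if r.mean_quality < p.min_mean_qual:
        return QCOutcome(None, STATUS_FILTERED_QUALITY, 0, 0)
    return QCOutcome(r, STATUS_KEPT, 0, 0)


def qc_read(r: Read, p: TrimParams) -> QCOutcome:
    """Trim then filter one read, recording per-end trim counts."""
    a, b = trim_points(r, p)
    trimmed = r.slice(a, b)
    t5, t3 = a, len(r) - b
    if len(trimmed) == 0:
        return QCOutcome(None, STATUS_EMPTIED, t5, t3)
    outcome = filter_read(trimmed, p)
    return QCOutcome(outcome.read, outcome.status, t5, t3)


def quality_report(
    reads: Iterable[Read],
    threshold: float = 20.0,
    flag_fraction: float = 0.10,
) -> tuple:
    """Per-read quality table plus run-level totals.

    Each row gives length, mean quality, and the count/fraction of bases
    whose Phred score falls below ``threshold``; a read is flagged
    "potential problematic" when that fraction exceeds ``flag_fraction``.
    Returns ``(DataFrame, totals_dict)``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rows = []
    for r in reads:
        q = np.asarray(r.quals, dtype=float)
        n_below = int((q < threshold).sum()) if len(q) else 0
        frac = n_below / len(q) if len(q) else 0.0
        rows.append(
            {
                "read_id": r.id,
                "length": len(r),
                "mean_quality": float(q.mean()) if len(q) else 0.0,
                "n_below_threshold": n_below,
                "frac_below_threshold": frac,
                "potential_problematic": frac > flag_fraction,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "length",
            "mean_quality",
            "n_below_threshold",
            "frac_below_threshold",
            "potential_problematic",
        ],
    )
    totals = {
        "n_reads": int(len(df)),
        "total_bases": int(df["length"].sum()) if len(df) else 0,
        "total_below_threshold": int(df["n_below_threshold"].sum()) if len(df) else 0,
        "n_flagged": int(df["potential_problematic"].sum()) if len(df) else 0,
        "threshold": threshold,
    }
    return df, totals


def write_quality_report(df: pd.DataFrame, totals: dict, path) -> None:
    """Render the report as TSV with a commented totals header."""
    with open(path, "w") as out:
        for key, value in totals.items():
            out.write(f"# {key}\t{value}\n")
        df.to_csv(out, sep="\t", index=False)


def plot_quality_profile(reads: Sequence[Read], path, threshold: float = 20.0):
    """Mean Phred per position across reads, with the threshold line (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not reads:
        raise ValueError("no reads to plot")
    max_len = max(len(r) for r in reads)
    sums = np.zeros(max_len)
    counts = np.zeros(max_len)
    for r in reads:
        q = np.asarray(r.quals, dtype=float)
        sums[: len(q)] += q
        counts[: len(q)] += 1
    mean = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(np.arange(1, max_len + 1), mean, lw=1.5)
    ax.axhline(threshold, color="red", ls="--", lw=1, label=f"Phred {threshold:g}")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("mean Phred quality")
    ax.set_ylim(0, 45)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
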