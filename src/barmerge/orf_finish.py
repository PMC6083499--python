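"""Stop-codon and frameshift correction for coding barcodes.

Barcode amplicons from coding regions (COI, rbcL, matK, ...) must be
stop-free and in frame before database submission.  The finishing stage
orients the consensus to the forward read, translates it in all six
frames, picks the frame holding the longest stop-free amino-acid run, and
trims everything outside that run, bounding stop codons included.  An
initiating ATG is deliberately NOT required: amplicons are internal gene
fragments and rarely begin at a Met.

Genetic codes are the NCBI tables (1 standard, 2 vertebrate mitochondrial,
5 invertebrate mitochondrial — needed for COI — and 11 bacterial), taken
from Biopython.  Any codon containing an N translates to 'X', never to a
stop, so uncertain bases cannot trigger trimming.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from Bio.Data import CodonTable as _BioCodonTable

from .io_seq import Read, reverse_complement

FRAMES = (1, 2, 3, -1, -2, -3)
SUPPORTED_TABLES = (1, 2, 5, 11)


@dataclass(frozen=True)
class CodonTableSpec:
    """An NCBI genetic-code table with the package's N-codon policy."""

    table_id: int = 1
    codon_map: Dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        table = _BioCodonTable.unambiguous_dna_by_id[self.table_id]
        mapping = dict(table.forward_table)
        for stop in table.stop_codons:
            mapping[stop] = "*"
        if len(mapping) != 64:
            raise ValueError(f"table {self.table_id}: incomplete codon map")
        object.__setattr__(self, "codon_map", mapping)

    def translate_codon(self, codon: str) -> str:
        if len(codon) != 3:
            raise ValueError(f"not a codon: {codon!r}")
        aa = self.codon_map.get(codon)
        return aa if aa is not None else "X"

    def translate(self, nt: str) -> str:
        return "".join(
            self.translate_codon(nt[i : i + 3])
            for i in range(0, len(nt) - len(nt) % 3, 3)
        )


@dataclass(frozen=True)
class FrameCorrection:
    """Outcome of six-frame analysis of one consensus sequence.

    Coordinates are 0-based half-open on the frame-adjusted sequence (the
    oriented consensus, reverse-complemented first for negative frames).
    ``credible`` is False when the best stop-free run was shorter than the
    minimum and the sequence was passed through untrimmed.
    """

    chosen_frame: int
    orf_start: int
    orf_end: int
    corrected_nt: str
    corrected_aa: str
    stops_found: Dict[int, int]
    credible: bool = True
    was_reverse_complemented: bool = False


def orient_to_forward(consensus: Read, fwd_read: Read, k: int = 16) -> Tuple[Read, bool]:
    """Return the consensus in the forward read's sense.

    Orientation is decided by shared k-mer counts between the forward read
    and each strand of the consensus; if neither strand shares a k-mer the
    consensus is returned unchanged with a warning.
    Returns ``(read, was_reverse_complemented)``.
    """
    if len(consensus) == 0 or len(fwd_read) == 0:
        raise ValueError("both sequences must be non-empty")

    def kmers(s: str) -> set:
        return {s[i : i + k] for i in range(len(s) - k + 1)}

    fwd_k = kmers(fwd_read.seq)
    as_is = len(kmers(consensus.seq) & fwd_k)
    rc = reverse_complement(consensus)
    flipped = len(kmers(rc.seq) & fwd_k)
    if as_is == 0 and flipped == 0:
        warnings.warn(
            f"{consensus.id}: orientation undetermined (no shared {k}-mer "
            "with the forward read); leaving as-is",
            stacklevel=2,
        )
        return consensus, False
    if flipped > as_is:
        return rc, True
    return consensus, False


def translate_six_frames(nt: str, t: CodonTableSpec = CodonTableSpec()) -> Dict[int, str]:
    """Translate frames +1/+2/+3 of ``nt`` and of its reverse complement.

    Frame +n reads from offset n-1; trailing 1-2 nt are dropped.
    """
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    rc = reverse_complement(Read("", nt, [0] * len(nt))).seq
    frames = {}
    for f in (1, 2, 3):
        frames[f] = t.translate(nt[f - 1 :])
        frames[-f] = t.translate(rc[f - 1 :])
    return frames


def _longest_stop_free_run(aa: str) -> Tuple[int, int]:
    """(start, end) of the longest '*'-free run, earliest on ties."""
    best = (0, 0)
    start = 0
    for i, c in enumerate(aa + "*"):
        if c == "*":
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = i + 1
    return best


def select_frame(frames: Dict[int, str]) -> Tuple[int, int, int]:
    """Frame with the longest stop-free amino-acid run.

    Maximising the intact run simultaneously minimises the impact of the
    stop codons found.  Ties break in frame order +1, +2, +3, -1, -2, -3.
    Returns ``(frame, run_start_aa, run_end_aa)``.
    """
    best_frame = None
    best_run = (0, 0)
    for f in FRAMES:
        run = _longest_stop_free_run(frames[f])
        if best_frame is None or (run[1] - run[0]) > (best_run[1] - best_run[0]):
            best_frame, best_run = f, run
    return best_frame, best_run[0], best_run[1]


def correct_sequence(
    consensus: Read,
    fwd_read: Optional[Read] = None,
    t: CodonTableSpec = CodonTableSpec(),
    min_orf_aa: int = 10,
) -> FrameCorrection:
    """Orient, pick the best frame and trim at the terminal stop codons.

    Everything upstream of the chosen run's first codon and downstream of
    its last codon — the bounding stops included — is removed.  If the best
    run is shorter than ``min_orf_aa`` amino acids the sequence is flagged
    as having no credible reading frame and passed through untrimmed.
    """
    if len(consensus) < 3:
        raise ValueError("consensus shorter than one codon")
    if fwd_read is not None:
        oriented, was_rc = orient_to_forward(consensus, fwd_read)
    else:
        oriented, was_rc = consensus, False

    frames = translate_six_frames(oriented.seq, t)
    stops = {f: aa.count("*") for f, aa in frames.items()}
    frame, run_start, run_end = select_frame(frames)

    if run_end - run_start < min_orf_aa:
        warnings.warn(
            f"{consensus.id}: no credible ORF (best stop-free run "
            f"{run_end - run_start} aa < {min_orf_aa}); passing through untrimmed",
            stacklevel=2,
        )
        return FrameCorrection(
            chosen_frame=frame,
            orf_start=0,
            orf_end=len(oriented),
            corrected_nt=oriented.seq,
            corrected_aa="",
            stops_found=stops,
            credible=False,
            was_reverse_complemented=was_rc,
        )

    source = (
        oriented.seq
        if frame > 0
        else reverse_complement(Read("", oriented.seq, [0] * len(oriented))).seq
    )
    offset = abs(frame) - 1
    nt_start = offset + 3 * run_start
    nt_end = offset + 3 * run_end
    corrected_nt = source[nt_start:nt_end]
    corrected_aa = frames[frame][run_start:run_end]
    assert "*" not in corrected_aa and len(corrected_nt) == 3 * len(corrected_aa)
    return FrameCorrection(
        chosen_frame=frame,
        orf_start=nt_start,
        orf_end=nt_end,
        corrected_nt=corrected_nt,
        corrected_aa=corrected_aa,
        stops_found=stops,
        credible=True,
        was_reverse_complemented=was_rc,
    )
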