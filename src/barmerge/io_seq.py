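"""FASTQ/FASTA input-output and elementary sequence operations.

A :class:`Read` is a named nucleotide sequence over ``{A, C, G, T, N}``
with one integer Phred score per base.  On disk, qualities use the
Sanger/Illumina-1.8+ convention (ASCII offset 33); Phred+64 input is not
supported.  Lowercase bases are uppercased on construction and IUPAC
ambiguity codes other than N are mapped to N with a warning, because the
downstream merge algorithm only defines behaviour for N.

Paired input follows the positional contract used throughout the package:
record *i* of the forward file is mated with record *i* of the reverse
file; mate ids are compared only to emit a warning, never to re-pair.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
MAX_PHRED = 93

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")
_AMBIG = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVryswkmbdhv"}
)

PathLike = Union[str, Path]


class FastqParseError(ValueError):
    """A malformed FASTQ record, reported with its 1-based index."""


def _normalize_seq(seq: str) -> str:
    s = seq.upper().translate(_AMBIG)
    if not _VALID_BASES.issuperset(s):
        bad = sorted(set(s) - _VALID_BASES)
        raise ValueError(f"invalid sequence characters: {bad}")
    return s


@dataclass(frozen=True)
class Read:
    """A named nucleotide sequence with per-base Phred qualities."""

    id: str
    seq: str
    quals: tuple

    def __init__(self, id: str, seq: str, quals: Sequence[int]):
        norm = seq.upper()
        if not _VALID_BASES.issuperset(norm):
            warnings.warn(
                f"read {id!r}: ambiguity codes outside ACGTN mapped to N",
                stacklevel=2,
            )
            norm = _normalize_seq(norm)
        q = tuple(int(x) for x in quals)
        if len(norm) != len(q):
            raise ValueError(
                f"read {id!r}: sequence length {len(norm)} != "
                f"quality length {len(q)}"
            )
        if q and not all(0 <= x <= MAX_PHRED for x in q):
            raise ValueError(f"read {id!r}: Phred scores must be in [0, {MAX_PHRED}]")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "seq", norm)
        object.__setattr__(self, "quals", q)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0

    def slice(self, start: int, stop: int) -> "Read":
        """Contiguous sub-read, qualities carried along (0-based half-open)."""
        return Read(self.id, self.seq[start:stop], self.quals[start:stop])


@dataclass(frozen=True)
class ReadPair:
    """A forward/reverse mate pair; both reads must be non-empty."""

    forward: Read
    reverse: Read

    def __post_init__(self):
        if len(self.forward) == 0 or len(self.reverse) == 0:
            raise ValueError("both mates of a ReadPair must be non-empty")


def reverse_complement(r: Read) -> Read:
    """Watson-Crick reverse complement; qualities are reversed, id kept."""
    return Read(r.id, r.seq.translate(_COMPLEMENT)[::-1], r.quals[::-1])


def _open_text(path: PathLike, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: PathLike) -> Iterator[Read]:
    """Yield reads from a 4-line Phred+33 FASTQ file (gzip ok by extension).

    Malformed records (sequence/quality length mismatch, missing '@'/'+'
    markers) raise :class:`FastqParseError` naming the 1-based record index.
    """
    index = 0
    with _open_text(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(
                    f"{path}: malformed FASTQ at record {index + 1}: {exc}"
                ) from exc
            index += 1
            quals = [ord(c) - PHRED_OFFSET for c in qual]
            if any(q < 0 or q > MAX_PHRED for q in quals):
                raise FastqParseError(
                    f"{path}: record {index}: quality characters outside "
                    f"Phred+33 range"
                )
            yield Read(title.split()[0] if title else "", seq, quals)


def _mate_stem(read_id: str) -> str:
    for suffix in ("/1", "/2", "_1", "_2", ".1", ".2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def pair_streams(fwd_path: PathLike, rev_path: PathLike) -> list:
    """Pair the two files positionally (record i with record i).

    Ids are NOT used for matching; differing ids at the same index only
    produce a single summary warning.  Unequal record counts are an error
    reporting both counts.
    """
    fwd = list(read_fastq(fwd_path))
    rev = list(read_fastq(rev_path))
    if len(fwd) != len(rev):
        raise ValueError(
            f"unequal record counts: {len(fwd)} != {len(rev)} "
            f"({fwd_path} vs {rev_path})"
        )
    mismatched = sum(
        1 for f, r in zip(fwd, rev) if _mate_stem(f.id) != _mate_stem(r.id)
    )
    if mismatched:
        warnings.warn(
            f"{mismatched} of {len(fwd)} pairs have differing mate ids; "
            "pairing is positional and proceeds anyway",
            stacklevel=2,
        )
    return [ReadPair(f, r) for f, r in zip(fwd, rev)]


def write_fastq(reads: Iterable[Read], path: PathLike) -> None:
    """Write reads as 4-line Phred+33 FASTQ."""
    with _open_text(path, "wt") as out:
        for r in reads:
            if any(q > MAX_PHRED for q in r.quals):
                raise ValueError(
                    f"read {r.id!r}: quality above {MAX_PHRED} cannot be "
                    "encoded in Phred+33"
                )
            qual = "".join(chr(q + PHRED_OFFSET) for q in r.quals)
            out.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_fasta(reads: Iterable[Read], path: PathLike, width: int = 70) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    if width < 1:
        raise ValueError("width must be >= 1")
    with _open_text(path, "wt") as out:
        for r in reads:
            out.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                out.write(r.seq[i : i + width] + "\n")
            if not r.seq:
                out.write("\n")


def read_fasta(path: PathLike) -> Iterator[Read]:
    """Yield FASTA records as reads with a flat placeholder quality (40)."""
    name = None
    chunks: list = []
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seq = "".join(chunks)
                    yield Read(name, seq, [40] * len(seq))
                name = line[1:].split()[0] if len(line) > 1 else ""
                chunks = []
            elif name is not None:
                chunks.append(line.strip())
        if name is not None:
            seq = "".join(chunks)
            yield Read(name, seq, [40] * len(seq))
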