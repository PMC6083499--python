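# Methods

This note documents the models and procedures implemented in `barmerge`,
the parameters that matter, the choices made where the design was open,
and what the synthetic fixtures do and do not establish about real data.

## Quality trimming and filtering (`qc`)

Trimming slides a window of `window` bases (default 10) in steps of `step`
(default 1) from the 5' end: while the window's arithmetic-mean Phred
quality is below `min_window_mean_qual` (default 20), the cursor advances
and those bases are dropped; the pass stops at the first window meeting
the threshold. The same pass then runs from the 3' end of the remainder.
When fewer than `window` bases remain, the whole remainder is one window.
Threshold tests are strict "below": a window (or read) at exactly mean
20.0 passes. Filtering then discards trimmed reads shorter than
`min_length` (default 50 bp, checked first) or with overall mean quality
below `min_mean_qual` (default 20). Phred 20 corresponds to a 1% base-call
error probability, which is where the defaults come from.

Trimming is idempotent: the 5'-stopping window is unchanged by the 3' cut
whenever the survivor is at least one window long, and a shorter survivor
is exactly the final passing (truncated) window of the 3' pass, so a
second pass always stops immediately. The test suite pins the exact
semantics against a brute-force scan over every window position.

Reads that fail QC are written to `rejected` files rather than dropped, so
problem barcodes can be inspected and re-sequenced; the quality report
lists, per read, the count and fraction of bases below a chosen Phred
threshold and flags reads with more than 10% such bases.

## Overlap merging (`merge_core`)

### Anchoring

A seed of `seed_length` bases (default 16) is taken from the 3' end of the
forward read and searched as an exact substring of the oriented reverse
read; on a miss the seed window slides `seed_step` (default 12) toward the
5' end, stopping when it would leave the read. The merger
reverse-complements the reverse read first (both BOLD reverse traces and
Illumina R2 are opposite-strand); if no seed is found it retries against
the un-complemented read, so pre-oriented input also works. When the seed
occurs more than once in the mate, the leftmost occurrence is used — a
deterministic rule; multi-hit seeds essentially only arise in repeats,
where no placement is defensible without external information.

### Column scan

The seed fixes which positions of the two reads face each other; the
implied overlap is scanned 5'→3':

1. equal bases score an identity; `N` is treated as compatible with
   anything (the consensus stage resolves it, so scanning does not
   penalise it);
2. on a mismatch, if the next `tolerance` columns (default 5) all match,
   one substitution is charged and the scan advances;
3. otherwise gap columns are inserted at the site — `g = 1..repeat`
   (default 4) columns, tried in the reverse read first and then the
   forward read at each `g` — and accepted as soon as the look-ahead
   after the inserted gaps matches. A base aligned to a gap scores an
   identity; all gap columns at one site count as a single gap opening;
4. if no placement up to `repeat` gaps satisfies the look-ahead, the
   insertions are rolled back and a single substitution is charged. This
   bounds gap chains and prevents the pathology of connecting two
   non-overlapping reads with a wall of gaps.

Near the overlap's 3' end the look-ahead compares only the remaining
columns (all must match); an empty look-ahead passes vacuously, so no
spurious gaps are opened at the boundary.

The overlap "length" used for acceptance is the number of alignment
columns, gap columns included — the same denominator as the identity
fraction, which keeps identity ≤ 1 by construction. A merge is accepted
iff columns ≥ `min_overlap` (25), identity ≥ `min_identity` (0.90) and
gap openings ≤ `max_gap_openings` (5), all thresholds inclusive.
Rejection reasons are checked in that order.

### Consensus

The consensus is the forward read's unmatched 5' tail, the per-column
overlap consensus, and the reverse read's unmatched 3' tail. Per column:
equal bases keep the maximum of the two qualities; a true mismatch keeps
the higher-quality base (forward read on ties — deterministic); a base
beats a gap and keeps its quality; an `N` defers to the other read's
base; two `N`s stay `N` at the maximum quality. Consensus length is
`len(fwd) + len(rev) − overlap_columns + gap_columns`, which the suite
asserts on simulated data.

### Known limitations

The scan is greedy. In low-complexity context (period-1 or period-2
repeats spanning the look-ahead window) both gap placements can satisfy
the look-ahead and the scan may place a gap on the wrong side, costing an
extra gap opening relative to the optimal alignment — which is itself
ambiguous there. The oracle-equivalence tests therefore construct
overlaps whose indels sit in unambiguous context; on such instances the
scan's substitution and gap-opening counts equal an optimal unit-cost
dynamic-programming alignment exactly. Identity is counted over columns;
counting over forward-read bases would differ in gapped overlaps.

## ORF finishing (`orf_finish`)

"Largest ORF" is operationalised as the longest stop-free amino-acid run,
with no requirement for an initiating ATG: barcode amplicons are internal
gene fragments, and demanding a Met would truncate valid rbcL/COI
sequences. Maximising the intact run also minimises the impact of the
stop codons found — the two frame-selection readings coincide under this
rule. Ties break in frame order +1, +2, +3, −1, −2, −3. Trimming removes
everything outside the run, bounding stop codons included. A best run
shorter than `min_orf_aa` (default 10) is flagged "no credible ORF" and
the sequence passes through untrimmed with a warning rather than being
shredded.

Orientation against the forward read uses shared 16-mer counts on both
strands; an undetermined orientation warns and leaves the sequence as-is.
Genetic codes ship for NCBI tables 1 (standard), 2 (vertebrate
mitochondrial), 5 (invertebrate mitochondrial — required for COI) and 11
(bacterial). Any codon containing an `N` translates to `X`, never to a
stop, so an uncertain base can neither create nor destroy a trim point;
this is deliberately stricter than ambiguity-resolving translation (which
would render e.g. GGN as Gly).

Note that on very short sequences the longest stop-free run is frequently
in an unintended frame purely by chance (a 5-codon fragment's reverse
frames are usually stop-free); frame selection is only meaningful when
the true open frame is substantially longer than the ~21-codon run
expected between random stops.

## Read simulation (`simgen`)

The Illumina-like generator emulates a 2×250 bp sequencing of ~400 bp
fragments: fragment lengths are Normal(`frag_mean`=400, `frag_sd`=10),
rounded and redrawn while outside `[read_length, 2·read_length −
min_overlap_floor]` so every pair genuinely overlaps; starts are uniform
on the reference. R1 is the fragment's first 250 bases, R2 the reverse
complement of its last 250. Per-base Phred scores follow a monotone
MiSeq-like curve — mean 37 at cycle 1 decaying linearly to 30 at cycle
250, Gaussian jitter sd 3, floored at 2 and capped at 40; this is the
fixture definition, not a claim about any instrument. Substitutions are
injected with the quality-implied probability `10^(−q/10)` (times
`sub_rate_scale`); single-base insertions and deletions occur at a flat
`indel_rate` (default 10⁻⁴) per template position. Every injected event
is recorded, and replaying the event list onto the fragment reproduces
each read byte-exactly — the truth contract the tests assert.

The Sanger-like generator produces one long forward and one long reverse
read (500–700 bp drawn, capped at the template length) covering a
400–900 bp template from opposite ends, with a low–high–low quality ramp
so end trimming is exercised, quality-implied substitutions, and `N`
injected at 20% of sub-Phred-20 positions — mimicking conservative
basecalling that emits `N` on ambiguous trace signal. `clean=True` gives
flat maximum-quality error-free reads for end-to-end identity checks.

What the generator does not emulate: empirically-learned platform error
profiles (motif-dependent errors, quality mis-calibration), adapter
read-through, chimeras, or trace artefacts. Passing the synthetic suite
shows the algorithms are correct under their stated error model, not that
real-data merge rates will match: real MiSeq data has a heavier, less
quality-faithful error tail, so identity and mismatch statistics here are
correspondingly better than published benchmarks on ART-simulated E. coli
reads (99.9% vs ~97.5% identity; the merged fraction and length
statistics are directly comparable).

## Evaluation (`evalign`)

Merged sequences are scored by the best local alignment against either
strand of the reference, using match +1, mismatch −1, gap open −2, gap
extend −0.5 — chosen to approximate megablast-style behaviour on
near-identical sequences; counts from other aligners may differ slightly,
which the report header discloses. A k-mer index (k=20) pre-locates each
query so the dynamic program only runs on a short reference window;
queries with no k-mer hit or alignment score below 20 are counted as
unaligned and excluded from the means. Summary statistics (merged %, mean
± SD length and identity, mean mismatches and gap openings) are over
merged pairs only, with sample (ddof=1) standard deviations.

## Problem sizes and determinism

The shipped checks run at desk scale, chosen to finish in minutes on one
CPU: 1,000 zero-error pairs for exact recovery; 10,000 pairs from a 1 Mb
random reference for the merge benchmark; 500 constructed overlaps for
oracle equivalence; 1,000 random quality strings for the trim oracle; 100
coding-sequence constructions for frame recovery. All randomness flows
from explicit integer seeds (NumPy `default_rng`); the pipeline writes no
timestamps, so identical inputs and parameters give byte-identical
outputs. `scripts/acceptance.py --seed N --out f.json` recomputes every
reported quantity from scratch under seed `N`.

## Interface decisions

Only Phred+33 FASTQ is read or written; Phred+64 input is rejected rather
than auto-detected. Pairing is positional (record *i* with record *i*);
differing mate ids warn but never re-pair. IUPAC ambiguity codes other
than `N` are mapped to `N` on input with a warning, since the merge rules
are defined only for `N`. Merged reads are emitted both as FASTA (the
pipeline's final barcode output) and as FASTQ carrying the consensus
qualities; unmerged pairs pass through as FASTQ. A pair enters merging
only when both mates survive QC — merging a survivor against a discarded
mate would manufacture sequence from rejected evidence.
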