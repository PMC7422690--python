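# Methods

## Scope and model

`amplitag` treats multiplexed amplicon sequencing as four coupled
combinatorial problems: (1) find a set of fixed-length ACGT barcodes that are
individually safe to attach to a primer and mutually distinguishable; (2) lay
samples out on the forward × reverse tag grid so that tag jumps are
observable; (3) assign merged reads to samples by exact tag matching; (4)
clean and summarize the resulting OTU × sample table.  All sequence screens
operate on IUPAC expansion sets: two codes are *compatible* when their sets
intersect, and they *pair* when one intersects the complement set of the
other.  Degenerate positions therefore pair worst-case, which makes every
screen conservative.

## Oligo screens

* **Homopolymer / composition.**  Longest literal run; per-base counts and GC
  fraction.  "Balanced content" is quantified as each base appearing 1–3
  times in an 8-mer and GC ∈ [0.375, 0.625] (i.e. 3–5 of 8); "no
  homopolymers" as runs ≤ 2.  Both are configurable on `DesignConstraints`.
* **Duplex scan.**  One oligo is slid against the reverse complement of the
  other over all ungapped offsets; the report carries the longest compatible
  complementary run, the longest run anchored at a 3' terminus of either
  oligo (where polymerase extension starts), and the best offset.  Scoring is
  match-count based — no nearest-neighbour ΔG model — because the design
  procedure is combinatorial and a thermodynamic model would import large
  parameter tables without adding decision power at these lengths.  Defaults
  reject a candidate at max run ≥ 6 or 3'-anchored run ≥ 4, common primer-QC
  practice.
* **Hairpin scan.**  Existence of two non-overlapping stretches of length
  ≥ `stem_min` (default 4) that pair antiparallel around a loop of
  ≥ `loop_min` (default 3) unpaired bases.  The tagged oligo
  (barcode + primer) is screened, so stems inside the primer alone also
  reject; both printed second-round primers are hairpin-free at these
  thresholds, which leaves the decision to the barcode.
* **Consensus.**  Majority-rule IUPAC consensus: per column, every base with
  frequency ≥ (1 − threshold) among non-gap characters is retained (degenerate
  characters contribute fractionally); columns ≥ 50% gaps are dropped; if no
  base reaches the cutoff the modal base(s) are kept.  The default threshold
  0.5 reproduces a planted degenerate primer exactly when its expansion bases
  are balanced across sequences.

A noteworthy empirical consequence of worst-case degenerate pairing: the
printed reverse primer `AAGARGAYATCCTTGGTG` is self-complementary over 10
bases (R/Y on both sides of the pairing), so the cross-combination screen
reports every rv × rv tagged pair on the real primers.  This is a property
of the primer, not of any barcode; the screen is still useful for comparing
candidate barcodes and for primers without that feature, and the tests
exercise both a passing and a failing configuration on constructed oligos.

## Barcode selection

Candidates are the composition/homopolymer survivors of all 4^L words
(enumeration is refused above L = 12).  The design pipeline walks them in
seed-shuffled order, applies the structure and flank screens lazily, and
greedily accretes barcodes at pairwise Hamming distance ≥ 3 until the target
size (default 18) is reached — equivalent to greedy selection over the fully
screened pool in the same order, but roughly two orders of magnitude
cheaper.  Hamming distance (not edit distance) is the right metric because
barcodes are fixed-length and matching is exact.

The standalone `select_set` solves pools of ≤ 20 candidates *exactly*
(branch-and-bound maximum compatible subset) and falls back to seed-shuffled
greedy above that.  Exact search at small scale costs nothing and removes
the pathological cases where greedy picks a "hub" candidate that blocks two
mutually compatible ones; the test suite pins greedy-vs-exhaustive equality
on random pools of ≤ 15.

`validate_set` re-derives every invariant (alphabet, length, distinctness,
distance, composition, structure, optional flank) independently of how a set
was built and names the worst offender per failed check.

## Tag schemes

With F forward and R reverse tags and n samples, the builder places sample k
at row k mod F, column (k + ⌊k / lcm(F,R)⌋) mod R.  This diagonal-band
construction is injective for n ≤ F·R and keeps every row and column usage
within one of the balanced value; the seed enters by relabelling rows and
columns with random permutations, which preserves both properties.  A
Latin-square-flavoured deterministic rule was preferred over randomized
search because balance is then provable rather than heuristic.  *Mistag
exposure* — the fraction of grid cells that are unused while their row and
column both serve samples — is the quantity the unused combinations buy; for
150 samples on 18 × 18 it is ≈ 0.54.

## Merging and demultiplexing

The paired-read merger finds the best ungapped overlap of read 1 against the
reverse complement of read 2 (largest overlap with mismatch fraction ≤ 0.1,
ties to fewer mismatches), resolving disagreements toward the higher-quality
base.  A 16-nt exact seed is tried before the exhaustive offset scan, which
keeps merging linear-time on clean data.  The merger exists so the pipeline
runs end to end; it does not model quality trimming, and no sequencing-error
profile is simulated.

Filters use strict-less-than removal semantics throughout: merged length
< 300 bp, overlap < 100 bp, sample yield < 10,000 reads, cluster abundance
< 0.01% of all reads — equality is always kept, and the e-value gate keeps
hits exactly at 1e-50.

Tag matching is exact: the 5' end must equal a forward barcode literally and
the attached primer up to IUPAC compatibility at its degenerate positions; the
3' end must equal the reverse complement of a reverse barcode + primer; N in
the read never matches.  Reads failing forward orientation are retried
reverse-complemented (library orientation is random for ligation-based
preps).  Both tags valid + assigned cell → the sample (tags and primers
trimmed); both valid + unused cell → mistag; anything else → unassigned.
Every read lands in exactly one of assigned / mistag / unassigned /
too_short / low_overlap.

## OTU-table post-processing

Best-hit parsing keeps, per query, the row with minimal e-value (ties:
higher identity, then first occurrence).  Non-target removal keeps OTUs
whose phylum is Cercozoa or Endomyxa.  Trait annotation walks species →
genus → family → order → class and stops at the first rank present in the
trait table; unmatched OTUs stay "unknown" and are never imputed; the rank
used is recorded.  Guild percentages support two weightings — by reads and
by OTU counts — because published community summaries use both conventions;
the output is labelled with the weighting that produced it.  Diversity is
computed in nats (H = −Σ pᵢ ln pᵢ) so that Pielou's J = H / ln S is the
natural normalization; J is defined as 0 for S ≤ 1, and Bray–Curtis is
undefined (raises) when both vectors are zero.  `rare_filter` accepts an
optional reference total so the 0.01% cutoff can be taken on the full read
pool regardless of filter order, making it commute with taxonomy filtering.

## Synthetic data

The generator is the package's study-conditions module, not a test utility.
Defaults, chosen once: desk-scale runs of 12 samples × 1,000 reads on the
18 × 18 grid (study scale, 150 samples and ~30k reads/sample, is a
parameter choice away and used where the planted value is itself
study-scale, e.g. 1,712 shared OTUs out of 2,101); log-normal OTU abundances
(σ = 1.5), the standard skewed-community stand-in; tag-jump rate ρ = 0.01,
the magnitude typically reported for dual-indexed libraries; random amplicon
orientation; insert lengths 260–340 nt so that clean 2 × 250 nt pairs merge
to 313–393 bp with 107–187 bp overlaps — inside the length/overlap gates, so
every filtered read is one the simulation planted.  Mistags are independent
single-tag swaps, uniform over the *used* tags of that side, the simplest
model consistent with tag jumping; per-read truth (sample, swap side,
landing-cell status, truncation) and all rates live in a manifest that fully
determines regeneration (same seed → byte-identical reads).

The OTU-table generator plants ecosystem occupancy (shared / G-only /
F-only by largest-remainder rounding, presence forced with ≥ 1 read),
guild labels drawn exactly from the requested mixture (default: ~50%
bacterivores, 23% omnivores, 10% eukaryvores, 5% plant parasites, 0.8%
hyperparasites of Oomycota, rest unknown), a 75/25 Cercozoa/Endomyxa split,
and an optional non-target fraction.  Because labels and occupancy are
planted exactly, OTU-weighted summaries recover them exactly; read-weighted
summaries vary with the abundance draws.  What passing tests show is that
the estimators recover what the generator planted under these models; they
say nothing about PCR chimeras, sequencing error, or clustering artefacts,
which are out of scope.

## Numerical and boundary choices

* All thresholds are reject-at-`≥` for duplex runs and remove-at-`<` for
  length/abundance filters, mirroring the stated rules; equality retained.
* Seeds: Python `random.Random(seed)` for shuffles, `numpy.default_rng(seed)`
  for draws; every public entry point takes an explicit seed and is
  reproducible bit-for-bit.
* Ties in best-hit parsing and exact subset search resolve to first
  occurrence / lexicographically earliest, so outputs are order-stable.
* `consensus` never emits a blank column: if no base clears the cutoff the
  modal base(s) are used.

## Known limitations

* No thermodynamic folding or melting temperatures; the structure screens
  are combinatorial stand-ins for dedicated oligo-QC tools and their
  thresholds are conventions, not fitted values.
* The merger and matcher assume error-free tags; real data with tag
  sequencing errors loses those reads to `unassigned` by design (no
  error-correcting decoding).
* The mistag model ignores the possibility of both tags jumping at once and
  of jump rates depending on tag identity.
* OTU clustering, chimera detection, ordination and inferential statistics
  on environmental drivers are out of scope.
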