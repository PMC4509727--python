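# Methods

This note documents the models and procedures implemented in pollenpipe,
the parameters that matter, the numerical choices, and what the simulator
does and does not emulate.

## Oligo scaffold and QC

A sample's amplification oligo is a pure concatenation
`adapter ∥ index(8) ∥ pad(10) ∥ linker(2) ∥ amplifying primer`; the
pad+linker+primer region doubles as the custom sequencing primer (Read1 /
Read2) and the index-read primer is the base-wise reverse complement of
Read2. The built-in `ITS2_SCAFFOLD` carries the published ITS2 design
(Illumina P5/P7 adapters, modified pad `CCTGGTGCTG`, ITS-S2F/ITS4R primers);
both of its read regions are 32 nt at 50% GC.

Three melting-temperature models are provided:

* `wallace` — 2(A+T) + 4(G+C); rule of thumb for ≤14-mers (a warning is
  logged for longer inputs).
* `marmur_doty` (default) — 64.9 + 41·(GC − 16.4)/len. On the 32-nt read
  regions it gives 64.39 °C; design documentation for this scaffold quotes
  64.8 °C without naming the formula used, so the package treats "within
  2 °C of 65" as the design criterion rather than chasing an unreproducible
  third digit.
* `nearest_neighbor` — Biopython's unified nearest-neighbour thermodynamics
  (SantaLucia unified parameter table) with a monovalent-salt correction;
  defaults 50 mM Na⁺, 250 nM total strand concentration.

Dimer QC defines "longest dimer complement" as the longest *contiguous*
antiparallel Watson–Crick complementary stretch, computed as the longest
common substring between one sequence and the reverse complement of the
other (self-dimer: the sequence against itself). G·T wobble pairs are not
counted — the simplest definition, and the one consistent with the 4 bp
value the built-in design exhibits. Both self- and cross-pairings are
reported, since a single quoted "longest dimer" number could refer to
either.

## Demultiplexing

A read pair is assigned to the unique sample whose (forward, reverse) index
pair it matches with at most `max_mismatch` Hamming mismatches per index —
default 0, matching the perfect-match-only policy of on-instrument
demultiplexers. Under relaxed matching, a pair within tolerance of two
different samples is *undetermined*, never nearest-matched: with error
rates high enough to need mismatch tolerance, a forced nearest assignment
would silently convert index errors into sample bleed-through. `N` bases in
index reads count as mismatches (instrument behaviour here is
undocumented; mismatch is the conservative reading). An optional flag
reverse-complements the i5 read to accommodate the two MiSeq chemistry
dialects, and index reads can come from I1/I2 FASTQ files or a
Casava-style `<i1>+<i2>` header token (auto-detected by which inputs are
supplied). Counts always satisfy Σ per-sample + undetermined = total.

## Merging and filtering

Merging reverse-complements the reverse read (reversing its qualities) and
scans every overlap length L ≥ `min_overlap` between the forward read's
suffix and the reverse-complemented read's prefix. Internally all L are
evaluated at once via the anti-diagonals of the pairwise equality matrix.
The candidate minimising mismatch *fraction* wins, ties going to the larger
L (favouring the biologically real long overlap over short spurious exact
matches); it is accepted iff fraction ≤ `max_mismatch_frac`. Defaults
min_overlap = 6 and max_mismatch_frac = 0.08 follow the defaults of the
widely used overlap-joining tools. Consensus: agreeing positions keep the
max quality; disagreeing positions keep the higher-quality base with
quality |q1−q2|, floored at 2 and capped at Q41 to stay within printable
Phred+33. Reads shorter than `min_overlap` fail as `no_overlap`; an
over-threshold best candidate fails as `too_many_mismatches`.

The quality filter discards reads shorter than 150 nt, with mean Phred
below 20, or containing any non-ACGT base (in that order of reporting).
"<Q20" is interpreted as *mean* quality — the most literal reading when the
exact filtering command is unspecified; the filter is idempotent.

## Reference databases

Lineages use seven fixed ranks (kingdom, phylum, class, order, family,
genus, species), selected off the root-ward path of an NCBI-style taxonomy
tree; intermediate ranks (subfamily, tribe) and unranked nodes are skipped.
Missing ranks become `unclassified_<nearest named ancestor>`, so no named
rank sits below an unnamed one; normalization is idempotent. Name
sanitation replaces `; , : * <tab>` with `_` because those characters
delimit the serialization dialects. Writers/readers are mutual inverses on
sanitized content; the RDP taxonomy file contains exactly one node per
distinct lineage prefix plus Root. Sequence retrieval and marker extraction
are out of scope — the builder consumes pre-extracted FASTA plus an
id→taxid map and a taxonomy tree; multiple sequences per species are all
kept (de-duplication policy is left to the database curator). Checklist
coverage is case-insensitive exact name matching at a chosen rank.

## Classifier

The naive-Bayes model is described in the README and
`pollenpipe/classify.py`. Choices worth recording:

* **Distinct words, not multiplicities**, are scored, following the
  canonical rRNA-classifier formulation; k = 8 by default.
* **Leaves** are full seven-rank lineages (usually species); ties in the
  arg-max break to the lexicographically smallest leaf key for
  determinism.
* **Bootstrap** draws ⌊W/8⌋ of the read's W distinct words with replacement
  per trial (divisor configurable), 100 trials by default; per-rank
  agreement with the full-word winner is the confidence. A cumulative-min
  pass from kingdom down enforces non-increasing reported confidences
  (raw bootstrap fractions can be non-monotone by noise).
* **Per-read RNG** is seeded from (global seed, CRC32 of the read id), so
  per-read results — and hence whole tables — are independent of read
  order and reproducible for a given seed.
* **Raw score** is the winner's mean log-likelihood per scored word. The
  min_raw_score cutoff (default −20) reproduces the *semantics* of the
  raw-score floors other amplicon classifiers apply — a read scoring below
  the floor keeps only its kingdom — but its numeric scale is this model's
  own: scores from proprietary scoring functions (e.g. a "cut-off at 20")
  are not comparable and no equivalence is claimed. −20 is far below the
  scores of any read with genuine database signal (in-domain reads score
  around −1 to −8) and catches only degenerate no-signal queries; the
  bootstrap confidence cutoff (default 0.80, the classical default) does
  the real work of truncating uncertain ranks.
* Words absent from the training data are ignored when scoring a query; a
  query sharing no word with the database is reported unclassified below
  kingdom with raw score −∞.

## Community matrix and filters

Taxa are keyed by the full lineage (not the deepest name) to keep homonyms
apart. Cell (t, s) counts reads of sample s assigned to taxon t, so column
sums equal per-sample assigned reads and the matrix conserves the total.
The rare-taxon filter zeroes entries below `rare_frac` (default 0.1%) of
the sample's total, *strict* inequality (exactly 0.1% is kept), evaluated
in a single pass against the original column sums — not iterated to a
fixed point, the most literal reading of "taxa accounting for less than
0.1% of sample reads". The depth filter drops samples with fewer than
2,000 reads. Pipeline default order is rare-filter → depth-filter; both
functions are independent so the other order is available. Rank summaries
sum counts within a rank across a sample group, convert to shares of the
group total (descending, ties lexicographic), and fold the tail into
"other" so shares always total 1.

## Rarefaction

The analytic curve uses the exact hypergeometric expectation with
log-gamma binomial ratios (agreement with rational-arithmetic enumeration
to <1e-9 on toy cases; stable for counts far beyond factorial overflow).
Monte-Carlo mode permutes the read pool per replicate and takes nested
prefixes for all depths, so analytic and Monte-Carlo curves are directly
comparable (they agree within 3 standard errors in tests). Curves are
computed on rare-filtered counts by default — filtering first can only
lower expected richness — with raw mode available. The default depth grid
is 50 log-spaced points from 1 to the sample total, capped at 5,000 (the
depth region where runs of this design saturate). Saturation depth is the
smallest depth reaching 99% (configurable) of the final expected richness.

## Simulator

The simulator defines the package's study conditions:

* **Reference set**: one random root sequence mutated down a 4-level tree,
  default 5 orders × 2 families × 2 genera × 2 species = 40 species in 20
  genera. Per-descent substitution fractions: order 0.15, family 0.08,
  genus 0.05, species 0.02 — chosen so that congeneric species differ by a
  few percent and genera by ~10%, the regime typical of ITS2. Species
  sequences are truncated to lengths drawn uniformly from 350–480 nt, the
  amplicon-length range of this marker, so merge overlaps vary (20–150 nt
  at 250-nt reads).
* **Communities**: species drawn without replacement with log-normal
  (σ = 1) relative abundances — skewed, like real pollen loads — apportioned
  to integer counts by largest remainder, summing exactly to
  `reads_per_sample` (default 5,000, the depth at which such runs
  saturate).
* **Reads**: 250 nt from each template end (reverse read
  reverse-complemented), independent per-base substitution errors at 1%
  default, qualities decaying linearly Q38→Q25 (mean well above the Q20
  filter, so filter behaviour is exercised by injected low-quality reads in
  tests rather than by default attrition). Index reads are exact unless an
  index error rate is set. Substitution-only (no indels) by design: it
  keeps the true merge overlap analytic so merged lengths can be checked
  exactly; indel and chimera simulation, PCR bias and trained MiSeq error
  profiles are out of scope.
* All randomness flows from one seed; reruns are byte-identical.

Passing end-to-end tests on these simulations demonstrates internal
consistency of the pipeline (demultiplexing, merging, classification and
aggregation recover a known truth under idealised errors). They do not
demonstrate accuracy on real MiSeq data, where error structure, chimeras,
incomplete reference coverage and marker copy-number variation add noise
the simulator does not model.

## Problem sizes used in checks

The bundled checks run a 20-genus / 40-species database with
5,000-read samples (8 samples for the end-to-end run, matching one pool's
worth of index combinations per row of a 96-well layout at small scale) and
10,000 Monte-Carlo replicates on the toy rarefaction case; these sizes make
every statistical criterion decidable while keeping a full run in tens of
seconds on one CPU.
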