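# Methods

## Problem and model

`clonesift` detects somatic variants at very low allele fractions
(down to ~10⁻⁴) in ultra-deep targeted amplicon sequencing of small
genomic regions — the regime of screening blood-cell DNA for small
clonal expansions, e.g. STAT3 SH2-domain mutations in CD8+ T cells. At
these fractions the signal of a real clone is comparable to the error
floor of standard (non-UMI) library preparation and sequencing, so the
caller combines three orthogonal defences:

1. **Dual-strand consensus pileup.** With 2×300 bp paired-end reads over a
   short amplicon, both mates read every template position. A basecall is
   accepted only if the two mates agree exactly and the sum of their Phred
   qualities is at least `min_combined_qual` (default **60**). Independent
   per-mate errors at rate *e* survive concordantly at only ≈ *e*²/3 per
   substitution class; template-level events (real clones, PCR artefacts)
   survive at full rate. What remains for the statistics is therefore
   dominated by template-level signal.

2. **Batch-level between-sample test.** All libraries of one library
   preparation + sequencing batch are analysed together, because
   preparation artefacts repeat across a batch. For every candidate
   (library, position, non-reference allele with ≥ `min_alt_count`
   accepted observations, default 1), the library's reference/alternate
   counts are compared with the summed counts of every other library of
   the batch at that coordinate by a two-sided Fisher exact test. A
   batch-recurrent artefact is present at a similar fraction everywhere
   and cannot reach significance; a clone private to one donor can.

3. **Within-sample noise test and log noise ratio.** For the candidate's
   substitution class X→Y, the library's own background rate ε is the
   summed count of Y at every *other* position whose reference base is X,
   divided by the summed accepted depth there (indel classes pool by
   inserted/deleted length over all positions). The candidate's alternate
   count is tested against Binomial(depth, ε), upper tail only — an
   excess, never a deficit, is evidence of a clone. The log noise ratio
   LNR = log₁₀(VAF / max(ε, ε_floor)) must exceed `lnr_min` (default 1,
   i.e. tenfold above the class noise).

Both p-values are Bonferroni-corrected by the **total number of
candidates enumerated in the batch run** (a shared divisor for both
tests), and a call must satisfy corrected p < 0.001 for both tests plus
LNR > 1, with strict inequalities. These defaults mirror a zero-call
calibration: on pure-noise technical-replicate libraries the pipeline
must produce no calls at all.

### Numerical choices

* The two-sided Fisher p is the sum of hypergeometric probabilities not
  exceeding the observed table's probability (relative tie tolerance
  1e-7, matching common practice); tables with an empty margin return
  p = 1. For batch-scale throughput all candidate tables are flattened
  into a single vectorised `scipy.stats.hypergeom.pmf` evaluation; tests
  pin this against both `scipy.stats.fisher_exact` and an exact rational
  enumeration oracle at ≤1e-9 relative error.
* ε is estimated with a two-pass scheme: candidates surviving the
  between-sample screen are treated as putative clones and their sites
  are excluded from the background of their class in their library, so a
  genuine clone does not inflate its own noise estimate. A zero ε is
  floored at 1/(eligible depth) — the rate-resolution limit of the data —
  which keeps the binomial test defined and the LNR finite.
* The within-sample p uses `scipy.stats.binom.sf(n_alt − 1, d, ε)`.
* `call_batch` computes per-candidate rates by subtracting each
  candidate's own site from precomputed per-(library, class) totals; a
  test asserts exact agreement with the direct estimator.

## Replicate integration

Libraries are independent PCR reactions from one donor's DNA; a library
may be sequenced in several batches/runs for more depth. Passing calls
are first deduplicated per library across runs (the deepest run carries
the representative evidence). A donor-level variant is
**double-positive** when the full statistical criteria passed
independently in ≥ 2 libraries of the donor, **single-positive** when in
exactly one; donors with a single library can only reach
single-positive. The replication unit is the library (independent PCR),
never a second run of the same PCR. An optional relaxation upgrades a
single-positive variant when another library of the donor merely
detects it with ≥ k accepted alternate reads (k = 3 by default, off
unless requested). The reported per-variant VAF pools alternate counts
and depths over the supporting libraries' deepest runs, so it always
lies within the range of the per-library VAFs.

## Annotation

The amplicon target metadata (strand, codon offset, frame) is the entire
transcript model; no annotation database is queried. Variants are
reverse-complemented into coding orientation for minus-strand genes,
translated with the standard genetic code, and labelled
protein-style (`S614R`, `E592*`, `G617G`, `E616del`, `Y657dup`).
Consequence classes are missense, stop-gained, synonymous, single-codon
in-frame deletion/duplication; anything else is `complex`. COSMIC/OMIM
identifiers and CADD scores come from a bundled static table keyed on
the label — they are looked up, never computed.

The bundled target fixture is a **synthetic** STAT3-like reference: the
codons named in the known-variant table carry the true STAT3 residues
(SH2 domain, exons 20–21, minus strand, GRCh37-like coordinates), all
other codons are deterministic filler. It exercises every code path;
analysing real reads requires a real reference, which the targets YAML
supports through a FASTA path.

## Synthetic data generator

The generator defines the study conditions used throughout the tests.

* **Counts path** (`simulate_batch_counts`): accepted depth per position
  is Poisson around the target depth (amplicon coverage over a short
  target is roughly flat; no GC/positional bias is modelled because the
  statistics never see it). The allele split at a site is a single
  multinomial draw over the configured alternate rates, so counts
  conserve depth exactly.
* **Noise defaults**: transitions 1.5e-4, transversions 5e-5 per
  accepted base (transitions 3× transversions, exercising the per-class
  estimator), 1-bp deletions 2e-5, 1-bp insertions 1e-5. These sit in
  the 10⁻⁴–10⁻³ regime of accepted-error floors in deep amplicon data
  and are calibrated so that pure-noise batches yield zero calls at the
  default thresholds.
* **Batch artefacts**: per-library fractions drawn from a Beta with the
  configured mean and CV = 0.1 — a preparation artefact repeats tightly
  within its batch, which is exactly the similarity the between-sample
  screen absorbs.
* **Spikes**: a clone is carried by *all* libraries of its donor at its
  true VAF, within the 0.005 %–1.5 % envelope of reported low-fraction
  clonal variants.
* **Reads path** (`simulate_reads`): pre-aligned full-amplicon read
  pairs, per-base qualities from a clipped normal (mean 36, sd 3),
  per-mate errors drawn independently with probability 10^(−q/10). This
  realises the e²/3 concordant-error mechanism; a test shows the
  accepted error rate falls more than twentyfold below the raw read
  error rate, and another shows the two generation paths produce
  statistically indistinguishable alt fractions.
* **Replicate experiment fixture**: 6 duplicate-library donors, 2
  single-library donors, 2 batches with one technical-reference library
  each, 2 libraries re-sequenced in a second run, depth 50,000×, spiked
  VAFs log-uniform in [0.3 %, 1.2 %]. Spikes in that VAF range at that
  depth are far above the detection limit, so the fixture isolates the
  replicate-classification logic from power questions.

Every draw is recorded in a truth ledger (expected per-site rates,
realised artefact fractions, raw per-fragment observations for the read
path), so tests recompute pileups and candidate sets by brute force.

**What the generator does not emulate** — polymerase chimeras,
sequencer-specific quality curves, index hopping, coverage bias, primer
artefacts, contamination. Passing tests therefore demonstrate the
statistical machinery under its own model assumptions, not performance
on any particular instrument's error idiosyncrasies.

## Cohort statistics

Carrier 2×2 tables (any mutation, ≥2 mutations, known-variant carrier,
other-mutation carrier) are compared between cases and controls with the
same two-sided Fisher exact test, Bonferroni-corrected by the number of
criteria compared (4). Age uses the classic pooled-variance Student
t-test (Welch behind a flag); degenerate inputs report NA. Mutation
load uses the two-sided Mann–Whitney U: exact (full enumeration,
tie-aware, two-sided p = 2·min of the one-sided tails, capped at 1) up
to 200,000 distinct group assignments, tie-corrected normal
approximation beyond. The VAF–age trend is a Pearson correlation.
Multivariate regression is deliberately out of scope; the donor-variant
table exported by the CLI is model-ready for any standard package.

## Problem sizes in the test suite

Property suites run at sizes that exercise the deep-sequencing regime
while keeping the default run short: specificity and artefact rejection
use 12-library batches at 30,000× over 20 seeds each; power uses
6-library batches at 50,000× over 40 seeds; oracle equivalence uses
200+ randomised small instances. The full suite runs in about two
minutes on one core.

## Known limitations

* The caller assumes every library of a batch shares target definitions
  and that coverage is deep enough for the Poisson/binomial asymptotics
  to be irrelevant (exact tests are used throughout, so shallow data is
  handled correctly but has little power).
* The detection limit is site- and class-specific: it depends on the
  library's own noise rate, the batch's pooled counts and the candidate
  count entering the Bonferroni divisor; no single VAF cutoff exists.
* Indel handling covers the simple events short coding amplicons
  produce (length-pooled noise classes, single-codon del/dup labels);
  complex indels are counted but labelled `complex`.
* Germline calling, alignment and UMI/duplex consensus are out of
  scope; input is expected to be aligned, primer-trimmed reads or
  accepted-count tables.
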