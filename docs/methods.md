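# Methods

This note documents the models and numerical choices behind `equichip`:
what the simulator emulates, how each statistic is defined, and where the
design was genuinely open.

## Simulated libraries

`simdata` generates aligned single-end libraries directly (no read
sequences or alignment step): each read is a (chromosome, start, end,
strand, MAPQ) tag.  The generative model per library:

1. **Fragments.** Lengths are Normal(`fragment_mean` = 200 bp,
   `fragment_sd` = 20 bp), floored at the read length (50 bp).  The target
   fragment size and read length are experimental parameters of the
   protocol being emulated; the Normal spread is our choice — the protocol
   specifies only "approximately 200 bp", and a truncated Normal is the
   simplest unimodal model.
2. **Placement.** Fragment starts are uniform over the genome, except
   inside planted elements carrying the library's mark for the library's
   tissue, where the rate is `enrichment_fold` (default 20) times
   background.  Per element and replicate the fold is jittered by an
   independent lognormal factor (σ = 0.25) so replicates agree but are not
   identical.
3. **Reads.** Each fragment emits one read from a uniformly chosen strand:
   the plus read starts at the fragment start, the minus read ends at the
   fragment end.  We book-keep the minus-strand 5′ end at the half-open
   end coordinate, so the plus/minus 5′-mode separation equals the
   fragment length exactly; duplicate keys and the cross-correlation
   estimator share this convention.
4. **Duplication.** A `duplication_rate` fraction of reads are exact
   copies of already-emitted reads (PCR-style).  The simulator never flags
   them; complexity metrics are computed, not read off.
5. **Phantom-peak artifact.** A small fraction of reads
   (`phantom_artifact_fraction` = 0.002) is emitted as same-span
   plus/minus pairs at random positions.  Real strand cross-correlation
   profiles show a "phantom peak" at the read length caused by
   mappability structure; a clean uniform simulation has none, which would
   make RSC — a ratio against the phantom peak — degenerate.  The pair
   artifact reproduces the phenomenon with one parameter: it is
   enrichment-independent, so well-enriched libraries dominate it
   (RSC > 1) while unenriched libraries do not (RSC ≪ 0.8).
6. **Decoys.** An optional `decoy_fraction` appends tags with MAPQ drawn
   uniform in [0, 30) so the strict MAPQ-30 filter is exercised; all
   ordinary tags carry MAPQ 60.

**Planted elements.** Shared elements (carried by all tissues) rotate
through three classes — enhancer {H3K4me1, H3K27ac}, promoter {H3K4me3,
H3K27ac}, repressed {H3K27me3} — so every mark receives signal; repressed
elements are 4× wider (2 kb) to exercise the broad caller.  When gene
models are available, promoter elements are centered on TSSs, which is
what makes the metagene profiles of promoter marks peak at the body-start
column.  Tissue-specific elements are active enhancers owned by exactly
one tissue, with a transcription-factor motif consensus substituted into
the genome at the element midpoint (random strand, IUPAC degeneracies
resolved uniformly).  `motif_consensus` may be one IUPAC string (planted
in every tissue's specific enhancers) or a per-tissue mapping (each tissue
gets its own motif — the configuration used to study unique detection).
Elements are placed by rejection sampling with a minimum spacing
(default 1.5 kb ≳ 2 fragment lengths + one window) so distinct elements
never merge into one peak.

**Default conditions.** The package defaults are the reference
"good-library" QC conditions: 200 k reads per library, duplication 0.1,
20-fold enrichment, on a 10 Mb two-chromosome genome (6 + 4 Mb) with 60
shared + 20 specific elements of 500 bp.  The genome and element budget
were sized once so that (a) ~6–8 % of ChIP reads fall in elements, giving
a clear fragment-length cross-correlation peak well above counting noise,
and (b) the 500 bp fingerprint binning yields ~20 k bins, keeping the
sampling bias of the empirical JSD (≈ 0.02) safely below the 0.05
threshold so unenriched libraries fail it for the right reason.

**Determinism.** All randomness flows from `SimConfig.seed` through
SHA-256-derived substreams keyed by purpose and (tissue, mark, replicate),
so outputs are byte-identical across runs and adding a library never
perturbs the others.

What the simulator does **not** model: sequencing errors and base
qualities, paired ends, mappability and GC bias, chromatin-state
autocorrelation, copy-number structure, or inter-individual biological
variation beyond the lognormal replicate jitter.  Passing tests therefore
demonstrate correctness of the estimators and rules under the assumed
statistical structure, not robustness to every artifact of real libraries.

## QC panel

* Filtering removes unmapped, secondary, vendor-failed, optical-duplicate
  and MAPQ < 30 tags; each removed tag is counted once under the first
  matching criterion, in that order.
* PCR duplicates share (chromosome, 5′ end, strand) — the right key for
  fixed-length single-end reads; the first tag in coordinate sort order
  is retained, making deduplication deterministic and idempotent.
* Complexity metrics are computed on filtered, *pre*-dedup tags.  PBC2
  with no doubly-seen position is reported as +∞ and always passes its
  threshold.
* Cross-correlation: cc(δ) is the Pearson correlation of the plus 5′
  vector against the minus 5′ vector shifted left by δ (computed via FFT
  with exact per-shift means and variances on the truncated slices),
  pooled across chromosomes by length-weighted averaging — concatenation
  was rejected to avoid artificial correlation across chromosome
  boundaries.  The fragment peak is the argmax outside an exclusion zone
  of ±10 bp around the read length (the phantom-peak position); the zone
  half-width is our choice, as is the 500 bp maximum shift.
* JSD: deduplicated tags are counted in 500 bp bins; each library's PMF
  over per-bin counts enters the Jensen–Shannon distance with log base 2.
  The bin size is our choice (the metric's usual implementations do not
  fix one); the matched input library is the comparator.
* Verdicts are strict (`metric > threshold`), matching the "(> x)"
  convention of the thresholds: NRF 0.5, PBC1 0.5, PBC2 1, NSC 1.05,
  RSC 0.8, JSD 0.05.

## Peak calling and consensus

Both detectors tile the genome at `window_size` (200 bp) and count each
tag once at its strand-aware extended-fragment midpoint (5′ end ±
fragment_size/2) — counting whole extended spans would double-count tags
straddling window boundaries.  The expected count is
max(local input rate × depth ratio, global ChIP rate over the effective
genome), the global floor guarding against zero-coverage input windows;
the effective genome is `genome_fraction` × genome length (fraction 0.63
for the broad mark, 1 otherwise).  P-values are upper Poisson tails.

* **Narrow caller:** windows with BH q ≤ `relaxed_q` (default 0.5) form
  candidates; adjacent candidates merge; peak q = min member q; summit =
  midpoint of the highest-count member; peaks with q ≤ the mark's FDR are
  significant.  The relaxed threshold is exposed because "regions of
  enrichment" for consensus combining must include sub-significant calls
  (see below).
* **Broad caller:** windows with Poisson p ≤ `island_window_p` (0.2) are
  eligible; islands are maximal eligible runs allowing ≤ `gap_size` (4)
  ineligible windows inside.  The island score sums truncation-corrected
  −ln(p/p₀) over eligible members, which is exactly Exp(1)-distributed
  under the null for continuous p, so the island p-value is a Gamma(k, 1)
  tail; island q-values are BH across islands.  This calibrated aggregate
  replaces SICER's island-score machinery.
* **Consensus:** all relaxed calls from both replicates are clustered
  into connected components of ≥ 1 bp overlap (chained overlaps resolve
  into one component); a component emits one consensus peak — the union
  span of its members — iff it contains calls from *both* replicates and
  at least one member with q ≤ the mark's FDR.  Interpreting "regions of
  enrichment" as relaxed-threshold calls is the only reading under which
  a consensus set can exceed the smaller replicate's significant-call
  count, a phenomenon the combined peak tables of real multi-tissue
  studies exhibit; the union span (rather than the intersection) likewise
  matches the observation that broad-caller consensus sets cover more
  genome despite fewer peaks.

## Comparisons, profiles, motifs

* Jaccard similarity is bp-intersection over bp-union of merged interval
  sets; both-empty input is an error rather than 0.  Replicate-level
  comparisons use per-replicate significant calls; unique/shared
  classification uses consensus peaks.
* Uniqueness is strict: any ≥ 1 bp overlap with another tissue's same-mark
  set disqualifies a peak; no reciprocal-fraction requirement.
  Tissue-specific enhancers are tested against the other tissues' *raw
  mark peaks* (the stricter of the two possible readings; the alternative
  — testing against their enhancer intersections — is noted but not
  default).
* Enrichment tracks: per bin, each replicate's reads-per-million count
  minus the depth-normalized input count, floored at 0, averaged across
  replicates (subtract-then-average keeps per-replicate diagnostics and
  equals average-then-subtract under equal scaling).  Output is bedGraph —
  text, lossless at bin resolution.
* Metagene: gene bodies are linearly resampled to 100 columns with 3 kb
  flanks sampled at the 50 bp track resolution (60 columns per side);
  minus-strand rows are reversed so columns run 5′→3′.  Body bin count
  and flank resolution are our defaults, config-exposed.
* Motifs: JASPAR text PFMs become log-odds matrices with pseudocount 0.25
  per cell and uniform background; hits are windows scoring ≥ 80 % of the
  matrix's maximum on either strand, with N scoring as the worst base.
  At that threshold an IUPAC-consensus PFM admits essentially exact
  consensus matches only.  Enrichment is a one-sided Fisher exact test on
  sequence-level hit presence against a dinucleotide-shuffled background
  (Altschul–Erickson shuffle preserving exact dinucleotide counts and
  endpoints), BH-corrected across motifs — a fully specified, exactly
  testable simplification of AME's ranking statistic.  Pooled other-tissue
  enhancers are available as an alternative background.  Short degenerate
  consensi (≤ 6 bp) saturate presence/absence in ~500 bp sequences and
  cannot rank well under any presence-based statistic; the demo therefore
  plants ≥ 11 bp consensi.

## Problem sizes

The shipped configurations are desk-scale by design: the QC reference
conditions use 200 k-read libraries on a 10 Mb genome; the demo cohort
uses 60 k-read libraries on 1.2 Mb; planted-structure recovery runs 20
seeded cohorts of 40 k-read libraries on 0.5 Mb.  Real studies run
30–80 M-read libraries on gigabase genomes; every operation here is
linear (or n log n) in reads and genome length, so the same code scales,
but the shipped numbers are chosen for fast, exact validation against
planted truth rather than for reproducing any real-data peak counts.

## Known limitations

* The narrow caller has no fragment-shift model building or local-lambda
  hierarchy; it is a windowed Poisson scan, adequate for planted-truth
  validation, not a MACS2 replacement on real data.
* Island p-values lean on the Gamma approximation with discretely
  conservative member p-values; calibration is conservative rather than
  exact.
* NSC is reported as cc(fragment)/cc_min even when cc_min ≤ 0 (possible
  in unenriched libraries), where the ratio is no longer a meaningful
  enrichment measure — verdicts still behave correctly since such values
  fail the threshold.
* The optical-duplicate flag is an input annotation (the simulator can
  inject decoys); no tile-geometry detection is attempted.
* GO-term annotation of motifs is carried through as an optional
  annotation table only; no ontology computation.
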