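# Methods

This note documents the models, numerical choices, and limitations behind
`concatcall`. It describes what the code computes; every empirical number
cited here is recomputed by the test suite or by
`scripts/acceptance.py`, never asserted from memory.

## Enrichment model

Allele enrichment by blocker-displacement PCR is modeled as a single
terminal fold *E* acting multiplicatively on variant/wildtype odds.
A sample at VAF *v* is expected to sequence at

    VRF(v, E) = E·v/(1−v) / (1 + E·v/(1−v)),        E > 0.

Properties used throughout: identity at E = 1; VAF 0 and 1 are fixed
points; strictly increasing in both arguments; exactly invertible, which
makes calibration and estimation mutual inverses:

    E  = [VRF/(1−VRF)] / [v/(1−v)]        (calibration, known v)
    v̂  = odds/(1+odds),  odds = [VRF/(1−VRF)]/E   (estimation)

Multiple calibration records for one locus combine by geometric mean
(folds are ratios; the geometric mean is the natural average and makes
the combination order-invariant). Records with VAF ∈ {0,1} or
VRF ∈ {0,1} carry infinite or zero odds and are excluded with a warning.
A cycle-by-cycle amplification model is deliberately not used: only the
terminal fold is observable from calibration data, and per-cycle
efficiencies are not identifiable from it. A linear VRF/VAF ratio was
rejected because it cannot saturate as VRF → 1.

**Saturation.** Above 90% VRF (`GateConfig.saturation_vrf`) the inverse
map becomes ill-conditioned — sequencing noise of a few percent moves the
estimate by large factors — so such loci are flagged `saturated` and
classified high-VAF (estimated sample VAF > 5%, the clinically meaningful
boundary) regardless of the numeric estimate. Estimation refuses to run
without a calibrated fold rather than assume a default. Multi-nucleotide
indels carry an over-estimation caveat flag: they enrich more strongly
than the SNVs used in calibration.

## Synthetic data generator

The generator emulates the post-PCR read population; its defaults are the
study conditions the rest of the package is tested under.

- **Monomer pool.** Each monomer is a full amplicon copy, amplicon chosen
  uniformly; each configured variant is present with probability
  VRF(v, E). Strand is ± with probability 1/2 (minus-strand monomers are
  reverse-complemented). Variants in primer regions are rejected —
  enrichment cannot act there, and primers are masked from calling.
- **Concatemers.** Monomer count per read follows a truncated geometric
  distribution on {1..40} reparameterized by its mean (default 13.5, the
  middle of the 12–15 monomers/read range measured for real ligation
  products by capillary electrophoresis); the geometric shape reflects
  ligation as a memoryless chain-growth process, and the truncation bound
  only needs to exceed anything observed. Read layout is
  `adapter + monomer (+ adapter + monomer)×(k−1)`; the junction adapter
  doubles as the leading adapter. The exact junction sequence of real
  libraries is not modeled — it is a required panel config string, and
  the simulator uses a random 24-mer per synthetic panel.
- **Errors.** Independent per-base substitution/insertion/deletion events
  at configured rates, default (0.04, 0.015, 0.015) — 7% total, the
  concatemer-read regime (phred ≈ 11.5); monomer-only regimes run nearer
  10%. The deletion rate is multiplied by 3 inside homopolymer runs ≥ 3
  (nanopore deletion errors concentrate there; the multiplier is a
  realistic order of magnitude, no published per-run rate exists).
  Emitted qualities are flat at the phred equivalent of the total rate —
  the generator models error *rate*, not per-base quality structure.

Not emulated: signal-level effects, chimeric/off-target amplicons, size
selection, strand-specific error asymmetries, PCR polymerase errors, and
real base-quality variation. Passing tests therefore demonstrate the
pipeline's behavior under idealized independent-error reads at realistic
rates, not performance on any particular flow cell or tissue type.

All randomness flows from one seed through `numpy.random.SeedSequence`
substreams, so every simulated dataset is exactly reproducible.

## Deconcatenation

Junction hits are approximate occurrences of the adapter (both
orientations) within bounded edit distance, found with edlib. Because
edlib reports only best-scoring locations, occurrences are harvested
iteratively: accept the current best locations, mask them out, repeat
until nothing within the budget remains. Overlapping candidates are then
resolved greedily — lowest edit distance first, ties by leftmost start.
Optimal interval scheduling is unnecessary: true hits are separated by a
full monomer length.

Defaults: `max_edit_fraction` 0.25 (a 20–24 nt adapter at 7–10% read
error carries 1.4–2.4 expected errors; a quarter-length budget accepts
those with margin), minimum segment length of half the shortest panel
amplicon (shorter fragments are uninformative and inflate mis-mapping).
At a quarter-length budget, chance near-matches in random sequence do
occur occasionally (the tests construct oracle-verified clean flanks for
exact-count assertions); spurious splits cost a segment, not a wrong
call. Segments are not strand-normalized here; orientation is resolved
at alignment. Splitting uses the full adapter, not the 4-nt sticky end a
ligation chemistry would leave — a 4-mer is unmatchable at these error
rates.

Conservation holds exactly: segment bases + junction-span bases +
dropped-short bases = read bases, checked by tests.

## Alignment and pileup

Segments are aligned semi-globally (edlib infix mode: the segment aligns
wholly, amplicon ends are free) against every amplicon in both
orientations; the lowest edit distance wins. A tie between *different*
amplicons discards the segment as ambiguous — guessing would recreate
pseudogene-style cross-mapping. Segments below 70% identity
(matches / alignment columns) are reported unaligned.

Unit-cost edit distance is used for both amplicon selection and CIGAR
extraction rather than an affine-gap scorer: at ≥ 20% inter-amplicon
divergence both make identical amplicon choices, and the edit-distance
kernel is roughly two orders of magnitude faster, which is what lets the
acceptance studies run thousands of simulated samples-worth of segments
in minutes. Alignment in amplicon space stands in for genome alignment
plus window extraction; for a PCR panel the two are equivalent because
every on-target read is an amplicon copy.

Pileup semantics (the basecount convention): matches and mismatches
increment the query base at the reference position; a deletion increments
a deletion counter at *each* deleted reference position; an insertion
increments an insertion-after counter *once* per event at the anchor
position (so a per-position variant table sees one insertion event, not
one per inserted base). Column invariant: A+C+G+T+del = depth at every
position. Insertions at a segment's very start have no anchor and are
dropped. An independent brute-force per-column recount over aligned
pairs verifies the accumulator exactly.

**Downsampling** caps per-amplicon coverage strictly below 150 segments
(a uniform seeded subset of 149 when at or above the cap): external
confidence models are trained at modest coverage and over-call at high
depth, and capping also bounds runtime. It operates on segments, not
pileup columns, so the score gate and the VRF see the same reads.

## VRF, ΔVRF, and the dual gate

The VRF at a position is the frequency of the most frequent single-base
change there, chosen among the three substitutions, insertion, and
deletion. Ties break by a fixed documented order (substitutions
alphabetical by target base, then insertion, then deletion). Zero-depth
and below-coverage positions are flagged, never dropped. Primer-region
positions are masked: after enrichment they are structurally
uninformative.

With a matched normal, ΔVRF_i = VRF_tumor,i − (frequency of the tumor's
top variant in the normal at i). The z-score compares ΔVRF_i against all
other unmasked positions pooled across amplicons, with leave-one-out
median and scaled MAD (1.4826·MAD): the background distribution is
heavy-tailed at homopolymers, so moment-based SD would be inflated by
exactly the artifacts one wants to flag. Per-position (rather than
global) noise statistics would need replicate normals and are not
implemented.

Calling is the conjunction: VRF ≥ 0.20 (inclusive) AND score ≥ 180 AND
depth ≥ 50 AND locus not blacklisted AND position inside the enrichment
region. Near-miss loci stay in the call table with per-gate flags.
Indel calls carry an informational caveat flag (external callers are
less reliable on indels); it does not gate.

**Confidence score.** The external neural-network caller the score gate
models is deliberately *not* reimplemented; the gate is a provider
interface. The default provider maps a binomial log-likelihood ratio —
observed variant fraction against an error-rate null (default 10%) —
onto 0–999 via a ×100 nat scale, clipped; it fails closed below minimum
coverage, and is monotone in variant count at fixed depth (so raising a
variant's support never un-calls it). At the gate's operating point
(VRF 0.2, depth 50, 10% null) the score is ≈ 222, so 180 is attainable
exactly where intended. When constructed with the panel, the null for
indel events is multiplied by the homopolymer run length at the position
(runs ≥ 3, capped at 0.8): alignment anchors every deletion of a run
onto one reference position, so a run of length L accumulates ≈ L times
the per-base deletion error there — at 7% total error this reaches ~20%
deletion VRF, which would otherwise pass both gates on wildtype input.
Real trained callers learn the same context penalty. An adapter that
reads scores from an external caller's VCF (QUAL column) can be swapped
in.

## Concordance and PR evaluation

The comparator positivity rule in NGS mode is strict: VRF > 5% and depth
≥ 80. Every locus of the assessed universe (panel enrichment-region
positions × samples) is classified TP/FP/FN/TN; a called locus outside
the universe is an error rather than silently admitted, because it would
drift denominators. Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP);
undefined ratios (no positives) return NaN rather than a fabricated 100%.

The PR curve sweeps the calculated-VAF cutoff over all distinct estimate
values, saturated loci ranked above every finite estimate (their numeric
VAF is untrusted by construction). The curve is anchored at recall 0
with the most-stringent precision and integrated by trapezoid over
recall (an average-precision-style convention; chosen and documented
because no single integration rule is canonical). At the lowest cutoff
precision equals prevalence, which the tests assert. Depth-stratified
discordance reports, for comparator-zero-VRF loci, the fraction per
depth bin where the pipeline VRF exceeded 20% (bin edges configurable).

## Problem sizes and determinism

The acceptance studies run at: 2,000 concatemers × mean 13.5 monomers
(~26k monomers) for deconcatenation recovery; ~10,000 analysis reads per
sample (740 concatemers) for the limit-of-detection study, 20 seeds per
VAF in {0.05%, 0.1%, 0.5%, 1%} at E = 1000 plus 20 wildtype samples; 20
seeds × ~10,000 reads for VAF recovery at E = 200. "Reads per sample"
counts monomer segments entering analysis, matching how a concatemer
protocol counts usable reads after deconcatenation. The unit-level
amplicon-assignment check runs 300 trials. A full pipeline run under a
fixed config and seed is byte-identical, manifest included.

## Known limitations

- VAF quantitation is depth-limited by the coverage cap (binomial noise
  at ≤149× is ~4 VRF points) and slightly biased by sequencing error
  (variant-base loss deflates, wildtype error inflates, and the convex
  odds inverse amplifies symmetric VRF noise asymmetrically); the
  dynamic range is inherently narrow once VRF saturates.
- The error model is i.i.d. per base apart from the homopolymer deletion
  multiplier; context-correlated errors (e.g. strand-specific motifs)
  are not modeled, so specificity on real data depends on the external
  score provider more than these simulations can show.
- The default confidence score is a calibrated statistical gate, not a
  learned model; it shares the VRF's information and adds context only
  through the homopolymer null.
- Multi-base insertions are counted as single events with their sequence
  not retained in the pileup, so insertion alleles are gated and
  reported generically (`ins`).
- No UMI support: absolute molecule counting is out of scope.
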