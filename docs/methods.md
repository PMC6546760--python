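# Methods

## Problem and pipeline

A riboSNitch is a single-nucleotide variant that substantially remodels
the local secondary structure of the transcript that carries it.  The
package implements a complete riboSNitch analysis chain for cohorts of
SNVs:

1. **Annotation.** One principal transcript per gene is chosen by the
   priority APPRIS rank > CCDS membership > transcript level > mature
   length (deterministic transcript-id tie-break).  Mature sequences are
   spliced from exons and strand-corrected; SNVs are projected onto
   mature coordinates with strand-corrected alleles; variants between
   exons are kept as intronic records for the neutral model; variants in
   blacklist regions are removed first.
2. **Folding.** Per-position base-pairing probability ("pairedness")
   profiles are computed for the reference and the mutated mature
   sequence with identical parameters.
3. **Scoring.** For a mutation at mature position *k* and half-window
   *w*:
   `MeanDiff = mean_{|i-k|<=w} |bpp_ref[i] - bpp_alt[i]|` and
   `EucDiff = sqrt( sum_{|i-k|<=w} (bpp_ref[i] - bpp_alt[i])^2 )`.
4. **Calling.** Per cohort, a mutation is a riboSNitch when it lies in
   the top tail (default 2.5%) of *both* statistics, a non-riboSNitch in
   the bottom tail of both, intermediate otherwise.  Thresholds are
   linear-interpolated empirical quantiles; cutoffs can be exported and
   applied to a different cohort (e.g. germline-calibrated thresholds
   for clinical variants).
5. **Neutral model.** Intronic mutations, assumed near-neutral, yield a
   96-class substitution profile (6 pyrimidine-centred substitution
   types x 16 flank combinations); each class count is divided by the
   number of occurrences of its trinucleotide context in the intron
   sequence (per-context rates).  For each transcript, the profile is
   recalibrated by the transcript's own 32-class context composition,
   giving a sampling distribution over classes; simulated mutations draw
   a class, then a uniform matching site, then the implied alt allele,
   and are scored exactly like observed mutations.
6. **Element tests.** For each 5'UTR, 3'UTR and lncRNA element, the
   observed riboSNitch contingency is compared with the simulated
   expectation by one-sided Fisher's exact tests in both directions,
   with Benjamini-Hochberg correction within each (element class,
   direction) stratum and calls reported at q < 0.05 / 0.1 / 0.2.
   Cancer specificity compares somatic vs germline contingencies (each
   called with its own cohort's cutoffs) and flags elements at
   P < 1e-3 (strict).  Coding mutations are excluded throughout: their
   structural effect is confounded by protein-level consequences.

## The folding model

The internal backend is a *pair-weight partition function*, not a
nearest-neighbour free-energy model.  Structures are pseudoknot-free
sets of canonical pairs (AU, GC, GU wobble) with a minimal hairpin loop
(default 3 nt) and a maximal pair span `max_span_L`; a structure's
Boltzmann weight is `pair_weight ** n_pairs`, and in the `stack` model
additionally `stack_bonus ** n_stacked` where a pair is stacked when the
pair directly inside it is also present.  Pair probabilities are exact,
via inside-outside recursions over the grammar

    S -> a S | P S | eps        P -> ( S )

with `Zb(i,j) = w * (Z(i+1,j-1) + (s-1) * Zb(i+1,j-1))`, O(n^3) time.
Every quantity can be cross-checked by exhaustive structure enumeration
for n <= 20, and the test suite verifies inside-outside against
enumeration to 1e-9 on hundreds of random sequences for both weight
models.

Defaults: `window_W = 200` (sequences longer than the window are folded
in every sliding window of that length and per-position values averaged
over covering windows), `max_span_L = window_W`, `min_hairpin = 3`,
`pair_weight_model = "stack"`, `pair_weight = 2`, `stack_bonus = 3`.

The stack model is the default deliberately.  Under uniform pair
weights the ensemble is dominated by slippage: a broken pair in a GC
stem is compensated by shifted registers and bulged variants with
almost the same total pair count, so single mutations barely move the
pairedness profile and stem-breaking and loop mutations are hard to
distinguish (hairpin-benchmark AUC ~0.7-0.85).  Rewarding contiguous
helices restores the cooperativity of real stacking energetics: a
mismatch in the middle of a helix splits one long stack into two short
ones and costs several bonus factors, which is what makes single
mutations genuinely disruptive (benchmark AUC >= 0.99).  The numerical
values (2 and 3) were chosen once as round numbers giving per-pair and
per-stack odds of the magnitude of thermal weights at ~1 kcal/mol and
are not fitted to anything.

Positions with N never pair (bpp 0).  Pairedness from RNAplfold output
is supported through an adapter that parses `_lunp` unpaired-probability
files (u = 1 column) and returns `1 - P(unpaired)`; runs wanting the
full Turner model can fold upstream with RNAplfold and feed the result
in.  The two backends share the profile container and everything
downstream is backend-agnostic.

A note on locality: although no pair may span more than `max_span_L`,
*probabilities* are not local - ensemble reweighting propagates through
chains of nested pairs, so a mutation measurably shifts bpp beyond the
span.  Exact decoupling holds only across an unpairable run at least as
long as the span (the partition function then factorises); the tests
assert that form.

## Scoring and calling conventions

Windows reaching past a transcript end are clipped, and MeanDiff is
normalised by the number of positions actually summed
(`effective_positions`), keeping it an average near transcript ends;
EucDiff is the plain Euclidean norm over the clipped window and
therefore grows with window size.  The invariant
`MeanDiff <= EucDiff / sqrt(effective_positions)` (arithmetic mean <=
RMS) is property-tested.  Tail thresholds include ties (>= / <=), so
tail fractions can exceed the nominal value on discrete distributions;
degenerate distributions in which a score qualifies for both tails are
labelled intermediate.

## Synthetic data: what it emulates, and what it does not

All inputs are generated by `ribosnitch.fixtures` from a seeded
`FixtureSpec`: a single-chromosome genome with multi-exon genes on both
strands (GENCODE-style GTF with APPRIS/CCDS/level tags, extra
lower-priority isoforms on one gene per biotype so principal-transcript
selection is exercised on real input), 5-column SNV cohorts, a BED
blacklist, and hairpin SNV benchmarks.

The default neutral profile is dense over all 96 classes with
transitions favoured and CpG C>T strongly favoured (x15 relative to the
base class), echoing the dominance of deamination signatures in somatic
spectra.

Transcripts come in two structural classes.  Unplanted transcripts are
structurally quiet (A/C-rich with 2% G/T), so their mutations score
low.  Transcripts carrying planted elements embed a fixed reference
hairpin - an aperiodic 8-bp GC stem with an all-A tetraloop - inside
fixed A/C pads: one hairpin (in a long quiet context) for enriched
elements, three for depleted elements.  Planting selects observed
mutations by rank on the package's own scorer from an oversampled
candidate pool: top ranks (in both statistics) for enriched elements,
bottom ranks for depleted ones.  This is deliberately circular - it
tests recovery of a planted signal through the full pipeline, not
biology.

Three design choices matter and were fixed while designing the
generator:

* **Fixed, shared hairpin sequences.**  Cohort-level tail thresholds
  compare scores *across* transcripts; if each transcript had its own
  random stem, the tail would collapse onto whichever transcript's stem
  happened to score marginally higher (winner-takes-all), making
  recovery a coin flip.  With identical hairpins in identical local
  context, hot-site scores are the same in every planted transcript and
  tail slots interleave.
* **Hairpin spacing >= pair span.**  Multiple GC hairpins closer than
  the span heal each other's broken stems by cross-pairing; the study
  configuration caps `max_span_L` at 30 nt and spaces hairpins by at
  least that, so each element folds independently.
* **Depleted elements need a high expectation.**  An observed *deficit*
  of riboSNitches is only testable against a large expected count, so
  depleted transcripts carry three hairpins (high neutral hot-site
  rate) and more observed mutations (144 vs 24 for enriched; recurrent
  mutations are counted per patient).

`synthetic_study_config()` scales the analysis to these cohorts: diff
half-window 15 nt, pair span 30 nt, tail fractions 4%, R = 200
simulated mutations per transcript, and the element analysis restricted
to mutations whose scoring window fits inside the transcript.  The last
restriction exists because MeanDiff normalises by the clipped window
while EucDiff does not, so near-end mutations rank the two statistics
inconsistently on transcripts not much longer than the window; at
genome scale (kilobase transcripts, W = 200) it excludes almost
nothing.  The 4% tails replace the 2.5% genome-scale default because a
tail of a few hundred scores must stay inside the discrete cluster of
high-impact sites in both the observed and the simulated pool: a
smaller fraction lands at the cluster's extreme where the two
statistics disagree on site order, a larger one dips into the quiet
bulk where the two pools' empirical quantiles diverge.

What passing these tests shows: the pipeline recovers planted
structural selection signals against its own neutral model, with
calibrated false-positive behaviour, on cohorts whose structure signal
is carried by designed hairpins.  What it does not show: performance on
real thermodynamic ensembles, real mutation-rate covariates
(replication timing, expression), overlapping genes, or cohort sizes
where the 2.5% tail convention applies unchanged.

## Numerical and protocol choices

* Quantiles: linear interpolation of order statistics (the convention is
  recorded with the exported cutoffs).
* Odds ratios: Haldane 0.5 correction when any cell is zero.
* BH strata: element class x direction; q-values never fall below raw p.
* Simulated-cohort cutoffs are computed on the pooled simulated
  distribution, not imported from the observed cohort.
* Cancer-specificity tests use the direction (enrichment/depletion) in
  which the element's element-test p-value is smaller.
* Mutations with N in the trinucleotide context or within 1 nt of a
  transcript end are excluded from classification (not fatal);
  multi-allelic VCF records are split; recurrent mutations are kept as
  separate records.
* Mutations overlapping several genes' principal transcripts are
  assigned to every overlapping transcript.
* RNG: every stochastic step takes a `numpy` `Generator` or integer
  seed; fixed seeds give byte-identical outputs, which the test suite
  asserts end-to-end.

## Known limitations

* The internal energy model is a two-parameter caricature of RNA
  thermodynamics; absolute score scales are not comparable to
  RNAplfold's, only the pipeline around the folding backend is
  backend-faithful.
* Long transcripts are folded window-by-window with O(n^3) cost per
  window; genome-scale runs should use the RNAplfold adapter.
* Depletion power is intrinsically limited by the expected riboSNitch
  count of the element; elements on structurally quiet transcripts
  cannot be called depleted no matter how many mutations they carry.
* The benchmark construction labels stem-interior mutations positive
  and loop mutations negative; stem-terminal breaks are genuinely mild
  and are excluded from the positive class rather than mislabelled.
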