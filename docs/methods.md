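# Methods

This note documents the statistical procedure the package implements,
the synthetic data model used to validate it, the numerical choices
made where the procedure left room, and what the tests do and do not
show about real microarray data.

## Experimental layout and data model

The target design is a 2 × 2 × 2 factorial: life-cycle stage
(diploid / haploid, treated as separate strata), pCO₂ (38.5 vs
101.3 Pa) and growth light (50 vs 300 µmol photons m⁻² s⁻¹), with
three biological replicates per cell — 24 arrays. Each array carries
three technical probes per transcript cluster plus spike-in control
probes, and hybridizes one sample against a pooled common reference,
so every probe measurement is a two-channel intensity pair. Probe
tables are long-format TSV (one row per probe per array); quality
failures and non-positive intensities are flagged at read time but
never dropped there — all exclusion logic lives in the analysis
stages, so there is a single source of truth for filtering.

## Normalization

M = log₂(sample/reference) is defined sample-minus-reference
regardless of dye orientation; no dye-swap averaging is performed
(the design table records the orientation, but the supported layouts
label the sample channel consistently). Within each array, the
intensity-dependent dye bias is estimated by a LOWESS fit of M on A
over non-control probes and subtracted; A values are never modified.

Numerical choices:

* **Span 0.4, 3 robustifying iterations** (configurable). The span is
  wide enough to average hundreds of probes per window at realistic
  array sizes yet follows a half-wave trend across the A range.
* **Controls are corrected, never fitted.** Spike-ins serve as the
  benchmark of the correction, so they must not influence it.
* **Gross M outliers are kept out of the fit** (|M − median| > 6
  robust SDs, MAD-scaled). Probes of transcripts expressed in only
  one life-cycle stage sit several log₂ units below zero against the
  pooled reference; with a bimodal M distribution the robust LOWESS
  iterations can latch onto the minority branch in some arrays and
  not others, corrupting the correction. Excluding gross outliers
  from the fit (they are still corrected by it) restores the
  assumption the normalization rests on: the trend reflects the
  unchanged majority of probes. If fewer than half the probes (or 20)
  would survive trimming, the fit falls back to all probes.
* Arrays with fewer than 20 usable non-control probes raise an error
  rather than produce a meaningless fit.
* The fitted curve is evaluated at arbitrary A by linear
  interpolation between fitted points (constant beyond the range).

The correction is idempotent to tolerance: a second pass changes no M
by more than the fit wiggle (~0.02 in the test conditions).

## Per-probe testing

For each stage separately, each probe's corrected M values are
grouped by the four pCO₂ × light cells, and a one-way fixed-effects
ANOVA provides the pooled residual mean square. Pairwise contrasts of
interest (CO₂ effect at each light level, light effect at each CO₂
level) are tested with Fisher's LSD t statistic; the fold change of
the contrast is the difference of group means, exploiting the common
reference. This is the plainest reading of "multiple comparison tests
using ANOVA" at the probe level; Tukey's HSD on the same pooled MSE
is available behind a configuration switch
(`multiple_comparison: tukey`) for analysts who want family-wise
control across the six group pairs. No across-probe multiple-testing
correction is applied by default, matching the screening character of
the procedure; Benjamini–Hochberg can be requested explicitly.

A probe is called up/down only when p ≤ α (default 0.05) **and**
|fold| ≥ the threshold (default 1.5) — conjunctive thresholds, probe
level. Degenerate inputs: a contrast group with fewer than two
usable replicates makes the probe *untestable* for that contrast
(retained, counted, treated as unaltered downstream); a pooled MSE of
exactly zero (possible in noise-free synthetic data) yields p = 0
when the means differ and p = 1 when they do not.

## Probe-set collapse

Decision order for a cluster's testable probe calls: (1) significant
calls in both directions → the whole probe set is excluded
(divergent) — divergence trumps everything, including two concordant
probes against one opposing; (2) exactly one significant probe among
otherwise unaltered ones → excluded (single-probe); (3) at least two
concordant significant probes → regulated, reporting the hit-probe
count and the signed geometric mean of the hit probes' fold changes
(fold changes are multiplicative, so the average is taken on the log₂
scale); (4) no significant probe → not regulated. Clusters with fewer
than two testable probes are untestable. "Unaltered" means *not
called* — failing either threshold — and the two-probe pattern
[significant, unaltered] is excluded as a conservative extension of
the single-probe rule.

## Gene-set partitioning

Directed gene sets (cluster → up/down) are built per stage and
contrast from regulated clusters only. Intersections and differences
are computed **by cluster identity**, not direction concordance: only
identity algebra satisfies the counting identities
|parent \ core| = |parent| − |core| that make the partition's
arithmetic auditable. Direction disagreements inside an intersection
are tracked in a `discordant` list — they do not change
cardinalities, the core's directions are reported from the first
parent, and the cross-stage "uniform" report excludes them. In
practice discordant intersections are rare to absent, since both
parents' calls derive from effects of one sign.

## Annotation filtering and categories

Model alignments with e-value strictly greater than 10⁻⁵ are
discarded. The free-text description and KOG class are retained only
while the best surviving model e-value is ≤ 10⁻⁶: the table format
carries no separate e-value for the text evidence, so the best model
alignment stands proxy for its support. Clusters without surviving
evidence stay in all outputs with `.` fields.

Functional categorization replaces manual curation with a declared,
version-controlled keyword map (case-insensitive regex against
description and KOG class; model identifiers never matched). This
makes category counts reproducible and monotone under keyword
addition, at the price of not reproducing any manually curated list:
the shipped defaults are seeded from gene families recurrent in
carbonate-system and light-acclimation transcriptomics and are meant
as a starting point, not a gold standard. A cluster may carry several
category tags but counts once per category and once in the
categorized total.

## Synthetic data model

The generator emulates the study conditions so that every stage of
the chain is testable against planted truth without any downloads.

* **Intensities are log-normal**: all structure is Gaussian on the
  log₂ scale (cluster baseline ~ N(10, 2²) in log₂ fluorescence
  units) and exponentiated at the end — the standard minimal model
  for fluorescence, sufficient for rank/threshold behaviour.
* **Response classes**: fractions of clusters respond to CO₂ under
  both lights (core, default 10%), only under low light (5%), only
  under high light (5%); analogously for the light factor (5% core).
  Planted effect magnitudes are |N(1.5, 0.3²)| log₂ units with random
  sign — comfortably above the 1.5-fold threshold (log₂ ≈ 0.585), as
  appropriate for a recovery benchmark of the calling rules rather
  than a power study at the detection boundary.
* **Stage-specific genome use**: a responsive cluster is expressed in
  both stages with probability 0.5, otherwise in exactly one; 10% of
  null clusters are also single-stage, and 2% are silent. Absent
  transcripts sit at a near-background intensity (log₂ = 4), so
  stage-specificity manifests as strongly negative M against the
  pooled reference, not as missing rows.
* **A 2 × 2 identity**: the four contrasts of a factorial cell-mean
  table carry three degrees of freedom, so a light-level-specific CO₂
  effect *implies* a light response at high CO₂ (realized contrast =
  co2_hl + light_1000 − co2_ll). The recovery oracle
  (`truth_to_expected_sets`) therefore scores realized cell-mean
  differences, not raw effect labels.
* **Noise**: a biological replicate effect ~ N(0, 0.1²) drawn once
  per (cluster, array) and shared by the cluster's three probes —
  this correlation is what makes probe concordance informative — plus
  independent probe noise ~ N(0, 0.2²) in each channel, and a
  probe-affinity offset (N(0, 0.25²)) common to both channels, which
  cancels in M.
* **Dye bias**: M_bias(A) = amplitude · sin(2πA/16), split half-and-
  half between the channels so A is untouched. The period (16 A
  units, a half-wave across the typical A range) gives a smooth,
  clearly intensity-dependent trend of the kind LOWESS is meant to
  remove. Default amplitude 0; benchmarks plant 0.5.
* **Anomalies**: with probability 0.01 each, a cluster's third probe
  carries the planted effect with inverted sign (exercising the
  divergent-set rule) or its second probe returns uncorrelated noise
  (sd 0.5) around the reference level (a dead probe, usually
  yielding a 2-of-3 regulated call).
* **Spike-ins**: 20 control probes at fixed log-ratios
  {−2, −1, 0, 1, 2}, evenly spread over the central A range, subject
  to dye bias and probe noise like any probe but excluded from all
  fits and sets.

What the generator does **not** emulate: spatial/print-tip array
artifacts, scanner saturation, background subtraction, dye-swap
designs, correlated probe cross-hybridization, heavy-tailed or
intensity-dependent variance, and composition effects in the pooled
reference (a single-stage transcript is modelled at full reference
intensity, though a real pool would dilute it — only a constant
offset in M, invisible to contrasts). Passing recovery tests
therefore demonstrates the correctness of the implemented rules and
their interplay, not performance on real arrays.

## Benchmark problem sizes

The packaged benchmarks use 300-cluster arrays (dye-bias flattening:
amplitude 0.5, zero biology; post-correction per-array median |M|
stays below 0.05 and spike-ins recover within ±0.1) and a
1000-cluster recovery run (3 replicates, probe noise sd 0.2, planted
|log₂FC| = 1.5, α = 0.05, fold cutoff 1.5), where the chain reaches
sensitivity ≥ 0.9 with a false-discovery proportion ≤ 0.1 against
planted truth and excludes divergent-flagged clusters at the planted
anomaly rate within binomial sampling error. These sizes were chosen
as the smallest at which the measured proportions are stable enough
to be meaningful; all quantities are recomputed at run time by
`scripts/acceptance.py`.

## Known limitations

* Fisher's LSD applies no family-wise correction across the six group
  pairs; with four groups this is the most permissive standard
  choice (Tukey available as an option).
* The e-value proxy rule for text evidence (best surviving model
  alignment) is a design decision forced by the 7-column table
  format; tables that carry a dedicated text e-value would need a
  schema extension.
* Identity-based core membership can, in principle, include a
  direction-discordant cluster in a core set's counts; the package
  reports such clusters but does not re-partition them.
* The keyword categorizer is deliberately shallow — substring/regex
  matching cannot resolve ambiguous descriptions and inherits any
  bias of the keyword list.
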