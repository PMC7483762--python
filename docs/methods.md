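# Methods

## The model

The pipeline addresses one question: which of the molecular changes a drug
induces are part of its mechanism of action, and which are secondary
reactions of the perturbed cell? Its operating assumption is that a causal
mechanism acts through the drug's target and therefore produces the *same*
response — same direction, same kinetics — in genetically different cell
lines, whereas secondary adjustments depend on each line's metabolic wiring
and diverge. The matching score operationalises this: for a protein *i* at
timepoint *t*, with directional calls d_A and d_B in cell lines A and B,

    s(i, t) = 1  if d_A(i,t) = d_B(i,t) ≠ unchanged,   else 0,

and a process P is scored by the arithmetic mean of s over its members.
The score is symmetric in the two cell lines, binary per protein, and its
process mean is 1 exactly when every counted member matches.

Two conventions matter and were genuinely open design choices:

* **Protein universe.** The mean is taken over proteins significantly
  regulated in *at least one* cell line at that timepoint. Proteins
  unchanged in both lines are excluded rather than scored 1: scoring them 1
  would reward shared inaction and inflate processes the drug never
  touched. This makes the score an estimate of
  P(concordant regulation | any regulation).
* **Time stratification.** Scores are computed separately at each timepoint
  and never pooled: a process can be discordant early and concordant late,
  and pooling would average that signal away. A relaxed variant
  (`mode="any_time"`) credits same-direction regulation at different
  timepoints, for sensitivity analysis; the strict same-time rule is the
  default.

## Differential calling

Treated samples are normalised per replicate to the vehicle-control mean of
the same (cell line, timepoint) stratum and reported in percent
(control = 100%); the reported spread is the sample SD of the per-replicate
percentages. Significance uses a two-tailed two-sample *t*-test at
α = 0.05, pooled-variance Student by default with Welch behind a flag.
Technical replicates, when marked, are averaged into their biological
replicate before testing. Testing happens on log2 intensities for
label-free layers (`log_transform=True`, the default) and on the raw scale
for kit-style metabolite panels; within a stratum both percent-of-control
and the p-value are invariant to a global intensity rescaling, which the
suite verifies by property test. No multiple-testing correction is applied
by default — the pipeline reproduces an uncorrected p < 0.05 calling
scheme — but Benjamini–Hochberg adjustment is available (`fdr=True`).

Degenerate cases: two groups with zero spread and equal means get p = 1 by
convention (flagged with a warning); a single treated replicate gets SD 0;
a stratum lacking a vehicle or drug group is skipped with a warning.

## Missing-value imputation

Left-censored missingness is handled by the down-shifted-normal
convention: per sample column, missing cells are drawn on the log2 scale
from Normal(μ_obs − shift·σ_obs, (width·σ_obs)²) with defaults shift = 1.8
and width = 0.3 — a narrow distribution placed in the low-intensity tail,
where censored values plausibly live. Both parameters are exposed because
the convention, not the exact values, is what matters for enabling
*t*-tests; imputation is deterministic given its seed, and observed cells
are never modified. A column with fewer than two observed values has no
estimable distribution and raises.

## Enrichment statistic

For a differential list of n identifiers from a detected background of N,
and a term with K members overlapping the list in k, the enrichment
p-value is the hypergeometric upper tail P(X ≥ k). The EASE variant
removes one identifier from the observed overlap first,
ease(k) = fisher(max(k − 1, 0)), which penalises terms supported by one or
two overlapping identifiers and is conservative by construction
(ease ≥ fisher everywhere). The background defaults to the union of
detected identifiers, not the genome: enrichment against an undetectable
background conflates detectability with regulation. The implementation
uses `scipy.stats.hypergeom.sf`; the test suite checks it against exact
integer enumeration of the pmf for every (N ≤ 60, K, n, k) to 1e-12, and
checks EASE's conservativeness under null resampling.

## Lipid quantification

Quantification is deliberately semi-quantitative, mirroring
internal-standard MALDI-MS practice: each species' signal is divided by
the intensity of its lipid class' internal standard, class abundances are
sums of those ratios without response-factor correction, and PC
composition is each PC species' share of the summed PC ratio in percent.
The PUFA fraction is the share of PC species with more than 2 double bonds
(threshold configurable); it is monotone non-increasing in the threshold
and, like every ratio-derived output, invariant to a global intensity
scale. The label grammar accepts sum compositions ("PC 38:4"), sn-resolved
forms collapsed to their sum ("PC 16:0/20:4" → PC 36:4) and bare acyls
("20:4"); ether/plasmalogen shorthand is rejected explicitly rather than
misparsed.

## Pathway status and overlap

Phosphoprotein pathways are classified from member percent-of-control
values with strict thresholds: `up` if the only threshold-crossing members
exceed 150% of control, `down` if they fall below 50%, `mixed` if both
kinds occur, `unaffected` otherwise. A pathway counts as affected when its
status is anything but `unaffected`, and the affected sets of the two cell
lines are compared by plain set arithmetic (concordant = intersection,
single-line = symmetric difference). The packaged 24 h SKOV3/OVCAR3 tables
carry pathway id, name, functional system (FS1 molecular/cellular
interaction, FS2 stress response due to derangement) and phosphoprotein
count; the published font-based status coding is not machine-readable in
our source and is therefore not part of the tables.

## Synthetic data: what it emulates and what it does not

The generator emulates the study design downstream code must handle — two
cell lines × {vehicle, drug} × {8, 24} h × n ≥ 2 replicates per layer —
with:

* baseline log2 intensities per analyte ~ Normal(20, 1.5²), a typical
  label-free intensity scale (configurable; nothing downstream depends on
  the absolute scale);
* multiplicative log-normal replicate noise with coefficient of variation
  `noise_cv`, default 0.20, inside the 10–33% reproducibility band of the
  targeted assays emulated; the log2-scale SD is
  sqrt(ln(1 + cv²))/ln 2 so the realised CV equals the nominal one;
* planted two-fold effects (`effect_log2 = 1`): primary analytes draw one
  sign and one active timepoint shared by both cell lines; secondary
  analytes draw sign and active timepoint independently per cell line
  (maximally discordant at matched effect size); null analytes and
  unannotated background carry no effect;
* left-censored missingness: P(missing) is logistic in −log2-intensity
  with 0.5-log2-unit steepness, with its offset calibrated by bisection so
  the overall missing fraction equals `missing_rate` (default 0: censoring
  is opt-in).

Each simulated analyte belongs to at most one process; the concordance
module itself supports many-to-many membership, which real annotation has.
The generator does **not** emulate correlated analytes, batch effects,
intensity-dependent variance, peptide-to-protein rollup or dose–response;
passing tests therefore demonstrate the pipeline's statistical behaviour
under clean replicate noise, not robustness to those real-data features.

Replicate defaults follow the emulated assays: biological triplicates,
with technical replicates representable via a `tech_replicate` metadata
column and averaged before testing.

## Problem sizes and numerical choices

The test suite runs the structure-recovery experiment at desk scale —
140 protein analytes, 2 primary + 2 secondary processes of 15 members,
3 replicates, CV 0.20, 50 seeded runs — where every primary process must
outrank every secondary process at 24 h in ≥ 95% of runs; type-I error is
calibrated on 1000 null analytes. These sizes were chosen so a full run
takes seconds while leaving the statistical margins wide (at these
settings the expected primary process mean is ≈0.7 versus ≈0.13 for
secondary). Ranking ties break alphabetically for determinism. All
randomness flows through `numpy.random.default_rng` seeded from the
configuration, so identical (config, seed) pairs give bit-identical
matrices and byte-identical written reports.

## Known limitations

* The matching score is binary per protein; partially concordant responses
  (same direction, different time) earn credit only in the `any_time`
  variant, and no fractional scores are assigned.
* Class-level lipid totals without response-factor correction are
  comparative, not absolute, quantities.
* The enrichment module implements the chart statistic only — no term
  clustering, fuzzy membership or live database retrieval.
* With uncorrected α = 0.05 calling, ~5% of null analytes are called per
  stratum by design; process-level aggregation dilutes but does not remove
  this noise floor.
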