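# Methods

## Readout model and normalisation

The screen readout is the percentage of GFP-positive cells per well
(0–100). Two z-score schemes are used at different stages. In the primary
screen, each plate is normalised against itself: μ and σ are computed over
the plate's sample wells only, controls excluded, and every well (controls
included, for QC) receives z = (x − μ)/σ. This removes multiplicative and
additive plate-level effects exactly (per-plate z is invariant to shifting
or rescaling all wells of a plate), which is why the synthetic generator's
log-normal plate effect does not propagate into calls. In the validation
stage, z is computed per replicate against the mean and standard deviation
of the twelve Rluc negative-control wells measured alongside, and averaged
over four replicates.

Standard deviations are sample sd (ddof = 1) throughout; the alternative
population-sd convention is a switch (`ddof=0`) and the mode in effect is
recorded in output records and the run manifest. Replicates are averaged
after normalisation (per-replicate plate z, then the arithmetic mean);
missing replicates are averaged over and flagged rather than discarded,
because single-trigger/partial-data genes must flow through the funnel.

Degenerate plates (fewer than two valued sample wells, or zero sd) raise a
named error instead of returning infinities.

## Hit calling

All thresholds are strict: "below −2" means z < −2, and boundary values
never call. Dual-trigger validation requires both triggers on the same side
of zero, one beyond ±2 and the other beyond ±1.5, with either trigger
allowed to be the stronger one. The same-direction requirement is imposed
although opposite-signed pairs never occur in practice: two triggers pulling
in opposite directions cannot support one phenotype. Genes with a single
usable trigger validate only beyond ±4 — the level of the strongest grade
band — so partial data cannot validate on weaker evidence than complete
data. The counterscreen excludes only in the decreasing direction (z < −4
on GFP levels in constitutively GFP-expressing cells): the confound being
removed is loss of GFP signal masquerading as loss of recombination;
knockdowns that raise GFP levels are reported but retained. Genes without a
counterscreen measurement are retained and flagged untested.

## Phenotype grades

Grade cut-offs live in a `GradeScale` config with the published values as
defaults, so sensitivity analyses need no code edits. Two boundary
conventions coexist deliberately: z-band grades are strict (matching
"below −4"-style wording) while percentage cut-offs for sensitivity are
inclusive (matching "by 40%"-style wording). Because the inclusive cut-offs
are decimal fractions, the computed ratios are rounded to 12 decimal places
before comparison; this makes an exact 30% decrease grade "++" regardless
of binary floating-point representation, while being far below any real
assay resolution.

Drug sensitivity is double-normalised: d = 1 − (treated/untreated)_gene ÷
(treated/untreated)_Rluc. The inner ratios remove each knockdown's baseline
viability effect so that only treatment-specific cell loss registers; a
knockdown that halves cell numbers with and without drug grades "−" for
sensitivity (and "+"/"++" for viability instead). The viability grades are
read as relative decreases (>50% decrease → "++", >25% → "+"); the severe
"++" grade is what excludes a gene from the secondary assays, the only
reading under which excluded genes carry the stronger symbol.

Gamma-H2AX kinetics are compared per timepoint (1 h, 6 h post-IR) with a
two-sided two-sample Student t test, pooled variance, df = 4 for the
standard 3-vs-3 replicate design; Welch is available by flag. Two-sided is
a choice — the direction of a kinetic difference is informative in both
directions (delayed removal and accelerated removal are different
phenotypes). The t statistic and p-value are computed from first principles
(scipy supplies only the t CDF), which keeps library t-test routines
available as an independent oracle in the tests. Identical constant
replicates (zero pooled variance) return t = 0, p = 1 when the means agree.

## Enrichment

Fold enrichment is (k/n)/(K/N) and significance the exact upper-tail
hypergeometric probability P(X ≥ k) (scipy's survival function, stable for
large universes). Over-representation only, matching how such screens are
read. Benjamini–Hochberg adjustment across categories is on by default with
an off switch. The background universe is a required explicit argument:
enrichment against the screened gene set and against the genome answer
different questions, and the choice materially changes K/N.

## AP-MS filters

The confident-identification rule (≥3 peptides with ions score strictly
above 20) is applied per experiment, not pooled across a bait's
immunoprecipitations — pooling would let two weak experiments manufacture a
confident call. The common-background rule excludes proteins seen in
strictly more than 15% of the control-IP registry; with 193 control IPs the
boundary falls between 28 occurrences (14.5%, retained) and 29 (15.03%,
excluded). Baits are exempt, and proteins absent from the registry are
retained at count 0 but reported, since an incomplete registry should be
visible, not silent.

## Variant consequences

c. coordinates are 1-based with inclusive deletion spans; insertions sit
between two adjacent bases. Bracketed complex alleles combining a deletion
and an insertion over overlapping coordinates are normalised to a single
replacement of the deleted span by the inserted sequence, with the
normalisation recorded on the variant; insertions stated only by length
parse into a variant usable for reading-frame arithmetic (net length mod 3)
but refuse sequence application. Frameshift nomenclature uses single-letter
codes with X for the termination codon (`fsX`), the older style still
common in clinical reports. `describe_frameshift` anchors at the first
diverging residue and therefore emits substituted-anchor descriptions
(stop at pos + k − 1); `stop_position_from_fs` additionally interprets
retained-anchor strings (ref aa = alt aa, stop at pos + k). Substituted
anchors trigger a warning because published usage is not uniform about
where counting starts; retained-anchor arithmetic is unambiguous.

## Synthetic screens

The generator emulates exactly the structure the analysis assumes: per-well
GFP-positive counts are Binomial(cells_per_well, clamp(baseline ×
plate_effect / fold)), scaled to percent. Defaults — 5% baseline
GFP-positive fraction, 2,000 cells per well, log-normal plate effects with
sd 0.1 on the log scale, 5-fold positive-control depletion, duplicate
primary screen and 4-replicate validation — are plausible screen-scale
values; the raw distributional parameters of real screens of this type are
not published, so these are stated assumptions, configurable and never
hard-coded in analysis code. One random stream per (plate, replicate) is
derived from the master seed, so outputs are byte-identical for identical
configs and individual plates can be regenerated independently.

Secondary assays are simulated as Poisson cell counts around condition
means (Rluc baseline 1,000 cells; survival ratios 0.65/0.65/0.75 for
cisplatin/MMC/IR) and Gaussian percent-gamma-H2AX around timepoint means
(2/80/30% at no-IR/1 h/6 h, sd 3 percentage points, clipped to [0, 100]).

What the generator does not emulate: cell-cycle structure, transfection
efficiency gradients, edge effects, or any spatial well correlation. Tests
passing on synthetic screens therefore demonstrate the correctness of the
statistics under the stated noise model, not robustness to artefacts that
per-plate z-scoring cannot remove.

### Fold recovery

The fold estimator (negative-control mean / knockdown mean) is unbiased to
first order, and its precision is dominated by the knockdown wells: at a
true 3.4-fold depletion from a 5% baseline with 2,000 cells per well, each
knockdown well carries ≈18% relative binomial sd, so four replicate wells
give the estimate a ≈9% relative standard error, and a ±15% window captures
roughly 90% of runs. Pooling a gene's two validation triggers (eight wells)
tightens this to ≈6.5% and ±15% coverage above 95%. Both facts are asserted
in the test suite at 200 seeds each.

## Problem sizes

Simulation-based tests use one 384-well plate per replicate, 100–200 seeds
for decision-rate checks and 500 seeds for the null p-value calibration of
the t test; the full suite runs in well under a minute, and the acceptance
script (funnel, frameshift arithmetic, 200-seed fold recovery) in seconds.

## Known limitations

- The funnel reproduces the published candidate table exactly only after
  one documented reconciliation: one printed row's trigger grades are
  mutually inconsistent with the stated validation rule, and the fixture
  resolves it in favour of the row's membership in the validated list
  (`hrscreen.datasets.RECONCILED_Z`, with an off switch).
- Gene-ontology-style enrichment here is generic: no ontology DAG
  propagation, and published fold values from specific annotation databases
  are version-dependent and not reproducible from this package.
- No robust-z/B-score variants, and no multiple-testing control on hit
  calling: the method under study uses fixed z cut-offs, and adding an FDR
  layer would change what is being reproduced.
- Upstream flow-cytometry gating is out of scope; inputs are already
  summarised to percent-positive per well.
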