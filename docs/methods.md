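# Methods

## Behavioral emotionality score

Each behavioral measure x is converted to a standard score against the
vehicle control group of the same behavioral round, z = (x − μ) / σ,
where μ and σ are the control group's mean and sample (n−1) standard
deviation for that measure and round. A per-measure direction sign maps
every measure onto a common anxio-depressive axis: open-arm time and
open-arm entries in the elevated plus maze (EPM) and grooming duration
in the splash test (ST) carry direction −1 (less activity = more
emotionality), the novelty-suppressed-feeding (NSF) latency carries +1.
Signed z-scores are averaged within each test, then across the three
tests with equal weight, giving the composite emotionality score. By
construction the control group's composite mean is zero in every round.

Choices worth knowing about:

* **Per-round reference.** Every round is standardized against its own
  vehicle group rather than reusing the first round's reference, so each
  round is internally calibrated; longitudinal change is then a change
  in position relative to contemporaneous controls. Consequently the
  denominator σ is re-estimated per round; with small control groups
  (n ≈ 10) this estimate is noisy, and with a heavy-tailed latency a
  single slow control animal can visibly shrink all z-scores of that
  round. This is inherent to control-referenced standardization at
  small n, not an artifact of the implementation.
* **σ is the control group's**, not the pooled cohort's.
* **Censored NSF latencies** (no feeding within the 10-min window)
  enter the z computation at the 600-s cap with a censor flag. The
  composite therefore under-weights how much slower a censored animal
  "really" was; the survival analysis below is the principled treatment
  of the same endpoint.
* **Missing data.** A missing single measure is dropped from its
  within-test mean; an animal missing a whole test gets a composite over
  the remaining tests plus a logged warning; missing values never enter
  as zeros.
* Home-cage food consumption is an appetite control, not a score
  component.

## Responder classification

An animal responds when its composite score falls by at least 50 %
between baseline (week 5) and follow-up (week 10):
100·(baseline − followup)/baseline ≥ 50, the boundary counting as
response (the clinical "≥ 50 % improvement" convention). Because the
composite is a signed z-score, percent change is unstable for baselines
near zero; animals with baseline ≤ 0.1 composite-z units (the
`baseline_floor`) are reported as *indeterminate* and excluded from the
response-rate denominator rather than classified from an ill-defined
ratio. Animals missing a session appear in an exclusions report.

## Behavioral inference

Group location comparisons pass through a Shapiro–Wilk gate at
α = 0.05 per group: if every group looks normal, Student's t (two
groups) or one-way ANOVA with Fisher's-LSD post-hoc (k > 2); if any
group fails, Mann–Whitney or Kruskal–Wallis with Dunn's rank post-hoc.
Post-hoc p-values are uncorrected, mirroring the per-comparison
reporting convention of this literature. The NSF latency is analyzed as
right-censored survival data: Kaplan–Meier product-limit curves
("fraction that have not eaten") and the Mantel–Cox log-rank test with
the standard hypergeometric tie handling (both via `lifelines`).
Significance is fixed at p < 0.05 throughout.

## Identification filtering and protein grouping

Peptides with E-value ≥ 0.01 are discarded. A protein is retained when
it has at least two distinct retained peptides and the product of its
unique peptides' E-values is below 10⁻⁴. (Given the 0.01 peptide cut,
two retained peptides already force the product below 9.8·10⁻⁵, so the
product rule can only bind exactly at the boundary; it is applied
literally nonetheless.) Duplicate peptide evidence is collapsed to the
best E-value with a warning.

Retained proteins sharing at least one retained peptide are merged —
transitively — into protein groups (connected components of the
bipartite peptide–protein graph). Within a group, a member with at
least one peptide specific to it is a *subgroup*: one distinguishable
protein, the quantifiable unit. Group identifiers are the
lexicographically smallest member accession, making the output
deterministic.

## Spectral-count quantification and differential testing

Spectral counts of specific peptides are summed per subgroup per
sample. Peptides shared between subgroup members are never assigned to
a subgroup (no razor assignment): they accumulate in a group-level row,
so no spectrum is counted twice. Samples with zero total spectra are
dropped with a warning.

Differential abundance per protein is a Poisson generalized linear
model of counts on the treatment group (log link). With three samples
per group only a fixed group effect is identifiable; no random term is
fitted. The group effect is tested by the deviance difference between
the group model and the intercept-only model, χ² with k−1 degrees of
freedom. All-zero rows are reported untestable (NaN), never as p = 1,
and are excluded from the Benjamini–Hochberg family, whose size is the
number of tested proteins. A per-protein over-dispersion diagnostic
(Pearson χ²/df of the full model) is reported but not modelled.

**Library-size offset.** The default exposure offset is the log of
median-of-ratios size factors (the median, over proteins observed in
all samples, of the count over the protein's geometric mean). Raw
total-spectra offsets are also available (`offset="total"`), but they
are compositionally biased: when a sizeable, mostly one-directional
block of proteins truly changes, it inflates the affected group's
totals and pushes every null protein toward an apparent opposite
change — in simulations with 33 mostly-up planted proteins out of 200
this raised the empirical FDR of BH-significant calls from ≈ 0.05 to
≈ 0.3. The median-of-ratios factor is robust to such asymmetric
signatures; `offset=False` fits the unadjusted model.

Pairwise contrasts are two-sample Student t-tests on the counts as
given (a √ transform is available behind a flag), significance at
p < 0.05, direction *up* when the alternative group's mean exceeds the
reference. The resulting exploratory list deliberately trades false
positives for sensitivity, as is usual for spectral-count screens;
zero-variance-in-both-groups rows are untestable.

## Clustering and PCA

The differential matrix is row-centered (each protein's mean across
samples becomes 0) and clustered with unweighted pair-group average
(UPGMA) agglomeration on Euclidean distances, independently along
proteins and samples; ties break deterministically toward the lowest
pair index. Trees are exported as Newick with branch lengths plus merge
tables. PCA runs over samples using centered protein abundances as
variables (unit-variance scaling behind a flag, off by default since
counts share a scale); component signs are fixed so the
largest-magnitude loading is positive. For display, each group's scores
in the (PC1, PC2) plane are summarized by their mean vector and 2×2
covariance — the parameters of a bivariate-normal density for ellipse
rendering — and draws from that density can be simulated.

## Synthetic data generator

The generator emulates the study design, not any particular dataset:

* **Behavioral cohort.** Arms Veh/Veh, Cort/Veh, Cort/Flx (n = 25,
  later split responder/non-responder) and Cort/Flx-NR-ECS over rounds
  W5 and W10. Baselines are field-typical for adult C57BL/6 males:
  open-arm time Gaussian 60 ± 20 s (clamped to the 5-min test),
  open-arm entries Poisson(8), NSF latency log-normal (median 150 s,
  log-SD 0.5) right-censored at 600 s, grooming 70 ± 15 s. Group effects
  are mean shifts in reference-SD units — on the log scale for the
  latency — planted in the anxio-depressive direction (corticosterone:
  −1.2 SD open-arm activity, +1.5 SD latency, −1.0 SD grooming), with
  fluoxetine and ECS arms recovering most of the shift by their
  respective follow-up rounds. A persistent per-animal susceptibility
  trait (SD 0.6 in effect units, shared across rounds and measures)
  produces the within-arm heterogeneity that makes responder /
  non-responder splits non-trivial. Published cohorts of this design
  report no per-measure variances, so these defaults are plausible
  rather than calibrated; what passing tests show is that the *pipeline* recovers
  planted structure, not that real cohorts look exactly like this.
* **Spectral counts.** Proteins × samples Poisson draws with rate
  baseline × library factor × effect; library factors log-uniform in
  [0.8, 1.25] per sample; planted proteins (default 16.5 % of 200,
  7/33 of them down) multiply the rate by the fold change (default 4)
  or its inverse in affected groups. The truth table records identity
  and direction of every planted effect.
* **Peptide tables.** Long-format identification rows with E-values
  log-uniform over [10⁻⁶, 0.1] — straddling the 0.01 filter — and an
  `ambiguity_spec` that plants exact shared-peptide structure for
  grouping tests.

All generators are deterministic given their seed. They do not emulate
run-to-run retention-time drift, peptide detectability differences,
over-dispersion beyond Poisson, or correlated protein modules; results
on real data will be noisier than on these fixtures.

## Problem sizes and numerical choices

The test suite and the acceptance script use seeded simulations at
sizes chosen to make Monte-Carlo error small relative to the margins
checked: 1,000 null proteins for Poisson-LRT calibration, 1,000–2,000
replicates for log-rank calibration, 20 seeds × 200 proteins for
planted-signature recovery, 100–200 random instances for the
grouping and UPGMA oracles. Oracle comparisons use absolute tolerances
of 10⁻⁸–10⁻¹² (closed-form deviance, BH arithmetic, product-limit
steps); calibration checks use three binomial standard errors. Deviance
differences are clipped at zero to absorb optimizer round-off in
degenerate fits.

## Known limitations

* Poisson (no over-dispersion) differential model; biological
  replicates of real PBMC pools are often over-dispersed — inspect the
  reported Pearson χ²/df.
* Percent-change responder calls are undefined for near-zero baselines;
  the indeterminate mechanism reports rather than resolves them.
* No repeated-measures or mixed-effects behavioral models; no pathway
  enrichment; no precursor-intensity quantification; raw spectra and
  database search are out of scope — the pipeline starts at the
  identification table.
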