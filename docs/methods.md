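# Methods

## Study model and alignment

The pipeline targets a three-condition design — baseline ("native"),
perturbed ("pre-EVLP") and treated ("post-EVLP") — with b biological
replicates (animals) per condition and t technical replicates (repeated
LC-MS/MS runs) per animal; the defaults throughout are b = 5, t = 2, i.e.
30 runs. Spectral counts (SpC, the number of MS/MS spectra assigned to a
protein in one run) are used as the label-free relative-abundance proxy.

Alignment takes the union of accessions over all runs and treats a protein
absent from a run as SpC = 0. Averaging is hierarchical: technical
replicates are averaged to an animal-level SpC\*, animal values to a
condition-level SpC\*. This is deliberate — a pooled grand mean over all 10
runs of a condition would weight animals by run count rather than equally.
Identification frequency is the fraction of a condition's runs in which the
protein was detected. Rows sharing a gene symbol can be collapsed (summed
counts, max score) before the multivariate steps, since isoform-level
spectral counts are rarely independent evidence.

A protein is "present" in a condition for Venn purposes when detected in at
least one of that condition's runs (configurable to ≥ k runs; presence
criteria are not standardized in the field).

## Repeatability and scattered proteins

Repeatability of two runs (or two animals) is summarized by the
least-squares slope through the origin and the squared Pearson correlation
of the aligned SpC vectors; both equal 1 for identical inputs. The
through-origin fit matches how such plots are conventionally reported (a
single slope, no intercept).

Scattered-protein detection asks which proteins of one sample depart from
the peer-group trend: the sample vector is regressed through the origin on
the peer average, and proteins with standardized residuals above 3 SD are
flagged. The residual scale is re-estimated iteratively after removing
flagged proteins until the flagged set stabilizes; a single pass would let
the outliers inflate their own yardstick and mask moderate contaminants.
Both the threshold and the iteration cap are configurable. Removing flagged
proteins and refitting does not decrease R² on contaminated data (asserted
in tests on planted contaminants; it is not a mathematical guarantee for
arbitrary inputs).

## Differential indices

For condition-level averages x, y: DAve = 2(x − y)/(x + y) (a signed
relative ratio bounded in [−2, 2]; ±2 exactly when one side is absent) and
DCI = (x + y)(x − y)/2 (count-scaled, so confidence grows with total
evidence). Default call thresholds are DAve ≥ |0.2| with DCI ≥ |10|. When
x + y = 0 both indices are defined as 0 and the protein marked not
evaluable, keeping downstream filters total. These are threshold rules, not
hypothesis tests; no p-value or multiplicity control is attached, which is a
documented caveat of the method rather than an implementation gap.

## Descriptor selection, LDA, AGNES

Descriptor selection computes a per-protein one-way F ratio (model mean
square / error mean square) over the animal-level SpC\* vectors — 15 samples
in the default design — and keeps proteins with F > 3.4 and raw p < 0.05
from the F(k−1, N−k) distribution. No multiple-testing correction is applied
because the selection criterion is defined that way; the descriptor list
should be read as a discriminative feature set, not a list of individually
significant proteins.

LDA uses a single covariance matrix pooled within groups (denominator
Σ(n_c − 1)) and assigns each sample to the group mean with the smallest
squared Mahalanobis distance. With 5 samples per group and hundreds of
descriptors the pooled covariance is singular; it is ridge-regularized with
ε = 1e−6 × trace/dim (configurable, warning emitted). Only training-set
structure is reported — with n = 15 samples cross-validation would be
nearly vacuous, and the quantity of interest is whether the conditions
separate, not generalization error.

AGNES clustering uses Euclidean distances and average linkage (UPGMA, the
conventional AGNES default). The agglomerative coefficient is the mean over
leaves of (1 − h_first/h_max), where h_first is the height of the leaf's
first merge; identical samples (h_max = 0) get AC = 0, the "no structure"
boundary. Dendrograms export as Newick plus a merge table.

## Remodeling indices

Modules are pairwise differential values on condition-level SpC\*:
perturbation M(b−p), treatment M(p−t), baseline M(t−b), computed with DAve
by default or ln fold change (pseudocount 0.5 substituted for zeros only) —
DAve is preferred because fold changes are undefined for n/0 and 0/n. Then
PRi = M(b−p)/M(p−t) and PAi = M(t−b)/M(p−t), both undefined (NaN) when the
treatment module is zero.

* recovered: PRi ∈ [−2, −0.5] — the protein moved under perturbation and
  returned toward baseline after treatment (PRi = −1 exactly when
  baseline = treated ≠ perturbed).
* activated / inhibited: PAi ∈ [−2, −0.5] with a null perturbation module
  (|DAve(b, p)| < 0.2, reusing the unchanged/changed boundary) — the protein
  responded to the treatment only. Direction follows the sign of the
  treatment module: activated means abundance rises from perturbed to
  treated.

The PAi window mirrors the PRi window; only "≈ −1" is prescribed for PAi, so
the window is configurable. Noise exclusion removes proteins whose module
DCIs are all below |5| (the permissive reading of "multiple DCI < |5|";
an "any" rule is available but would discard every perfectly recovered
protein, whose baseline module has DCI 0). Candidates are validated with
one-way ANOVA across conditions on animal-level SpC\* plus Tukey's HSD;
the index extraction over-extracts by construction and the ANOVA step is
the pruning stage.

## Statistical primitives

One-way ANOVA and Tukey's HSD (Tukey–Kramer for unequal n, p from the
studentized-range distribution) are computed from textbook sums of squares
with scipy distribution functions; fully degenerate inputs yield F = 0,
p = 1. The two-sided single-outlier Grubbs test uses the t-based closed-form
critical value at α/(2n). Sample size for a minimum detectable difference δ
with SD σ uses the two-sided two-sample t-test power from the noncentral-t
distribution (noncentrality δ/(σ√(2/n))), returning the smallest integer n
per group reaching the target power; a three-group one-way ANOVA variant
(group means 0, δ, 0) is available behind a flag. The two-sample reading is
the conservative default since the design behind such published power
statements is usually unstated. Subnetwork enrichment uses the exact
hypergeometric upper tail with Benjamini–Hochberg correction across
subnetworks (the correction choice is ours; none is standard for this kind
of curated-annotation test). pI and MW from sequence are delegated to
Biopython's ProteinAnalysis (Bjellqvist pKa set, bisection on net charge;
average residue masses), which is exactly the documented-pKa/bisection
construction and not worth duplicating.

## Synthetic-data generator

Counts are Poisson(λ_jc × e_ja) where λ_jc is the protein-by-condition rate
and e_ja ~ LogNormal(0, σ_bio) is a biological effect drawn once per protein
and animal (σ_bio = 0.3 by default — per-protein between-animal variability
of ~30%, a realistic figure for tissue proteomics). An over-dispersion
option multiplies rates by a per-run Gamma variable (negative-binomial
counts). Base abundances follow LogNormal(ln-mean 1.6, ln-sd 1.0), i.e. a
median rate of ~5 spectra with a heavy right tail, mimicking the dynamic
range of spectral counts. Planted classes: recovered proteins have
λ_pre = 2λ_native with λ_post back at baseline; activated (inhibited)
proteins scale λ_post up (down) 2-fold; condition-specific proteins are
absent outside one condition; the remainder are stable. One animal of the
treated condition is plasma-contaminated: 20 proteins — drawn from the
abundant half of the distribution, since plasma proteins such as albumin are
high-abundance — are inflated 10× in that animal's runs only. Identification
scores are generated roughly proportional to counts with log-normal scatter;
they carry no independent information. All randomness flows through a single
numpy PCG64 generator seeded from the config, so studies are exactly
reproducible.

What the generator does **not** emulate: peptide-level protein inference,
shared peptides, run-to-run normalization drift, missing-not-at-random
dropout of low-abundance proteins, or correlated protein modules. Passing
recovery tests therefore demonstrates the pipeline's correctness under the
stated count model, not its performance on real tissue data.

A property worth knowing when interpreting recovery experiments: at a median
rate of ~5 spectra, the condition-level SpC\* (mean of 10 runs) has Poisson
coefficient of variation ≈ 1/√(10λ) ≈ 0.14, so DAve carries sampling noise
with SD ≈ 0.2 even before biological variability — the same magnitude as the
|0.2| thresholds. Threshold-based calls and the remodeling gates are
therefore intrinsically noisy for low-to-mid-abundance proteins, false DEP
calls on a null study are far above α-level, and the raw index extraction
substantially over-calls stable proteins (the published-style workflow
prunes with ANOVA, which restores a low false rate at the cost of recall).
This is a property of the method at these abundances, documented here rather
than hidden by gentler defaults.

## Numerical choices and edge cases

* DAve/DCI with x + y = 0: defined as 0, flagged not evaluable.
* PRi/PAi with zero treatment module: NaN ("undefined" state, never raises).
* Zero-variance vectors in repeatability: R² undefined (NaN) and flagged.
* Singular pooled covariance: ridge ε = 1e−6 × trace/dim with a warning.
* Identical samples in AGNES: all heights 0, AC = 0.
* Edge scores on a 0–1000 integer scale are detected (max > 1) and divided
  by 1000 with a logged notice; the score filter is strict (> min).
* Duplicate accessions within a run are merged by summing SpC (additive
  evidence) and keeping the maximum score, with a logged warning.
* Problem sizes: the test suite exercises the full default study (2000
  proteins × 30 runs) end to end and smaller 200–400-protein studies for
  stage-level checks; these sizes were chosen to match the scale of a real
  rodent-tissue spectral-count experiment while keeping the suite quick.

## Known limitations

* No count-model inference (e.g. beta-binomial) behind the DAve/DCI calls;
  the method is threshold-based by design.
* No protein inference or FDR estimation — inputs are assumed to be
  already-filtered protein lists.
* Subnetwork memberships are user-supplied annotations; no topological or
  GO-based clustering is performed.
* LDA reports training-set structure only (see above).
* The remodeling classification inherits the noise floor of spectral
  counting; treat the raw classified sets as candidates and the
  ANOVA-validated sets as results.
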