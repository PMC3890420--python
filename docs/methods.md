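# Methods

## Polarization model

Immune polarization within a signature family (T helper: Th1/Th2/Th17/iTreg;
macrophage: M1/M2) is treated as model selection among K mutually exclusive
states.  Genes shared between subsets of a family (e.g. CD4, which appears
in all four T-helper signatures) carry no discriminating information and are
removed before scoring; each subset is represented by its exclusive gene set
E_k.  The data vector is the per-gene cohort z-score of log2 median-centered
expression: raw intensities are normalized per sample to the sample median
(log2(I / median), so each sample's median maps to 0), then standardized per
gene across all samples of the cohort — tumors and normals together — using
the sample standard deviation (n−1 denominator; configurable).  Zero-variance
genes z-score to 0 with a warning rather than failing.

The likelihood of a sample under model M_k is a product of per-gene Gaussian
kernels with unit bandwidth, centered at +a for the subset's own exclusive
genes and at −a for the other subsets' exclusive genes:

    log L_k = −1/2 Σ_{g∈E_k} (z_g − a)² − 1/2 Σ_{j≠k} Σ_{g∈E_j} (z_g + a)².

The target amplitude a (default 1, in z-units) encodes how strongly a
polarized sample is expected to deviate; posteriors depend on a only through
the spread of the z's around ±a, and the synthetic-recovery results are
insensitive to a over roughly [0.5, 2].  Posteriors follow from Bayes' rule
with uniform priors (1/K, configurable) and are computed in log space with a
log-sum-exp normalization, so finite z never underflows; the add-one
empirical machinery never reports a p-value of exactly 0.

Unequal exclusive-set sizes bias the null mean posterior away from 1/K.
This is deliberate: significance is always judged against the *empirical*
bootstrap null, which absorbs the size asymmetry, never against 1/K itself.

## Bootstrap null and empirical p-values

The no-signal null pools every z-value in the matrix (all genes, all
samples).  Each of B = 1000 replicates builds a cohort of n synthetic
samples, drawing one pooled value per exclusive gene with replacement, and
records the cohort-mean posterior.  The one-sided p-value for an observed
cohort-mean posterior is (1 + #{null ≥ observed}) / (B + 1); the minimum
resolvable p is therefore 1/(B+1) ≈ 0.001 at B = 1000.  A Gaussian KDE
(scipy's default Silverman-type bandwidth) summarizes each subset's null for
reporting and plotting; p-values always use the distribution-free add-one
rule, not the KDE.  The null cohort size is matched to the observed cohort
being tested.

## Cohort structure

Samples are clustered on the immune gene panel (log2 ratios) with Ward's
minimum-variance criterion on Euclidean distances (scipy's `ward`, the
textbook objective, equivalent to R's `ward.D2`); the R `ward.D` variant —
the Lance-Williams update applied to unsquared distances — is available as
an option via a direct O(n³) agglomerator.  Samples are sorted
lexicographically before linkage so results do not depend on input order,
and the groups from a tree cut are renumbered by decreasing size (largest =
group 1, ties broken by smallest member id).

Infiltration is the per-sample mean log2 ratio over recruitment markers
(NK: KLRD1, KLRC2, KLRC3; T cell: CD247, CD3G, CD3D, CD3E; macrophage:
CD14, CPM, MRC1, ITGAM).  Missing markers are dropped with a warning.

PCA is an SVD of the per-gene-centered (covariance, not correlation;
correlation available as an option) panel matrix.  Loadings are orthonormal,
components ordered by variance, and each component's sign is fixed so its
largest-magnitude loading is positive.  Noise thresholds come from B
synthetic samples drawn value-wise from the pooled expression values and
projected onto the loadings; ellipse radii are reported at 1, 2, 3, 5 and
7 projection standard deviations around the median.  External cohorts are
projected onto the fitted loadings; genes absent from the external matrix
(allowed up to 50%) are imputed at the training mean, i.e. contribute 0
after centering.

## Survival analysis

Kaplan-Meier estimation and Cox proportional-hazards regression are
delegated to lifelines (Greenwood variance for the KM curve — lifelines uses
the exponential-Greenwood log(−log) CI transform, which is this package's
convention — and Efron tie handling with Wald intervals for Cox).  The
Peto & Peto modified Gehan-Wilcoxon test is computed directly as a weighted
log-rank statistic whose weight at each event time is the modified pooled
survival estimate S̃(t) = Π_{t_i ≤ t} (1 − d_i/(n_i + 1)), the convention of
the R survival package; the implementation returns the signed z (sign flips
under group exchange) and is verified against lifelines' Peto weighting in
the test suite.

The random-signature null for the survival claim redraws, B = 1000 times,
disjoint pseudo-subsets from the full immune panel gene list with the
reference family's subset cardinalities, scores each sample's pseudo-type-1
posterior, and refits the same Cox model (posterior + molecular pathology).
The one-sided p toward protection is (1 + #{random HR ≤ observed}) /
(B_ok + 1); replicates whose Cox fit fails are excluded and counted.

## Contingency statistics

The cluster-enrichment odds ratio is reported under two readings, because
published values can follow either: the group's odds of a diagnosis against
the full cohort's odds, OR = [k_g/(n_g−k_g)] / [k_c/(n_c−k_c)]; and the
diagnosis-versus-reference-diagnosis reading, OR = (k_g/ref_g)/(k_c/ref_c).
For the published counts (26/370 TN in the large cluster, 60/150 in the
small one, 86/520 cohort-wide, 375 hormone-receptor-positive reference) the
first reading gives 0.38 and 3.36, the second 0.38 and 3.49.  Woolf
intervals on the log odds ratio; no continuity correction, so zero cells are
errors.  Fisher's exact test covers 2×2 composition tests; larger tables use
a seeded Monte-Carlo exact test over fixed-margin tables
(scipy's `random_table`), flagged as such in the output.  P-values are
unadjusted; a Benjamini-Hochberg utility exists but is off by default.

## IHC quantification

Optical density is OD = −log10((I + 1)/256) per 8-bit channel: the +1 offset
avoids log(0) and the 256 denominator makes a saturated channel exactly
OD 0, with ~1 OD per decade of attenuation.  Color deconvolution inverts
OD = densities × S for a 3×3 stain matrix S whose rows are unit-norm stain
vectors — packaged defaults are the published hematoxylin (0.650, 0.704,
0.286) and DAB (0.268, 0.570, 0.776) vectors, with the residual channel the
normalized cross product.  Negative densities (noise, unmodeled absorbers)
are clipped to 0 and the clipped fraction reported.  Mean stain density is
taken over a tissue mask (total OD > 0.15 by default, excluding background
glass); masking and the stain vectors are configurable because staining
protocols vary.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, directly
on the log2 median-ratio scale: i.i.d. Gaussian noise (sd 1) plus group mean
structure.  Defaults are three groups of 50; planted polarization amplitudes
of 1.0 z-units for Th2/M2 in the normal-like group, Th2+Th17/M2 in the
group-1-like (hormone-receptor-like) tumors, and 1.5 z-units for Th1/M1 in
the group-2-like (triple-negative-like) tumors; infiltration offsets
−1.0/+1.0 for groups 1/2; a latent N(0,1) factor loading +1 on WISP1 and
GATA3 and −1 on PPARG (implied WISP1-GATA3 correlation λ²/(λ²+σ²) = 0.5);
WISP1 elevated in tumors (offsets 1.5/0.5); and +1.5 log2 units on IL12RB2
in group 2.  Molecular pathology is drawn per group from the mixture
(ER+/PR+, HER2+, TN) ∝ (300, 48, 26) in group 1 and (75, 27, 60) in group 2,
so pathology correlates with, but never equals, cluster membership — a
degenerate one-to-one assignment would make the Cox covariates collinear.

Survival is exponential with hazard 0.02/month × exp(−0.8 × planted type-1
level), giving a ≈0.30 hazard ratio between the type-1-biased group and the
rest; censoring is an independent exponential whose rate is solved
numerically so the expected censored fraction is 0.5 — enough events for the
survival machinery to be testable while keeping censoring substantial.
The per-sample planted type-1 level and true hazard are emitted as a
separate ground-truth table so recovery tests never read truth through the
analysis path.

What the generator does *not* emulate: array probe effects, batch effects,
tumor purity, gene-gene correlation beyond the planted latent factor, or
non-exponential hazards.  Passing recovery tests therefore demonstrates that
the inference machinery is correct and calibrated under its own model
assumptions, not that those assumptions hold in any real cohort.

The IHC generator renders circular cores through the forward stain model
(densities × S → OD → 8-bit intensity) plus Gaussian pixel noise.  Note that
8-bit quantization alone introduces density errors of order 2×10⁻³, so
exact (1e−3) recovery checks are run on the composed OD image and
quantified-noise checks (±0.02) through the full rendered image.

## Problem sizes

Default problem sizes throughout the tests and the acceptance script —
cohorts of 150-500 samples, B = 1000 bootstrap/ensemble replicates, 10-20
seeded repetitions of recovery experiments — were chosen so each
experiment's Monte-Carlo error is small relative to the effects being
demonstrated.

## Known limitations

- The exact kernel constants of the likelihood (amplitude, bandwidth) are a
  modeling choice; only the qualitative structure (own genes up, competing
  genes down, product over genes) is fixed.  Cohort-level conclusions are
  insensitive to the amplitude over a broad range.
- Cohort inference averages per-sample posteriors; scoring the cohort-mean
  z-vector instead is possible via `cohort_mean_posterior`'s building blocks
  but is not the default.
- No missing-value handling in expression matrices; imputation is out of
  scope.
- The Monte-Carlo exact test for R×C tables is approximate at its stated
  resolution (add-one over B samples), unlike the 2×2 Fisher path.
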