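# immunopolar

Model-based inference of immune-cell polarization from bulk tumor gene
expression, with the cohort analysis that surrounds it: Ward clustering of
immune gene panels, infiltration scoring, PCA with bootstrap noise
thresholds, survival statistics with a random-signature hazard-ratio null,
contingency statistics, and immunohistochemistry stain quantification by
color deconvolution.

## The problem

Bulk tumor expression profiles mix malignant, stromal and immune cells.  Two
properties of the immune compartment matter for anti-tumor immunity: how many
immune cells are present (infiltration) and what they are doing
(polarization).  T helper cells polarize into Th1 / Th2 / Th17 / iTreg
states and tumor-associated macrophages into M1 / M2; type 1 (Th1, M1)
polarization supports cytotoxic cell-mediated immunity while type 2
polarization suppresses it.  This package infers, from a homogenized tissue
sample alone, which polarization state the data are most consistent with.

## The model

Each subset k of a signature family is a model M_k.  Let E_k be the genes
exclusive to subset k (polarization is treated as mutually exclusive: genes
shared between subsets are uninformative and removed), and let z be the
cohort z-scores of the log2 median-centered expression values.  With target
amplitude a > 0, the likelihood of a sample under M_k is a product of
per-gene Gaussian kernels,

    log p(z | M_k) = -1/2 Σ_{g∈E_k} (z_g - a)² - 1/2 Σ_{j≠k} Σ_{g∈E_j} (z_g + a)²,

i.e. a subset's own genes should be up-regulated and competing subsets'
genes down-regulated.  Bayes' rule with uniform priors π_k = 1/K gives the
per-sample posterior

    p(M_k | z) = p(z | M_k) π_k / Σ_j p(z | M_j) π_j,

and a cohort's polarization bias is the mean posterior over its samples.
Significance is assessed against an empirical null: bootstrap resampling
(B = 1000) from the pooled set of all observed z-values builds equal-size
cohorts that carry no polarization information, and the add-one empirical
p-value locates the observed mean posterior in that null.

The same skepticism is applied to survival claims: the hazard ratio of the
inferred Th1 posterior in a Cox model (survival ~ p(Th1) + molecular
pathology) is compared against an ensemble of random gene signatures of
identical subset sizes drawn from the same panel.

## Worked example

Everything below is runnable without any downloads; the built-in generator
produces a cohort with a normal-like group, a hormone-receptor-like tumor
group (type 2 biased, low infiltration) and a triple-negative-like tumor
group (type 1 biased, high infiltration), plus survival tied to the planted
type-1 level.

```python
import immunopolar as ip

expr, clin, truth = ip.generate_cohort(ip.SyntheticCohortConfig(seed=7))
zm = ip.zscore(expr)
fam = ip.thelper_family()                      # Th1/Th2/Th17/iTreg, reduced
member = truth.set_index("sample")["group"]
means = ip.cohort_mean_posterior(zm, fam, membership=member)
print(means.round(3))
```

```
          Th1    Th2   Th17  iTreg
group
group1  0.032  0.379  0.456  0.133
group2  0.671  0.002  0.071  0.256
normal  0.116  0.591  0.076  0.217
```

The group planted with a 1.5-sigma Th1 bias shows a 0.67 mean Th1 posterior;
the normal-like group is Th2-dominated.  Against the bootstrap null the
group-2 Th1 bias is significant at the resolution of B = 1000 replicates:

```python
null = ip.bootstrap_null(zm, fam, n_cohort=50, B=1000, seed=7)
p = ip.empirical_pvalue(float(means.loc["group2", "Th1"]), null, "Th1")
print(p)            # 0.000999000999000999  (= 1/1001, observed beats every replicate)
```

Contingency statistics work directly from counts — here, triple-negative
diagnoses in a 370-patient cluster versus the 520-patient cohort:

```python
r = ip.odds_ratio_vs_cohort(26, 370, 86, 520)
print(f"{r.odds_ratio:.2f} ({r.ci_lower:.2f}-{r.ci_upper:.2f})")   # 0.38 (0.24-0.60)
```

A one-command demo of the whole pipeline (cluster → infiltration →
polarization + null → PCA → survival → stats) on synthetic data:

```sh
immunopolar run-all --seed 7 --outdir demo_out
```

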