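# Methods

This note documents the statistical machinery in `netscreen`: the models
and their assumptions, the parameters that matter, what the synthetic
generator does and does not emulate, numerical choices, and known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Single-sample enrichment scores

**Kernel-CDF walk score (`gsva_scores`).** The NET score is a
nonparametric, unsupervised per-sample enrichment statistic. For gene
*i* with sample standard deviation *sᵢ*, expression is converted to a
smoothed empirical CDF with a Gaussian kernel,
F̂ᵢ(xᵢⱼ) = n⁻¹ Σₖ Φ((xᵢⱼ − xᵢₖ)/hᵢ), bandwidth hᵢ = sᵢ/4. Within each
sample genes are ranked by F̂ descending (rank rᵢⱼ ∈ 1..p) and mapped to
the symmetric statistic zᵢⱼ = |p/2 − rᵢⱼ|^τ with τ = 1, which up-weights
both tails of the expression distribution. Walking down the ranked
list, in-set genes add zᵢⱼ/Σ_set z and out-of-set genes subtract
1/(p − m); the score is the largest positive plus the largest negative
deviation of the running sum ("max-diff" form), bounded in [−1, 1].
Because the kernel CDF is invariant to per-gene positive-affine
transforms, so is the score — normalization of the input matrix (as
long as it is monotone per gene) does not matter. Constant genes have
an undefined kernel (zero bandwidth) and are dropped with a warning.

The O(p·n²) kernel evaluation is the pipeline's hot spot; it is
computed by a numba-jitted erf kernel that exploits the antisymmetry of
the pairwise difference matrix (Φ(−t) = 1 − Φ(t)), with a vectorized
`scipy.special.ndtr` fallback. Both routes evaluate the same statistic
(libm `erf` and `ndtr` agree to ~1e-15); correctness is pinned by a
pure-Python brute-force oracle at 1e-10 on hundreds of random
instances.

**ssGSEA (`ssgsea_scores`).** Genes are ranked per sample by raw
expression; the score accumulates, over all list positions, the
difference between the weighted in-set cumulative fraction (weights =
rank value^α, α = 0.25, where the top gene has rank value p) and the
uniform out-of-set cumulative fraction. Optional range normalization
divides the whole score matrix by (max − min). Whether hallmark scores
should be normalized is left to the caller; both behaviors are exposed
because downstream Pearson correlations are insensitive to the global
rescaling.

**Marker means (`marker_mean_score`).** Immune/stromal cell abundance is
estimated as the arithmetic mean of a population's marker genes per
sample — the transparent published form of marker-based deconvolution.

**Pre-ranked GSEA (`preranked_gsea`).** Classic running-sum enrichment:
in-set increments |metric| normalized to the in-set total, out-of-set
decrements 1/(N − m), ES = the running sum at its maximum absolute
deviation. The null is gene-set permutation (random same-size sets,
seeded); NES divides ES by the mean |null ES| of matching sign, and p is
the add-one-corrected one-sided tail among same-sign nulls. Gene-set
permutation is used because single-sample pipelines have no phenotype
labels to permute.

**Tie-breaking.** Every ranking in the package breaks ties by input gene
position (stable sort), making all scores deterministic functions of the
input.

## Survival models

Kaplan–Meier curves use the product-limit estimator with events
processed before censorings at tied times. The two-group log-rank test
sums observed-minus-expected events over distinct event times with the
hypergeometric variance; it is implemented directly on numpy arrays
because the cutpoint search evaluates it at every admissible threshold,
and it is cross-checked against lifelines in the test suite. Univariate
Cox models are fit with lifelines (Newton–Raphson on the
Efron-corrected partial likelihood); fits whose |β| or SE exceed 10 per
covariate SD are flagged `converged=False` (monotone likelihood /
perfect separation) and their estimates must not be consumed.

**Maximally selected cutpoint.** The high/low NET split per cancer type
maximizes the log-rank statistic over all distinct score values inside
the 10%–90% quantile window (configurable). The reported p at the
selected threshold is **selection-biased** and is flagged as such; no
minP adjustment is applied, matching the common usage of the tool
family this emulates. Consequences: under a true null, directional
calls occur more often than the nominal α, which is why neutral cancer
types occasionally leak into a survival class.

**Survival-direction classes.** A cancer type is *favorable* when the
cutpoint log-rank p < 0.05 and the high-score group has the larger KM
median survival, *poor* when smaller, else *neutral*. The direction is
taken from the KM medians rather than from the hazard ratio because the
curve ordering is unambiguous; when medians are tied or unreached, the
sign of the high group's observed-minus-expected event count decides.
The HR reported alongside is high-vs-low from a Cox fit on the group
indicator.

## The screening cascade

Per cancer type with ≥10 samples, every candidate gene (the signature
itself is excluded to avoid self-correlation) is Pearson-correlated with
the NET score; pairs with |r| > 0.35 and p < 0.05 qualify. A gene is
*core* for a survival class when it forms qualifying pairs in ≥5 cancer
types of that class (counting both signs); *class-exclusive* genes are
positively correlated in ≥6 types of one class and ≤1 of the other
(positive-sign pairs only — the exclusivity screen targets co-activated
genes; negative pairs remain in the pair table, flagged by sign).
Neutral types count toward neither class. The exclusive-set identities
(exclusive = core minus overlap) hold exactly by construction and are
asserted on every run.

**Key-gene nomination.** Among poor-exclusive genes the nominee is
selected by, lexicographically: significant over-expression in pooled
poor-class vs favorable-class tumors (BH p < 0.05 and log2FC ≥ 1, i.e.
fold change ≥ 2), then log2FC, then the number of poor-class types with
a positive qualifying pair, then mean r, then gene name. Leading with
the expression contrast is deliberate: exclusivity already guarantees
recurrent positive correlation, so recurrence counts and mean r barely
distinguish exclusive genes, whereas class-restricted over-expression is
the discriminating signature of the target gene.

**Combined stratification.** NET score and the key gene are each
dichotomized (median by default; mean and optimal-cutpoint are options),
samples form four joint groups, and a Cox model contrasts high/high
against low/low (mixed groups excluded), alongside a 4-group log-rank.
The median default is the conservative choice where no rule is given;
the optimal cutpoint would inflate the contrast by selection.

**Differential expression.** Welch's t per gene with
Welch–Satterthwaite degrees of freedom and Benjamini–Hochberg control.
An empirical-Bayes moderated t (limma-style) was deliberately not used:
the screen consumes only signs and thresholds at large per-group sample
sizes, where moderation is immaterial; this is a documented deviation
from the moderated-t convention. "Fold change > 2" is interpreted as
|log2FC| ≥ 1 because expression is log2-scale throughout. Genes
constant in both groups get t = 0, p = 1 rather than an error.

**Other statistics.** Pearson p-values come from the exact t transform
with n − 2 df (p = 0 at |r| = 1). Group comparisons (e.g. therapy
response) use Mann–Whitney U with `method='auto'` — exact enumeration
for small tie-free samples, tie-corrected normal approximation
otherwise — chosen for robustness over a Welch t, which remains
available. Over-representation uses the upper-tail hypergeometric
P(X ≥ k) against a user-supplied universe with BH control across sets;
no annotation databases are bundled. The EMT score is
Σ z(mesenchymal) − Σ z(epithelial) per sample (z across samples,
ddof = 1), so higher = more mesenchymal; the sum (rather than mean) is
equivalent up to a positive scale for every downstream use.

## Synthetic data: what it emulates, and what it does not

One latent activity a_s ~ N(0,1) per sample drives everything — this is
the minimal structure the analysis can see, because every screen stage
reduces to pairwise correlations with the NET score or to hazards in
a_s:

- **Signature genes**: x = μ_g + λ·a_s·σ + ε with ε scaled so the
  population correlation with a_s is exactly λ (default 0.8);
  para-tumor samples are shifted down by 1.0 log2 unit.
- **Planted NRGs** (default 30 per class): the same construction with
  correlation `planted_r` (default 0.5), active only in tumors of one
  survival class and pure noise elsewhere.
- **Key gene** (SPP1 analog): the first poor-class NRG, plus a mean
  shift of 1.2 log2 units in poor-class tumors.
- **EMT programs** (15 genes each): mesenchymal genes load (+0.5) and
  epithelial genes load (−0.5) on the standardized product
  a_s · z(key-gene expression).
- **Survival**: time ~ Exponential(h₀·exp(γ_c·a_s)), h₀ = 1/1000 per
  day, γ = +0.6 in poor, −0.6 in favorable, 0 in neutral types;
  censoring Uniform(200, 2000) days, event = death before censoring.
  Longer censoring horizons therefore observe more events.
- **Layout**: 22 cancer types (6 favorable / 7 poor / 9 neutral), 150
  tumors + 20 normals per type, 2000 genes. All draws come from one
  seeded generator; a fixed seed reproduces the dataset bit for bit.
  `null_dataset` zeroes every loading, shift, and γ.

Not emulated: count-level noise (negative binomial), batch effects,
copy-number structure, gene–gene networks beyond the single factor, and
any NET × gene interaction in the hazard. The last point matters for
interpretation: the pooled high/high-vs-low/low survival contrast and
the key gene's marginal hazard association are *structurally modest*
under this generator — the hazard depends on a_s only, the favorable
class inverts the NET effect, and the class marginal survival
distributions coincide — so those contrasts have limited power at the
default effect sizes even with perfect scoring (the tests quantify
this). Passing tests demonstrate planted-signal recovery under this
idealized model, not performance on real RNA-seq.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| `r_nrg` | 0.35 | \|Pearson r\| threshold for an NRG pair (per cancer type) |
| `r_hallmark` | 0.30 | \|r\| threshold for hallmark/immune association screens |
| `p_sig` | 0.05 | two-sided significance level throughout |
| `fc_min` | 2.0 | linear fold-change threshold (log2FC ≥ 1) |
| `recurrence_min` | 5 | cancer types per class for a core NRG |
| `exclusive_in_min` / `exclusive_out_max` | 6 / 1 | positive-pair counts for class exclusivity (">5" and "<2") |
| `n_quantile_groups` | 4 | quantile strata for the pooled survival view |
| `cutpoint_quantile_range` | (0.10, 0.90) | admissible window for the maximally selected cutpoint |
| `perm_count` | 1000 | permutations for pre-ranked GSEA nulls |

`r_nrg` and `r_hallmark` are separate fields on purpose; the screens
they govern have different thresholds and must not be conflated.

## Numerical choices and degenerate inputs

- Expression is assumed log2-scale; `log2_transform` applies log2(x+1)
  on load for raw FPKM input. Duplicate gene rows collapse to the row
  with the highest mean. Values round-trip bit-exactly through the TSV
  writer/reader (`%.17g` on write, correctly rounded parse on read).
- Quantile stratification uses type-7 (linear) quantiles with ties
  assigned to the lower group; an all-constant score vector puts every
  sample in group 1 with a warning.
- Cox convergence requires a score norm below lifelines' default
  tolerance; the separation diagnostic above guards downstream
  consumers. Constant covariates and all-censored data are errors, not
  silent NaNs.
- Pipeline scoring runs per cancer type (kernel CDFs and rank walks
  inside one cohort), which both mirrors the per-cancer analysis design
  and keeps the O(p·n²) kernel cost linear in the number of types. The
  default problem size (22 types × 150 tumors × 2000 genes) runs the
  full cascade in well under a minute per dataset on one core.

## Known limitations

- The selection-biased cutpoint p inflates directional classification
  of truly neutral cancer types (no minP correction is applied).
- Pooled class-DE compares tumors across cancer types without batch
  adjustment; on real data this conflates type-level composition with
  the signal of interest.
- The bundled default NET signature is a partial reconstruction of
  commonly reported NET constituents and should be replaced by the
  user's curated signature for real analyses (the generator supplies
  its own synthetic signature).
- Marker-mean cell scores are a transparent stand-in for full
  deconvolution; they ignore marker covariance and platform effects.
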