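# Methods

## Scope and model of the data

The package targets a five-arm dietary dose design: a selenium-deficient
basal diet (SD, measured 0.056 mg Se/kg), selenium yeast at three doses
(SY0.15 → 0.211, SY0.30 → 0.377, SY0.45 → 0.552 mg/kg measured) and
sodium selenite at the top dose (SS0.45 → 0.480 mg/kg), with ten birds
sampled per group. Inputs are a gene-level count matrix, an OTU count
table, a sample→group/dose design, per-bird phenotypes (laying rate %,
ileal Se content mg/kg) and GMT gene sets. All stages operate on the
sample intersection of these tables, ordered as in the design table.

## Switched ON/OFF genes

State calls per gene × group: OFF when the within-group median is 0 and
the sample SD (n−1 denominator) is ≤ `sd_bound` (1.0 counts); ON when
the median is > 0; INDETERMINATE when the median is 0 but the SD bound
fails. The SD bound is a tightness condition on the silent state only —
applying it to the expressed group as well would reject genuinely
induced genes. A switch event is (baseline OFF ∧ treatment ON) or the
reverse, supported by the two-sided rank-sum test at raw P < α = 0.05
(no multiplicity correction by default, `bh_correct=True` available).

The rank test treats the two groups as independent samples (they are
different animals; a paired signed-rank statistic is undefined for
unpaired groups). For pooled sizes ≤ 14 the null is enumerated exactly
over all C(n, n₁) group assignments using doubled mid-ranks (integer
arithmetic, so ties are exact); two-sided extremity is |U − n₁n₂/2|.
Above that bound the normal approximation with tie and continuity
corrections is used. The reported U is the larger one-sided
Mann–Whitney statistic, symmetric in the two samples.

### The variance / quartile-deviation filter

The upstream filter drops genes whose sample variance exceeds 1.5 × the
quartile deviation (Q₃ − Q₁)/2 (linear-interpolation quartiles; strict
inequality, so equality retains). Note the rule compares a squared-unit
quantity to a linear-unit one. On count-scale data this is extremely
aggressive: any gene with typical counts in the tens has variance far
above its semi-interquartile range, and a gene that is zero in most
samples but expressed in one group has QD = 0 and positive variance, so
every switching gene fails it. Running the default simulation through
the filter removes all 2000 genes. The filter is therefore implemented
literally as its own stage (counts are reported in the run summary) but
is **not** applied inside `detect_switches` unless requested via its
`factor` argument or the `apply_variance_filter_to_switches` config
flag — otherwise the detector could never find anything.

One fragment of the original procedure's description ("the mean of gene
expression and each gene should show …") is grammatically incomplete;
no condition on the mean is implemented.

## Normalization and the DE screen

Size factors are median-of-ratios: the per-sample median, over genes
positive in every sample, of count / per-gene geometric mean. Factors
are defined only up to one global scalar; scaling one sample's column by
c multiplies its factor by c *relative to the others* and leaves the
normalized matrix unchanged up to that scalar (the invariant is tested
in this quotient form).

The DE stage is deliberately a stand-in, not a negative-binomial GLM:
per-gene two-sided rank-sum p, BH correction within each
baseline-vs-treatment contrast, log2 fold change of group means with
pseudocount 1, pass at q < 0.05 ∧ |log2FC| > 1.0. The method tag is
recorded in the output metadata. Downstream stages only need *a* DEG
list; dispersion estimation, shrinkage and covariates are out of scope.

## Dose-profile clustering

Gene series over the ordered SY gradient (SD → SY0.15 → SY0.30 →
SY0.45, d = 4; the selenite arm is not part of the gradient):
x_g = log₂((μ_g + 1)/(μ_baseline + 1)) of normalized group means, so
x₀ = 0 by construction. Model profiles are all integer trajectories of
length d starting at 0 with steps in [−c, c] (c = 1 default, 26
profiles), the constant profile removed. If the pool exceeded the
budget m = 100, a greedy max-min selection under distance 1 − r would
thin it (seeded at the profile with the largest summed distance, ties
to the lower index); at the default geometry the budget exceeds the
pool and selection is the identity.

Assignment is argmax Pearson r between series and profile levels, with
strict retention at r > 0.88; zero-variance series are unassigned.
Significance of a profile's gene count uses a within-gene permutation
null: entries beyond the anchored baseline are shuffled and
re-assigned; p = (1 + #{null ≥ observed})/(1 + n_perm), Bonferroni
across the library. n_perm must exceed m/α − 1 (≈ 520 at α = 0.05 over
26 profiles) for the permutation floor to be able to reach
significance; tests use 600, the pipeline default is 1000.

Adjacent cumulative-step profiles are highly correlated (e.g.
(0,1,2,3) vs (0,1,2,2) have r ≈ 0.98), so series-level noise with SD
0.25 caps argmax accuracy near 80% no matter the rule. At the
pipeline's operating point the series entries are means over ten birds;
with per-bird log2 noise of SD 0.25 the series noise is ≈ 0.08 and
assignment accuracy is ≈ 99%. Recovery experiments therefore simulate
noise at the bird level and build series through the normal path.

## ssGSEA

Per sample, genes are ranked by expression descending (ties broken by
gene identifier, so scores are deterministic); the rank magnitude of
the i-th gene from the bottom is i. The score of set S is
Σ_positions (P_in − P_out) where P_in is the cumulative |rank|^τ-weighted
fraction of in-set genes and P_out the cumulative unweighted fraction of
out-of-set genes; τ = 0.25 (τ = 0 makes small examples hand-checkable:
with 3 genes ranked 3 > 2 > 1 and S = {top}, the walk gives
1 + 0.5 + 0 = 1.5). Scores depend only on within-sample ranks. Sets
with empty intersection, or covering every gene, are dropped with a
warning. No cross-sample normalization is applied by default
(`normalize=True` divides by the global score range).

The display filter keeps sets whose range-normalized score SD across
samples is ≤ 0.1. As written this retains the *low*-variance sets; it
is a stability filter for visualization, not a feature selector, and is
implemented literally.

## Correlation screens

Pearson r with the asymptotic two-sided p from t = r√((n−2)/(1−r²)),
t-distribution with n − 2 df, after pairwise deletion of missing
values; |r| within 1e-12 of 1 is reported as ±1 with p = 0; constant
features are suppressed with a warning. Pass criteria are strict:
p < p_max and |r| > r_min, defaults (0.05, 0.6); a named preset
(0.01, 0.6) covers the stricter selenoprotein-style screen. OTU
abundances enter as per-sample proportions; `log_relative_abundance`
provides log10 proportions, which match a log-scale generative link
better. The pathway↔OTU screen is flat all-against-all with BH
correction — a deliberate simplification of hierarchical
all-against-all testing, recorded in the edge-table metadata. The
OTU↔phenotype screen emits every defined edge with sign and magnitude
(no pass threshold), since those correlations are reported as signed
associations rather than filtered.

## Constrained correspondence analysis

With P the count table scaled to grand total 1, row masses r, column
masses c: Q̄ = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}; total inertia = ΣQ̄²
(= χ²/N). Constraints are centered under row weights and row-weighted
by √r; Q̄ is projected onto their column space by least squares. SVD of
the fitted part gives constrained axes (eigenvalues = singular values²)
and SVD of the residual the unconstrained axes; the two sets partition
the total inertia. Scores use the symmetric ("scaling 3") convention —
sites D_r^{−1/2}U√Λ^{1/2}, features D_c^{−1/2}V√Λ^{1/2} — and axis
signs are fixed by making the largest-magnitude feature score positive.
Biplot scores are row-weighted correlations of each constraint with the
axes. Zero-total OTUs are dropped with a warning; zero-total samples
are an error.

VIF pruning first removes exactly collinear columns by greedy QR rank
detection (earliest independent columns kept), then repeatedly drops
the column with the largest VIF (1/(1−R²) against the others plus an
intercept) while max VIF > 10, ties to the later column.

## Synthetic data generator

The generator is a pure function of its configuration (including the
seed); independent substreams (expression / phenotypes / OTUs / gene
sets) are derived via CRC-tagged seed sequences so the pieces are
individually reproducible.

* **Expression**: negative binomial with var = μ + 0.2 μ² (single
  dispersion, no gene-wise trend — enough to exercise every stage).
  Null gene means are log-normal(log 100, 1). Switched-on genes have
  NB mean 0.05 everywhere (median 0, SD ≤ 1 with high probability)
  except one randomly chosen SY group at mean 50; switched-off genes
  are the mirror image. Three 30-gene trend classes follow
  selenoprotein-like dose shapes over the SY gradient at two-fold
  amplitude — monotone decrease under supplementation, peak at the
  lowest SY dose, monotone increase with dose — with the selenite arm
  at the basal level.
* **Phenotypes**: laying rate per bird ~ Normal(group mean, SEM×√5)
  using the 12-week group means 63.52 / 65.97 / 71.96 / 65.16 / 63.47 %
  (SY0.30 highest); ileal Se content ~ Normal(0.1 + 1.5·dose, 0.08)
  mg/kg, spanning ≈ 0.2–1.0 mg/kg across arms.
* **OTUs**: a Dirichlet base composition (log-normal concentration);
  ten linked OTUs replace their log abundance with ρ·z + √(1−ρ²)·ε
  where z is a standardized driver — a planted gene's log2 expression
  or a phenotype — and ρ = 0.8 by default; counts are multinomial at
  50,000 reads/sample (optional log-normal depth variation exercises
  normalization).

What the generator does **not** emulate: gene–gene correlation, batch
effects, library-size trends (unless enabled), phylogenetic or
taxonomic structure in the OTUs, and compositional interactions beyond
the shared multinomial denominator. Passing recovery tests therefore
demonstrates correctness of the chain's logic and calibration under the
stated model, not robustness to real-data pathologies.

## Numerical and design choices

* Exact rank-sum enumeration bound: pooled n ≤ 14 (C(14,7) = 3432
  assignments, integer rank arithmetic).
* Degenerate inputs: identical pooled values → p = 1; zero-variance
  series → unassigned; degenerate global score range → SD filter
  retains all; zero-variance correlation features → edge suppressed.
* Pseudocount 1 in all log2 ratio computations (fold changes, dose
  series); 1e-6 in log10 relative abundances.
* Eigenvalue cutoff 1e-10 (relative) separates numerically-zero CCA
  axes; the constrained/unconstrained split preserves the inertia sum
  to well below 1e-8.
* Problem sizes in the recovery experiments (2000 genes × 50 samples ×
  20 seeds for switch recovery; 400 genes for profile assignment; 100
  seeds of 120 genes / 30 OTUs for the planted-pair screen) were chosen
  to give stable Monte-Carlo estimates at interactive runtimes.
* The run summary separates wall-clock timings from scientific content,
  so reproducibility checks can compare everything else byte-for-byte.

## Known limitations

The DE stand-in has less power than a count-model GLM at small n and no
shrinkage; the variance/QD filter is faithful to its description but
unusable as a gate (see above); profile merging of near-duplicate
model profiles is not implemented; CCA axis significance (permutation
ANOVA) and partial/conditioned CCA are out of scope.
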