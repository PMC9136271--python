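# selenoscope run configuration — every key shown with its default.
# `selenoscope run --config run.yaml`

outdir: runs/demo          # all stage outputs + summary.json land here
seed: 0                    # drives simulation and permutation tests

# --- inputs -------------------------------------------------------------
simulate: true             # generate a synthetic bundle under <outdir>/fixtures
sim_overrides: {}          # any SimConfig field, e.g. {n_genes: 500, rho: 0.9}
# With simulate: false, provide the five paths instead:
# counts: counts.tsv       # genes × samples, first column gene ids
# otus: otus.tsv           # OTUs × samples (+ optional taxonomy column)
# design: design.tsv       # columns sample_id, group, dose
# phenotypes: phenotypes.tsv  # sample_id, laying_rate, se_content ("NA" = missing)
# gene_sets: sets.gmt

baseline_group: SD
dose_order: [SD, SY0.15, SY0.30, SY0.45]   # the SY gradient; SS0.45 excluded

# --- differential expression stand-in ------------------------------------
lfc_threshold: 1.0         # pass requires |log2FC| > 1.0
fdr_threshold: 0.05        # and BH q < 0.05 (within each contrast)

# --- switched ON/OFF detection -------------------------------------------
switch_alpha: 0.05         # raw rank-sum p threshold
sd_bound: 1.0              # max group SD for an OFF call (counts)
variance_filter_factor: 1.5          # reported as its own stage
apply_variance_filter_to_switches: false  # see docs/methods.md before enabling

# --- dose-profile clustering ---------------------------------------------
max_profiles: 100          # model-profile budget (26 candidates at d=4, c=1)
profile_step: 1            # max unit change between consecutive doses (c)
min_r: 0.88                # strict retention threshold on Pearson r
n_perm: 1000               # permutation null size

# --- ssGSEA ----------------------------------------------------------------
tau: 0.25                  # rank-weight exponent
score_sd_max: 0.1          # display filter on range-normalized score SD

# --- correlation screens ----------------------------------------------------
r_min: 0.6
p_max: 0.05

# --- constrained correspondence analysis ------------------------------------
vif_threshold: 10.0        # iterative collinearity pruning

skip_stages: []            # e.g. [cca] to skip ordination
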