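# Methods

## Model and procedure

The pipeline treats a gene's two poly(A) sites (PAS) as a 2 × S count
table: deduplicated read 3′-end counts for the proximal (P) and distal
(D) site across S samples from two conditions. Counts are modeled as
negative binomial, NB(μ, φ) with Var = μ + φμ² (NB2), and each gene is
fit with the log-link GLM

    log μ = log(effective library size) + β₀ + batch + condition + PAS
            + γ · condition×PAS

The interaction coefficient γ is the natural-log change of the P/D usage
ratio between conditions; the null γ = 0 is tested with a likelihood-ratio
statistic 2(ℓ_full − ℓ_reduced), clipped at zero and referred to χ² with
1 df. Both fits use iteratively reweighted least squares at fixed φ
(weights μ/(1+φμ), working response η + (y−μ)/μ), with step-halving on
the log-likelihood, convergence at relative log-likelihood change ≤ 1e-8,
and a 100-iteration cap (non-convergence flags the gene and yields p = NA).
The linear predictor net of offsets is clamped to ±30 to keep degenerate
all-zero cells finite; rank-deficient designs (e.g. batch confounded with
condition) raise an error naming the confounded columns.

A shift is called significant by the joint rule **q < α (default 0.05)
and |log2 ratio change| > log2(fold) (default 2)**. The ratio change is
computed on TMM-scaled, replicate-pooled counts with a pseudo-count of
0.5 added to each pooled cell — the pseudo-count protects the ratio at
zero cells, while the GLM itself handles zeros natively and uses none. An
alternative would be to read the fold change off the fitted γ; the pooled
estimator was chosen as the primary definition because it is transparent,
monotone in the data, and independent of fit convergence; γ is reported
alongside.

## Normalization

TMM (trimmed mean of M-values) factors correct compositional bias. The
reference sample is the one whose upper-quartile count fraction is
closest to the mean upper quartile. For each sample, rows with zeros in
either sample are dropped; M (log2 ratio) and A (log2 abundance) values
are rank-trimmed (30% on M, 5% on A, double-sided) and the remaining M
values averaged with inverse asymptotic-variance weights; factors are
rescaled to geometric mean 1. Library sizes default to column sums.
Tables with fewer than two shared nonzero rows fall back to factor 1 with
a warning. Effective library size = library size × factor; its log is the
GLM offset.

## Dispersion

The common φ maximizes the Cox-Reid adjusted profile likelihood
Σ_g [ℓ_g(β̂) − ½ log det(XᵀŴX)] over genes, on a log-spaced grid
(1e-4…10) refined by bounded scalar minimization (tolerance 1e-3 on
log φ). Optional tagwise estimates shrink per-gene maximizers toward the
common value on the log scale with weight prior_df/(prior_df +
residual_df), prior_df = 10 — with infinite prior_df the tagwise values
collapse to the common φ. Data with no replication anywhere are rejected
with instructions to supply a fixed φ.

## Multiple testing

Storey q-values: π̂₀(λ) = #{p > λ}/(m(1−λ)) on λ = 0.05…0.95, cubic
polynomial smoother evaluated at λ = 1, clipped to (1/m, 1]; then
q_i = π̂₀ · min_{p_j ≥ p_i} (m p_j / rank_j). Below 100 tests the π₀
smoother is unstable, so the method falls back to BH (π₀ = 1)
automatically.

## PAS calling

Reads are deduplicated per sample (`umi`: unique (site, strand, UMI);
`position`: unique site; `none`), then distinct 3′-end positions are
clustered by single linkage per (chromosome, strand) with an inter-site
gap ≤ 24 nt. The default gap must exceed twice the simulated read scatter
(±5 nt) and stay below typical inter-PAS spacing; it is exposed as a
parameter. The representative cleavage site is the modal position over
pooled counts, ties broken toward the 3′-most member (the downstream-most
cleavage is the conservative PAS coordinate). Clusters are assigned to
the unique strand-matched gene whose span contains the cleavage site
(multi-gene overlaps are rejected and logged). Genes keep their two
highest-count clusters and are retained when the pooled two-PAS count is
≥ 20 and the minor PAS holds ≥ 5% of the pooled total; both cutoffs are
parameters because the two-PAS gene definition is intentionally a tunable
family, not a single fixed rule.

## Classification and screen

The major PAS of a condition is the site with >50% of the pooled,
TMM-scaled two-PAS counts (an exact 50/50 split has no major PAS; a
raw-count mode is available). A gene is CDS-APA when at least one
cleavage site is **not strictly downstream** of the CDS end in
transcription order — a site exactly at the CDS end counts as CDS-APA, a
conservative boundary. The functional filter keeps genes that are
significant, switched their major PAS, and are CDS-APA.

The motif scanner enumerates every UGUA start (overlaps allowed) and
emits a twin hit for every pair of starts exactly 5 apart; restricted
twins require the spacer ∈ {C, U}. Distances run from a motif's first
base to the cleavage site, and a motif is in-window iff its first base is
within the window. Windows are upstream-only by default (the UGUA element
is enriched roughly 40–100 bp upstream of cleavage sites, and all screen
outputs in practice lie there); a downstream-inclusive mode exists. The
candidate rule is: significant shift, major-PAS switch (toggleable), ≥1
twin UGUA within 100 bp upstream of the **loss-of-use** cleavage site
(the PAS whose relative usage fell in condition B), and zero twin hits in
the other PAS window. The exclusion tests twin motifs, matching the
screened pattern; a strict mode excludes even single UGUAs.

## Synthetic data

`simulate_counts` draws counts with log μ = log(lib) + a_g + b_gk +
batch + δ_g·ln2·1[B]·1[P]: gene abundance a_g is lognormal around
`mean_gene_count` (log-SD 0.4, mean-preserving); the baseline proximal
fraction is uniform on [0.2, 0.8] to exercise the major-PAS logic;
per-(gene, batch) effects are N(0, `batch_effect_sd`, default 0.1);
δ_g = ±`delta_log2` for shifted genes. Designated candidate genes use a
fixed baseline proximal fraction of 0.30 with a positive δ, so the major
PAS switches D→P and the loss-of-use PAS is always distal with the twin
motif planted there (defaults: 6 candidates, `UGUACUGUA` at 50 nt
upstream). Defaults φ = 0.1 and mean 200 counts/gene are calibration
choices representative of moderately deep 3′-end libraries, not measured
values.

`simulate_dataset` lays each gene on its own chromosome (alternating
strands; every third gene CDS-APA, with the CDS end between the two
sites), separates the two cleavage sites by `pas_window` + 100 nt, and
overwrites the `pas_window` bases upstream of each site with
rejection-sampled windows: candidate loss-of-use windows contain exactly
the planted twin and nothing else; every other window is UGUA-free. This
gives the screen an exact truth set — a property of the fixture, not of
real genomes, where background UGUAs are common and screen specificity
depends on the exclusion window.

Read 3′-ends are scattered around true sites with a deterministic
balanced offset cycle (0, 0, −5, 0, +5, 0, …): support is ±5 nt, so
clustering must merge an 11-position spread, but the true site remains
strictly modal for every count, making site recovery exact by
construction. I.i.d. uniform jitter would occasionally displace the mode
and make exactness a probabilistic statement; the deterministic cycle
trades a little realism for a sharp invariant. Each read carries a unique
UMI, so UMI deduplication is lossless and read conservation is exact.

What the generator does **not** emulate: internal-priming artifacts,
>2-PAS genes, multi-gene loci, mappability gaps, UGUA-containing genomic
background, and library-specific positional biases. Passing tests
therefore certify the statistical machinery and the screen logic, not
robustness to those artifacts.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 20 genes for the
LRT-vs-grid-search oracle comparison (agreement < 1e-4); 2000 genes,
3+3 replicates, φ = 0.1, mean 200 for type-I error (nominal 5% band
3–7%, KS uniformity) and, with δ = 2 (a 4-fold ratio change), for power
(≥90% under the joint rule) and interaction-coefficient recovery (≤10%
bias); 200 genes, 4 replicates for dispersion recovery (φ̂ ∈
[0.07, 0.14]); 200–500 genes for exact PAS recovery and the end-to-end
candidate screen (δ = 3, mean 400, φ = 0.05 — chosen so the planted
major-PAS switches and significance calls are near-certain events and
the expected recovery is exactly the planted candidate set); and 1000
random 300-nt sequences for the motif-scanner oracle.

## Known limitations

- Two conditions, two PASs per gene, categorical batch only; no
  quasi-likelihood F-test, no continuous covariates.
- The exact cleavage-site recovery guarantee is specific to the synthetic
  scatter model; on real data the modal position is an estimator, not an
  identity.
- The ΔΔCt module assumes ideal 2-fold-per-cycle amplification; no
  efficiency correction or melt-curve QC.
- The BED6 entry point presumes upstream alignment and adapter handling
  were already done; BAM conversion is out of scope.
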