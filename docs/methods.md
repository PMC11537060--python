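# Methods

This note records the models, parameter choices and numerical details
behind `spongenet`, and what the synthetic data do and do not show.

## Data model and normalization

The universal input is a dense non-negative integer ASV × sample count
matrix with unique ids, read from TSV or BIOM-JSON v1.0 (dense or
sparse). Relative abundances divide each sample column by its total;
depth normalization, where wanted, is seeded rarefaction without
replacement (multivariate hypergeometric per sample) to a common
depth — the standard amplicon choice, and the one that keeps the
abundance-class thresholds comparable across samples. The prevalence
filter for network construction keeps ASVs detected in strictly more
than a fraction (default 0.5) of the samples *of the group being
networked*; the per-group reading is used because networks are built
per host.

## Abundance classes

With per-ASV relative-abundance extremes m = min, M = max and
thresholds l = 10⁻⁴, u = 10⁻²: AT if m ≥ l and M ≥ u; DT if m < l and
M ≥ u; RT if m < l and M < u; MT (always-moderate) if m ≥ l and M < u.
Boundaries are inclusive at l and u. The three-way AT/DT/RT scheme
leaves the MT cell of the (m, M) plane unnamed; it is reported as its
own label rather than silently merged, since forcing it into AT or RT
would bias both class inventories.

## Diversity and permutation statistics

Shannon entropy uses the natural log (the ecology default, and the
magnitude that matches reported sponge values of roughly 2–4 nats);
inverse Simpson doubles as the effective species number n_eff used by
the association-method heuristic (LSA is appropriate when n_eff ≥ 13,
the table is < 50% sparse, and samples form a time series — otherwise
the failing criterion is reported). Bray–Curtis, ANOSIM, PERMANOVA and
Mantel go through scikit-bio with explicit seeds; permutations default
to 999 and p-values respect the 1/(n_perm+1) floor. MRPP is
implemented directly (no Python implementation exists in the stack):
delta is the group-size-weighted mean within-group distance, A = 1 −
delta/E[delta] with E[delta] the permutation mean, one-sided p with
add-one correction; it reproduces R `vegan::mrpp` to numerical
precision on a fixed fixture. Dendrograms use average linkage (UPGMA);
the linkage is not dictated by the analysis, and UPGMA is the
conventional choice for Bray–Curtis community trees. Mantel defaults
to Spearman. VIF screening regresses each environmental variable on
the rest (with intercept), drops constant variables first (infinite
VIF), then iteratively removes the largest VIF until all are ≤ 20.

## Levins niche breadth

B_i = 1/Σ_j P_ij² with resource states j = the samples of the analysis
group (replicates kept separate) and P_ij the ASV's mean relative
abundance in state j renormalized across states. Each sample is one
state because that is the usage under which community means of order
5–30 arise for 15-sample groups; only detected ASVs (occupancy ≥ 1
state) enter the community mean, switchable via `min_occupancy`.

## Co-occurrence networks

Spearman correlations (average ranks for ties) of non-log-transformed,
prevalence-filtered counts; ≥ 4 samples required; zero-variance ASVs
removed and flagged. The cutoff scan runs s = 0.30…0.99 in steps of
0.01. At each s the matrix with |r| < s zeroed is diagonalized
(restricted to rows with surviving off-diagonal entries — excluded
rows contribute only duplicate unit eigenvalues), exact-duplicate
eigenvalues are collapsed, the spectrum is unfolded by a cubic fit to
the empirical cumulative spectral function, and the nearest-neighbor
spacing distribution is χ²-tested against the Poisson law e^(−d) on a
20-bin histogram over [0, 3] with tail bins merged to expected counts
≥ 5. The selected threshold is the smallest s whose fit is
Poisson-consistent (p > 0.05) and remains so for two further steps; if
none qualifies the error carries the full per-threshold diagnostics,
and the pipeline then falls back to the scanned cutoff with the best
Poisson fit (recorded as such in the report).

Two properties of this selector matter for interpretation. First, on
p ≫ n data the spacing transition tracks the *percolation* of the
thresholded matrix: once the surviving graph fragments into small
components its spectrum genuinely is a near-Poisson superposition, so
the cutoff lands near the fragmentation point, not at the extinction
of noise correlations (at n = 50 samples the null Spearman sd is
≈ 0.14, so cutoffs ≈ 0.33 still pass noise pairs). Networks at the RMT
cutoff therefore have perfect recall of strong planted associations
but carry sub-percolation noise edges. Second, strongly structured
matrices (a correlated block) keep GOE-like repulsion alive and are
assigned much higher cutoffs than noise-dominated ones. Densities of
networks built at different cutoffs are not comparable; the pipeline
therefore reports per-group topologies at their own RMT thresholds
*and* a cross-group comparison block recomputed at a harmonized cutoff
(the maximum of the sponge groups' thresholds), which is the contrast
used for HMA-vs-LMA avgK statements.

Topology: avgK = 2L/N; connectedness = fraction of node pairs joined
by a path; modularity from the deterministic greedy (CNM) partition;
betweenness normalized by (N−1)(N−2)/2. Thresholding uses |r|; signs
are kept for positive/negative edge fractions. Null ensembles are 100
Maslov–Sneppen double-edge-swap randomizations (igraph's C
implementation; 100×L swap proposals each, proposals creating
self-loops or multi-edges rejected, so node set, edge count and degree
sequence are preserved exactly), with Z = (observed − null mean)/null
sd and degree-determined metrics (e.g. avgK) flagged as degenerate.
Keystones are the top 10 nodes by the mean of the degree rank and the
betweenness rank, ties broken lexicographically.

## Local similarity analysis

Series are rank normal-score transformed (rank/(n+1) through the
normal quantile) and z-scaled; constant series are flagged and
dropped. For each offset |d| ≤ D (default D = 1; longer lags are
meaningless for five time points) the dynamic program tracks positive
and negative chains of products, P_i = max(0, P_{i−1} + x_i·y_{i+d})
and the mirrored N_i; LS is the largest chain over i and d divided by
n, signed by which chain attained it, with positive chains winning
exact ties and smaller |d| preferred. The DP provably equals
exhaustive window enumeration (property-tested on all series lengths
≤ 8). Two-sided permutation p-values reorder one side's time axis
(add-one correction); q-values are Benjamini–Hochberg across all
pairs, significance at q ≤ 0.05.

Replicate handling defaults to *concatenation* (columns ordered by
month then replicate, a 15-point series) rather than averaging to five
points: five points admit only 120 reorderings, putting the
permutation floor near 0.01, which no pair survives after FDR control
across hundreds of pairs — the averaged layout remains available via
`lsa.replicates = "average"`. Even concatenated, bipartite
significance on the synthetic coastal data is marginal and
seed-dependent (BH is all-or-nothing near the boundary); empty
significant sets are a legitimate outcome and summarized as such.

## Synthetic data generator

One community = a Dirichlet base composition (concentration =
"evenness" × uniform over its richness), perturbed per time point by
(i) iid lognormal jitter of sd σ_t shared across replicates
("temporal turnover") and (ii) a driver response β·z_t added to the
log-abundance of the top-decile ASVs, where z is the standardized
temperature; counts are multinomial draws per replicate at the
configured depth (default 20,000 reads, matching >10⁴-read amplicon
libraries). A fraction φ of each community's ASV ids is drawn from a
common seawater pool so Venn/shared-ASV logic is exercised. The
environmental table gives temperature a month-based seasonal arc
(~14 °C in January to ~29 °C peaking at the mid-series June point,
October staying warm — the asymmetry is realistic and avoids making
series reversal a null symmetry), DO anti-correlated with temperature,
and lognormal nutrient levels.

Presets (per 5 months × 3 replicates): HMA — richness 800, evenness
2.0, σ_t 0.25, β 0.8, φ 0.10; LMA — richness 150, evenness 0.15, σ_t
1.2, β 1.5, φ 0.45; seawater — richness 3000, evenness 1.0, σ_t 0.8,
β 2.0, φ 1 (it *is* the pool). Environmental susceptibility rises
from HMA through LMA to seawater while turnover is lowest in HMA, so
HMA dynamics are tightly mutually correlated (dense network, high
niche breadth, low seawater overlap) and LMA dynamics driver-coupled
but noisy — the qualitative HMA/LMA/seawater contrasts the analysis
measures. The planted-network generator draws a Gaussian copula with
correlation ρ on planted edges (disjoint-pair mode guarantees positive
definiteness; arbitrary edge sets are thinned with a warning),
lognormal marginals (log-sd 0.8 spread of mean abundances) and
multinomial counting.

What the generator does *not* emulate: phylogenetic structure and real
taxonomies, compositional zero-inflation beyond multinomial sampling,
spatial effects, inter-annual trends, and sequencing artifacts
(chimeras, contamination). Passing tests show the statistics behave
correctly under the assumed generative structure, not that real sponge
data satisfy those assumptions.

## Pipeline and reproducibility

`run_full_analysis` sequences load/simulate → abundance classes →
diversity and permutation tests → shared ASVs → niche breadth →
per-group networks (plus the harmonized comparison) → bipartite LSA,
with per-stage logging and errors naming the failing stage. Every
random step derives from the single config seed; reruns are
byte-identical. For desk-scale runtimes the network stage caps each
group at its 300 most abundant prevalent ASVs and LSA tests the top 40
per side (both configurable); the acceptance script's replication loop
uses lightened null-ensemble and permutation counts where only
orderings, not their uncertainties, are consumed.

## Known limitations

- The RMT cutoff on p ≫ n tables sits near graph percolation (see
  above); downstream edge lists contain noise edges and should be read
  as density contrasts, not literal interaction inventories.
- MRPP's expected delta comes from the permutation sample, so A
  carries Monte-Carlo error of order 1/√n_perm.
- LSA significance is permutation-based only; with few time points the
  discreteness of the permutation distribution bounds attainable
  p-values, and FDR control can zero out marginal signal.
- VIF screening assumes linear redundancy among environmental
  variables; with replicated env values per month the design matrix is
  rank-deficient and most variables are dropped as intended.
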