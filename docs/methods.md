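# Methods

This note documents the models, numerical conventions and design
choices behind `lakemicro`, in the spirit of a package methods
appendix. Nothing here reports an empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

A survey is three aligned objects: a `CommunityMatrix` (samples × OTUs
integer counts, each sample labelled with its lake group), an
environment table (numeric DataFrame per sample: Temp °C, pH, DO mg/L,
SAL g/L, TDS mg/L, EC ms/cm, Turb NTU, ORP mV, Chl-a µg/L, DOC/TN/TP/
NH4-N/NO3-N/NO2-N mg/L, longitude/latitude degrees, altitude m), and a
rooted phylogeny (`skbio.TreeNode`, branch lengths ≥ 0) whose tips
cover the OTUs. Input tables are TSV with OTUs as rows (the common
amplicon convention; a flag flips orientation). Community/metadata
alignment is an inner join that logs what it drops. Counts are kept raw
by default; rarefaction to the minimum library size is available behind
a flag because practice varies between labs, and all abundance-based
statistics internally use relative abundances where the method requires
them.

## Synthetic surveys

`simulate_metacommunity` emulates the structure of a plateau-lake
amplicon survey: `n_groups` lakes on a 1-D transect with unit spacing
(default 8 lakes × 4 samples), a pure-birth phylogeny of `n_taxa` tips
(default 1000), a long-tailed metacommunity with ranked log-series
relative abundances p_i ∝ x^i / i (x = 0.5^(1/n_taxa), giving the
~1/rank tail amplicon tables show), and an environment table whose
gradients span the ranges reported for eastern-plateau lakes
(pH 8.87–10.10, Temp 1.78–18.17 °C) plus transect coordinates.

The local community of each sample is drawn from the stationary
(diffusion) law of a Hubbell/Sloan island community: relative
abundances x ~ Dirichlet(N_T · m · π), where π is the (possibly
selection- or dispersal-filtered) metacommunity and m the immigration
rate, then discretized to a census of exactly N_T individuals by
flooring x·N_T and handing the leftover individuals to already-detected
taxa. The census **is** the community — no extra multinomial read
sampling is layered on top. This matters: the Dirichlet law already
carries the full demographic noise, and a second sampling layer would
(a) double-count noise and (b) blur the one-individual detection limit
d = 1/N_T that the Sloan model assumes, biasing any downstream estimate
of m upward by ~25% (verifiable in closed form from the Beta-binomial
occupancy 1 − B(a, b+N)/B(a, b)). With the census-as-state generator
the immigration rate is recoverable essentially exactly.

Regimes modify π per sample:

* `neutral` — π = p everywhere.
* `homogeneous_selection` — Gaussian fitness
  w = exp(−s·(trait − opt)²) with the same optimum in every lake,
  placed at the 0.8 trait quantile. The niche trait evolves by Brownian
  motion whose edge variance is depth-weighted (edge spanning relative
  depths [d0, d1] contributes d1^δ − d0^δ; Pagel's delta transform).
  With δ < 1 most trait variance sits on deep splits, so the taxa near
  the optimum form genuine clades — selecting around a *central*
  optimum of a plain Brownian trait picks taxa from many clades and
  produces no phylogenetic signal, which is why both the off-center
  optimum and the depth weighting are part of the regime definition.
* `heterogeneous_selection` — per-lake optima at trait quantiles
  0.05…0.95.
* `dispersal_limitation` — each taxon has a home lake; its membership
  in lake g decays as exp(−r·distance(home, g)). The default decay
  r = 2 leaves adjacent lakes sharing ~14% of pool membership, a strong
  but not absurd limitation.
* `mixed` — heterogeneous selection and dispersal decay combined.

Every component consumes its own child random stream, so a selection
regime with gradient strength 0 reproduces the neutral draw bit-for-bit
at the same seed. The regime-expression settings used by the test suite
and the acceptance script are frozen in
`lakemicro.simulate.REGIME_STUDY_OVERRIDES` (selection: m = 0.02,
s = 15, δ = 0.05 — strong filtering with enough local drift that many
non-shared taxa inform the phylogenetic turnover; dispersal: r = 2).

What the generator does **not** emulate: sequencing error and chimeras,
compositional depth variation (libraries are exactly N_T), taxonomy,
seasonal dynamics, and 2-D lake geometry (the transect is 1-D). Tests
passing on these surveys therefore show the estimators are correct and
calibrated under the stated model, not that real lake data satisfy that
model.

## Diversity and ordination

Alpha indices come from scikit-bio: Shannon in natural log (base
flaggable), Gini–Simpson, Chao1 in the classic form S_obs + F₁²/(2F₂)
with the bias-corrected form when F₂ = 0, Faith's PD including the root
path, and Pielou J′ = H′/ln S (undefined, reported NaN, for single-taxon
samples). Bray–Curtis uses scikit-bio's implementation. PCoA is
classical scaling of the Gower-centered matrix, implemented directly so
the negative-eigenvalue convention is explicit: negative eigenvalues
are reported but excluded from the proportion-explained denominator (no
Lima/Cailliez correction); the scikit-bio PCoA serves as a cross-check
in the tests. ANOSIM is implemented with seeded permutations
(R = (r̄_between − r̄_within)/(M/2) on dissimilarity ranks); its R
statistic is cross-checked against scikit-bio. Group tests are
Kruskal–Wallis (tie-corrected χ² approximation) and two-sided
Mann–Whitney U with the continuity-corrected normal approximation.
Spearman screens star raw p-values by default (0.05/0.01/0.001);
Benjamini–Hochberg-adjusted starring is a flag, since published
correlation heatmaps are often un-adjusted.

## Drivers

VIF screening iteratively removes the highest-VIF variable (ties broken
alphabetically) until all VIF < 10. RDA Hellinger-transforms the counts
(flaggable), z-standardizes the constraints and takes the PCA of the
fitted values of the multivariate regression; per-factor significance
is envfit-style — the marginal R² of each variable against simple row
permutations of that variable. PCNM builds the great-circle (haversine)
distance matrix (planar flag for simulated transects), truncates at the
largest minimum-spanning-tree edge, replaces beyond-threshold distances
with 4× the threshold, and returns the unit-norm positive-eigenvalue
eigenvectors of the Gower-centered truncated matrix, with a
deterministic sign convention. All positive axes enter VPA (no forward
selection). VPA partitions adjusted R² (Ezekiel) by
inclusion–exclusion; degrees of freedom use the *rank* of the
standardized design, not its column count, so fully redundant sets
partition into pure ≈ 0 / shared = single-set adjR² with a logged
warning instead of erroring. The pipeline passes only the
envfit-significant water factors (p ≤ 0.05; top-3 R² fallback) into the
partition to keep the model identifiable at survey-scale n.

## Assembly processes

`fit_neutral` fits m by bounded scalar least squares of observed
occurrence frequencies against the Sloan prediction
Beta.sf(1/N_T, N_T·m·p, N_T·m·(1−p)) with N_T the mean library size;
R² = 1 − SSE/SST; the 95% band is a Wilson score interval around the
prediction at n = number of samples, and OTUs are partitioned
above/within/below it. The fit refuses to run with fewer than five
OTUs of intermediate (0 < f < 1) frequency.

βMNTD is abundance-weighted by default (unweighted flag), computed from
the full tip-tip patristic matrix; the implementation pre-computes, per
sample, the minimum distance from every tip to that sample, making the
null loop linear in tips × samples rather than quadratic in sample
richness. βNTI standardizes against `n_null` = 999 (flag) permutations
of tip labels across the whole tree; pairs with zero null variance
(e.g. star phylogenies) are NaN with a warning and excluded, counted,
from process fractions. RC_bray draws, per sample pair, null
assemblages preserving each sample's richness and library size — taxa
selected without replacement by metacommunity occurrence frequency
(Efraimidis–Spirakis keys), individuals filled multinomially by
metacommunity relative abundance — and scores
2·[(#{BC_null < BC_obs} + ½ ties)/n_null] − 1 with half-weighted ties
at 1e-12 tolerance. An explicit `reference` community can supply the
metacommunity, which is also how the self-calibration check draws pairs
from the null itself.

Classification applies the printed thresholds strictly and in order:
βNTI < −2 homogeneous selection; βNTI > 2 heterogeneous selection;
otherwise RC > 0.95 dispersal limitation, RC < −0.95 homogeneous
dispersal, else undominated. Equality at any boundary falls through to
the next rule. Fractions are percentages of non-NA pairs, pooled across
all pairs by default (a within-group flag restricts them). The
βNTI-vs-environment correlation uses Δvar = |var_k − var_l| per pair,
Spearman over the upper triangle, and a Mantel-style joint permutation
of sample labels for p.

## Networks

Edges require Spearman |ρ| > 0.8 (strict) and BH-adjusted p < 0.01 over
all tested pairs; OTUs are prefiltered to those present in ≥ 1/3 of
samples (tunable — published networks of ~300 nodes from thousands of
OTUs imply heavy prefiltering), and at least 8 samples are required for
the p-values to mean anything. Graphs are `networkx` objects; path and
community metrics are computed through python-igraph's C backend, which
is what makes 1000-replicate ensembles affordable. Average path length
is over the connected pairs (i.e. the largest component for a
disconnected graph); geodesic efficiency averages 1/d over all pairs
with disconnected pairs contributing 0; harmonic geodesic distance is
the harmonic mean of the finite geodesics. Modularity uses greedy (CNM)
maximization — deterministic — with Louvain behind a flag. The
Erdős–Rényi ensemble draws G(n, M) graphs with exactly the empirical
node and edge counts, so every replicate's average degree is 2M/N
identically; note that at equal nodes and edges a random-network
average degree *different* from the empirical one is arithmetically
impossible, so a published random-ensemble degree below the empirical
value at stated-equal sizes should be read as a reporting inconsistency
(the ensemble here reports the analytic value). Per-sample subnetworks
are the induced subgraphs on each sample's nonzero OTUs (per-lake mode
available), joined to the environment table for property–environment
screens.

## Problem sizes and determinism

All stochastic stages take explicit seeds; identical configuration and
seed give byte-identical pipeline outputs. The acceptance script
re-derives every reported number at these sizes, chosen as the smallest
at which the properties are stable: regime recovery over 10 seeds of
4 lakes × 3 samples × 1000 taxa with 199 nulls; neutral recovery over
10 seeds of 30 samples × 1000 taxa at N_T = 10⁴ (10-seed medians);
βNTI false-positive rate pooled over four independent 18-sample neutral
surveys (612 pairs, 999 nulls) — pairs within one survey share the
community draw, so pooling across surveys is what stabilizes the rate;
RC_bray self-calibration over 200 null-drawn pairs; ANOSIM type-I error
over 1000 simulations of 20 iid samples at 199 permutations; VPA sum
identity over 100 random designs; graph identities and the ensemble
degree at the published sizes (291/1728, 304/1726).

## Known limitations

* The process classifier inherits the thresholds' all-or-nothing
  character; near-boundary pairs are sensitive to the null sample size.
* βNTI magnitudes scale with the effective number of independent taxa
  per sample; at a few hundred taxa the attainable |βNTI| under strong
  filtering is ~2–4, far below values seen in 10⁴-taxon surveys.
* The RC null conditions on observed richness and abundance; it is not
  a fully independent generative model of the data.
* PCNM axes enter VPA unselected, which can overfit spatial structure
  at small n; the pipeline's envfit-significance filter applies only to
  the water set.
* The Sloan fit assumes a single metacommunity and equal N_T across
  samples; strong depth variation would need rarefaction first.
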