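# Methods

This note documents the models and numerical choices behind `rhizoq`, what
the synthetic-data generator does and does not emulate, and the design
decisions made where the underlying methodology left room.

## Soil quality index

**Membership functions.** An indicator value Y with observed extremes
(Mᵢ, Mₐ) is scored as (Y − Mᵢ)/(Mₐ − Mᵢ) when more of the indicator is
desirable and (Mₐ − Y)/(Mₐ − Mᵢ) when less is desirable. pH and EC default
to descending ("less is better": the studied amendment raises both into a
range that stresses plants), the remaining indicators — organic matter,
ammonium and nitrate nitrogen, phosphatase, cellulase and sucrase activity
— to ascending. Directions are overridable per indicator, since desirable
pH is soil- and crop-dependent. Two variants are offered: the plain unit
range (default) and an affine rescale 0.9·s + 0.1 onto [0.1, 1.0], a
convention some fuzzy-evaluation studies use so that no indicator is ever
weighted by exactly zero. Degenerate bounds (Mₐ = Mᵢ) raise rather than
silently producing 0/0; values outside the bounds are clipped with a
warning.

**Bounds scope.** Extremes default to replicate-level values within one
species (`bounds_scope="replicates"`), with treatment means as the
alternative. Replicate-level extremes mean a treatment *mean* rarely sits
exactly at 0 or 1, matching how published membership tables usually look.

**Weights.** Indicators are z-standardized; a PCA of the resulting
correlation structure retains components by the Kaiser rule
(eigenvalue > 1; at least one), varimax-rotates the retained loadings, and
assigns each indicator its communality share
wᵢ = h²ᵢ / Σⱼ h²ⱼ, h²ᵢ = Σₖ loadingᵢₖ². Communalities are invariant under
orthogonal rotation, so the rotation affects only the reported loadings,
not the weights — the test suite exploits this by comparing against an
independently coded eigendecomposition with a Jacobi-rotation varimax.
Adequacy is reported via KMO (anti-image partial correlations from the
inverse correlation matrix) and Bartlett's sphericity statistic
−(n−1−(2p+5)/6)·ln|R| on p(p−1)/2 degrees of freedom.

**Aggregation and grading.** SQI(t) = Σᵢ Qᵢ(t)·Sᵢ, a convex combination,
graded I ≥ 0.85, II [0.7, 0.85), III [0.55, 0.7), IV [0.4, 0.55),
V < 0.4. Tests on the packaged published table use a tolerance of 5·10⁻⁴,
the propagation of its three-decimal rounding through an eight-term
weighted sum.

**Packaged fixture.** The published membership/weight table covers five
biochar doses under two plant species. Recomputing its weighted sums places
the ryegrass control at SQI ≈ 0.499 (level IV) even though the source
narrative groups both controls under "level V"; the level-V claim is
therefore asserted only for the cosmos control (≈ 0.246), which does
satisfy it. The fixture's conductivity column is labelled "CEC" in the
source but is treated as EC, consistent with the surrounding text.

## Alpha diversity

Shannon is −Σ p ln p in nats (a log-base flag converts); Simpson is
reported as the concentration D = Σ p², under which *larger* values mean
*lower* diversity — the convention matching diversity tables that report
Simpson values near 0.005 for ~3000-taxon communities. Chao1 defaults to
the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)), which is defined even
without doubletons; the classic S + F₁²/(2F₂) is available and raises
explicitly when F₂ = 0. ACE uses the standard abundance-based coverage
estimator with rare/abundant cutoff 10 (configurable) and falls back to
bias-corrected Chao1 in the degenerate all-singletons case. Good's
coverage is 1 − F₁/N. Rarefaction offers an exact mode — the
hypergeometric expectation E[S_d] = Σᵢ (1 − C(N−nᵢ, d)/C(N, d)) — and a
seeded subsampling mode; the exact mode is the default because it is
deterministic and cheap.

## Co-occurrence networks

Taxa are first filtered by mean relative abundance (strictly greater than
the threshold, default 1 %). Correlations are computed on relative
abundances by default; Spearman is the default method (rank correlation is
robust to the monotone distortions compositional data impose), implemented
as Pearson on column ranks with two-sided p-values from the t
approximation — identical to scipy's Spearman p-values but robust to
constant taxa, which are recorded as missing with a warning rather than
aborting. Edges require |r| > r_min AND p < p_max with *strict*
inequalities (defaults 0.6 and 0.01); no multiple-testing correction is
applied by default, with Benjamini–Hochberg available by flag. Isolated
nodes are dropped unless kept explicitly.

Topology: average degree 2E/N; mean local clustering with degree-<2 nodes
contributing 0; Freeman centralizations — degree Σ(d_max − dᵢ)/((n−1)(n−2))
on raw degrees and betweenness Σ(b_max − bᵢ)/(n−1) on normalized
betweenness — both reported as missing for n < 3; and the percentage of
negative-correlation edges. All metrics are verified against a brute-force
oracle (explicit triangle counting, all-pairs shortest-path counting) on
random graphs up to n = 30.

## Community–environment association

Bray–Curtis dissimilarity d(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ) for communities;
z-scored Euclidean distance for environmental profiles (the source
methodology names no environmental metric; standardized Euclidean is the
common default and is documented as such). The Mantel statistic is the
correlation of the unraveled lower triangles, Pearson by default (the
common default in community-ecology software) with Spearman available via
a rank transform of the off-diagonal entries — valid because joint
row/column permutation only re-pairs the same multiset of values. The test
is one-sided for positive association with
p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), so 999 permutations give a floor
of p = 0.001. Ordinations use classical PCoA (double-centered −½D²,
eigendecomposition, axes by decreasing eigenvalue, negative eigenvalues
dropped with a warning): a deterministic embedding was preferred over
stress-minimizing NMDS, which adds run-to-run variability without changing
the association question. Procrustes superposition is symmetric — both
configurations centered and scaled to unit Frobenius norm — giving
m² = 1 − (Σσ)² and r = √(1−m²) with the PROTEST permutation of row order,
same p-value convention. Both permutation tests hold their nominal 5% size
on null data (verified at 200 replicates in the suite and at 2000
replicates during development) and are bit-reproducible under a fixed seed.

## Synthetic pot experiment

The generator emulates a 2-species × 5-dose (0/1/3/6/9 % w/w) × 3-replicate
design, 30 samples by default.

**Indicators.** Each indicator follows one of four dose-response shapes in
u = log1p(dose): monotone up/down (baseline ± effect·u) or a hump —
a parabola in u anchored at the baseline for dose 0 with its interior
maximum (baseline + effect) at a configurable peak dose (default 3 %) —
plus Gaussian replicate noise. Default baselines follow a real unamended
planting soil (pH 8.22, SOM 20.98 g/kg, ammonium-N 20.28 mg/kg, nitrate-N
5.83 mg/kg); shapes and effect sizes are chosen to reproduce the
qualitative trends of amended pot soils (EC and SOM rising, mineral N and
cellulase/sucrase hump-shaped, phosphatase declining, pH nearly flat).
Published effect sizes exist only as bar charts, so the magnitudes are
package defaults, not calibrated values.

**Counts.** Per sample, taxon log-concentrations are
log(base) + slope·dose + ε; the softmax of these, scaled by a total
concentration θ (default 300), parameterizes a Dirichlet draw, and counts
are multinomial at fixed depth (row sums are exact). The
Dirichlet layer provides the overdispersion real amplicon tables show — a
plain multinomial would make downstream correlation tests
anti-conservative. Default dose slopes follow the qualitative phylum
trends of biochar-amended soils (a rising Pseudomonadota-like stratum,
declining Bacillota- and Chloroflexota-like strata) at magnitudes that put
the community–environment Mantel correlation in the 0.15–0.45 range
observed in such studies. Planted pairs couple two taxa's ε via a
bivariate normal at a target correlation (latent sd 1.5); background taxa
get independent ε (sd 0.5). The background sd matters: it represents
realistic per-taxon sample-to-sample variability and keeps
compositional-closure correlations (everything co-varying against a
surging dominant taxon) below the network thresholds.

**What passing tests do and do not show.** Because planted associations
act on latent log-concentrations, realized compositional correlations are
attenuated; recovery checks therefore use thresholds over many seeds, not
equalities. The generator has no sequence-level error, chimeras, spatial
pot effects, or taxon-taxon interactions beyond pairwise latent coupling —
so passing recovery tests demonstrates the inference chain is correct
under its own assumptions, not that those thresholds are optimal for real
amplicon data.

## Problem sizes and determinism

Default analyses run in seconds on one core: the suite's calibration
checks use 200 null replicates of 15-sample tests at 999 permutations, and
structure-recovery checks use 20 seeds of 100-sample × 30-taxon tables —
sizes chosen to give stable pass/fail behaviour at interactive runtimes.
The pipeline derives per-stage seeds from the global seed by fixed
offsets, so enabling or disabling one stage never reshuffles another's
randomness, and identical config + seed yields byte-identical reports.

## Known limitations

* Compositionality is handled by rank correlation and filtering, not by a
  compositional model (no SparCC/FastSpar-style correction).
* The SQI weighting is a PCA communality share over *all* indicators (the
  "total data set" approach); no minimum-data-set indicator selection.
* Bray–Curtis is a semimetric; PCoA on it can produce negative
  eigenvalues, which are dropped (with warning) rather than corrected
  (no Lingoes/Cailliez adjustment).
* Rows with missing indicator values are rejected, not imputed.
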