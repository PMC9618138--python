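# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecotraitmap`, and what the synthetic validation does and does not
demonstrate.

## Trait inference

**Similarity.** The co-occurrence similarity of two species is the Spearman
rank correlation of their biomass vectors across all samples, computed with
average ranks for ties. Absences (zeros) participate as tied ranks; this is
deliberate, since joint absence from the same habitats is itself
informative of niche similarity. Raw biomasses are used (any monotone
per-species transform leaves ranks unchanged). Species observed in fewer
than `min_occurrence = 5` samples are removed first: a rank correlation
estimated from fewer than ~5 paired presences is dominated by the tie
structure. A species with a constant biomass vector has undefined
correlation and is treated as an error rather than silently dropped.

**Trusted links.** For each species the k = 10 largest similarities are
nominated (signed values rank; ties at the k-th rank are all admitted, so
the result is order-independent). A pair is linked if either member
nominates the other (union-kNN). Nominated negative similarities are
clipped to zero weight — a negative correlation cannot serve as a
diffusion conductance — so a node whose entire neighbourhood is negative
becomes isolated and is reported. Only the largest connected component is
embedded; diffusion distance is undefined across components, and excluded
species are dropped from downstream diversity with their samples'
compositions renormalised and the lost biomass reported as reduced
coverage.

**Embedding.** The unnormalised Laplacian L = Diag(rowsum S) − S is
eigendecomposed densely (`scipy.linalg.eigh`; component sizes here are
O(10²–10³)). The zero-eigenvalue constant eigenvector is discarded; axis n
is vₙ/λₙ for the n-th smallest nonzero eigenvalue, and distance is
Euclidean in those coordinates, equivalently d² = Σₙ (vₙᵢ−vₙⱼ)²/λₙ².
Sign convention: each eigenvector is oriented so its largest-magnitude
entry is positive, making output deterministic across eigensolvers (for
symmetric graphs with tied magnitudes the orientation follows the solver's
tie, but distances are unaffected). A random-walk normalised variant
(generalised problem L v = λ Diag v) is available behind a flag; in our
validation it performs indistinguishably from the default.

**Number of axes.** m = 20 by default. Because contributions decay as
1/λₙ², reconstruction quality is insensitive to m: in validation scans
m ∈ {5, …, 50} changes regional R² by under 0.02, and only m ≲ 3 or
unweighted coordinates degrade it materially.

## Rao diversity

Q = Σᵢⱼ pᵢ pⱼ dᵢⱼ, the full double sum (each unordered pair counted
twice), without the ×1/2 factor and without the "equivalent numbers"
normalisation; `half=True` exposes the halved convention. Q is invariant
to species permutation and to rescaling a sample's absolute biomasses, is
zero for a monoculture and bounded by max dᵢⱼ. Station trends are ordinary
least squares of Q on decimal year, the minimal reproducible choice for
"diversity change over time"; the two-sided p-value comes from the usual
t statistic and should be read descriptively (samples within a station are
not independent in real monitoring data).

## Metacommunity simulator

The generator emulates a monitoring campaign over a spatially
heterogeneous region with a fully known answer.

* **Traits.** n = 200 species; R\* triplets drawn uniformly (flat
  Dirichlet) on the shifted simplex Σₖ R\*ₖ = C_tot = 30, R\*ₖ ≥ R_min = 1
  (concentration units are arbitrary but consistent). The triangle
  encodes a strict competence trade-off, guaranteeing niche
  differentiation.
* **Landscape.** 10 × 12 lattice of 120 patches; supplies Sₖ i.i.d.
  uniform on [10, 40] per patch and resource, spanning eutrophic to
  oligotrophic conditions around the triangle's centroid.
* **Dynamics.** Per patch, chemostat resource renewal at rate D = 0.25 d⁻¹
  toward the supply point; Monod–Liebig growth
  μᵢ(R) = μ_max minₖ Rₖ/(Rₖ+Kᵢₖ) with μ_max = 1 d⁻¹; mortality
  m = 0.25 d⁻¹; content coefficients cₖ = 1; diffusive nearest-neighbour
  dispersal a = 0.05 d⁻¹ with no-flux boundaries. Half-saturation
  constants are tied to the traits, Kᵢₖ = R\*ᵢₖ(μ_max−m)/m, so growth
  balances mortality exactly at Rₖ = R\*ᵢₖ — the R\*-rule fixed point,
  verified in the tests against the closed-form chemostat equilibrium.
* **Sampling.** All species seeded at B₀ = 10⁻³; integration to
  T = 150 d; biomasses below ε = 10⁻⁶ censored to exactly zero. One
  end-time snapshot per patch is one sample; the patch's three supply
  values serve as synthetic environmental covariates.

**Choice of horizon.** The community state at T = 150 d is quasi-steady
for the dominant dynamics — local growth (timescale 1/(μ_max−m) ≈ 1.3 d)
and resource turnover (1/D = 4 d) equilibrate within a few tens of days —
while competitive exclusion, which proceeds on a ~10³ d timescale in this
system, has not yet removed species: every species persists somewhere in
every run at this horizon. Running instead to full competitive equilibrium
(T ≳ 10³ d) collapses regional richness to well under half the pool,
which neither matches the persistent-coexistence regime the simulator is
meant to emulate nor leaves enough co-occurrence signal to map. The
`SimOutput` reports the achieved end-time residual median |dB/dt|/B
instead of enforcing a convergence tolerance.

**Integration.** Adaptive RK45 (`scipy.integrate.solve_ivp`,
rtol = 10⁻⁴, atol = 10⁻¹⁰) over three windows, with (rare, tiny) negative
states clipped to zero between windows and counted. Tightening rtol to
10⁻⁵ changes the validation R² by < 10⁻⁴, so solver error is irrelevant at
these tolerances; the state is also clipped inside the right-hand side so
transient negatives cannot produce NaNs in the Monod terms.

## Validation experiment

Training: 200 metacommunities (desk scale; 800 at full scale), pooled into
one 200 × 24 000 table, then the full inference pipeline with all
defaults. Testing: 30 (full scale: 100) held-out metacommunities; for each,
regional composition = biomass summed across patches (local = single
patches), and Rao Q computed under (a) the inferred diffusion distances
(over embedded species, renormalised) and (b) the ground-truth Euclidean
R\* distances (over all species). Agreement is the R² of a cubic
polynomial of inferred on true Q — the cubic absorbs the smooth monotone
scale distortion a diffusion embedding introduces — plus the Spearman
concordance of the two distance matrices over all pairs.

What this shows: with ample heterogeneous samples the trusted-link
diffusion map recovers species neighbourhood structure almost perfectly in
rank terms (concordance rS ≈ 0.92–0.94 in our runs) and tracks regional
functional diversity well (regional R² typically 0.78–0.92 across seeds at
desk scale, with seed-to-seed variability dominated by the trait draw and
the 30-point regression, not by solver or estimator noise; more training
data sharpens individual correlations but does not remove the residual,
which is systematic embedding distortion). The experiment is
deterministic: identical configuration and seed reproduce reports
bit-identically.

What it does not show: robustness to the features of real monitoring data
that the generator deliberately omits — observational noise, uneven and
seasonal sampling effort, taxonomic misassignment, detection limits that
vary by taxon, temporal autocorrelation, and trait spaces of unknown
intrinsic dimension. Passing validation here means the machinery is
correct under the model's assumptions, not that any field dataset will be
mapped this well.

## Trait interpretation

Per species, the biomass-weighted mean of a covariate over the samples
where it occurs (missing covariates excluded pairwise); per axis and
covariate, the Spearman correlation between coordinates and weighted
means. Day-of-year-like covariates are treated as linear; circular
statistics are out of scope. These correlations are associations between
an inferred coordinate and an occupancy-weighted environmental summary —
they suggest interpretations ("this axis separates high- from low-nitrate
species") but imply no causal link, and are labelled accordingly.

## Known limitations

* Diffusion distances exist only within the giant trusted component;
  datasets whose species split into disconnected guilds yield diversity
  estimates for the dominant guild only (coverage makes this visible).
* The union-kNN rule with k = 10 assumes the species pool is large enough
  that 10 neighbours are "short-range"; for pools ≪ 100 the network
  approaches completeness and the embedding degenerates gracefully toward
  classical spectral ordination.
* Rao values from different trait spaces are on different scales; compare
  them only through rank- or regression-based statistics, as done here.
* The simulator's regional diversity varies only moderately across
  metacommunities under i.i.d. patch supplies; agreement statistics that
  normalise by that spread (like R²) are correspondingly conservative.
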