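# ecotraitmap

Inferred trait spaces and functional diversity from ecological monitoring
data.

Functional diversity — the variety of ecological roles present in a
community — is usually computed from distances between species in a trait
space that a researcher must define and measure by hand. `ecotraitmap`
instead infers a trait space directly from the species × sample abundance
(or biomass) tables that long-term monitoring programs already produce, and
quantifies diversity in it. It is aimed at community ecologists and
microbiome researchers with co-occurrence tables of dozens to hundreds of
taxa across hundreds of heterogeneous samples.

## Method

1. **Similarity.** For every pair of species, the Spearman rank correlation
   ρ of their abundances across all samples — an indicator of
   co-occurrence, and hence of niche similarity. Absences count as tied
   zeros.
2. **Trusted links.** Only short-range comparisons are reliable, so a link
   (i, j) is kept iff j is among the k = 10 most similar species to i *or*
   vice versa (union-kNN). The trusted similarities form a sparse matrix
   **S**; everything else is set to zero. k is the method's only tunable
   parameter.
3. **Diffusion map.** Eigendecompose the graph Laplacian
   **L** = Diag(Σⱼ Sᵢⱼ) − **S** on the largest connected component. Each
   eigenvector vₙ with nonzero eigenvalue λₙ (ascending) is one inferred
   trait axis ("i-trait"); λₙ is inversely proportional to the axis'
   importance, so the scaled coordinate is vₙ/λₙ. Functional dissimilarity
   is the diffusion distance

   d²ᵢⱼ = Σₙ (vₙᵢ − vₙⱼ)² / λₙ² ,

   the Euclidean distance in the scaled coordinates (m = 20 axes by
   default; the 1/λₙ² weighting makes higher axes negligible).
4. **Diversity.** For a sample with relative abundances p, Rao's quadratic
   entropy Q = Σᵢⱼ pᵢ pⱼ dᵢⱼ. Per-station OLS trends of Q over time are
   provided for monitoring series.

Because inferred axes have no labels, the package can also correlate each
axis with per-species biomass-weighted environmental means (e.g. nutrient
concentrations at the samples where a species occurs) to attach tentative,
hypothesis-generating interpretations.

A built-in metacommunity simulator provides ground truth for validation:
200 species whose minimal resource requirements (R\*) for three essential
resources fill a trade-off triangle (Σₖ R\*ₖ = const) compete on a 10×12
patch lattice with random resource supplies, Monod–Liebig growth,
mortality, chemostat resource renewal and nearest-neighbour dispersal.
Rao diversity from the inferred distances can then be compared against Rao
diversity from the known R\* distances on held-out simulations.

## Worked example

Generate synthetic monitoring data, infer the trait space, and compute
per-sample diversity — via the CLI (the same functions are importable from
`ecotraitmap`):

```bash
$ ecotraitmap simulate --species 40 --grid 4x5 --runs 6 --seed 3 --horizon 100 --out sim
wrote 40×120 table to sim

$ ecotraitmap embed --input sim/abundance.csv --k 10 --axes 8 --out ts_
embedded 40 species on 8 axes (lambda_2 = 0.4584)

$ ecotraitmap diversity --table sim/abundance.csv --meta sim/covariates.csv \
      --traitspace ts_ --out diversity.csv
wrote 120 diversity records to diversity.csv

$ head -3 diversity.csv
sample_id,Q,n_effective_species,coverage,flagged
run000_patch000,0.2385013934988042,40,1.0,False
run000_patch001,0.3403743885874637,40,1.0,False
```

Each row is one sample: `Q` is its Rao diversity in diffusion-distance
units, `coverage` the biomass fraction belonging to embedded species
(estimates with low coverage are flagged rather than silently biased).
Correlating axes with the simulator's supply covariates recovers the
planted structure:

```bash
$ ecotraitmap interpret --table sim/abundance.csv --covariates sim/covariates.csv \
      --traitspace ts_ --axes 2 --out interp.csv
 axis covariate        rs   abs_rs            p  n_species
    1  supply_2 -0.966041 0.966041 6.162517e-24         40
    2  supply_3  0.836961 0.836961 1.711638e-11         40
    ...
```

The first inferred axis aligns almost perfectly with the supply of
resource 2 (|rS| = 0.97) — the axes are statistically meaningful niche
dimensions, not abstract coordinates. Signs are arbitrary (eigenvectors),
which is why |rS| is the headline statistic.

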