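# hostspec

Tools for asking two questions about a host–parasite association table, a
host phylogeny and a host trait table:

1. **How host-specific is a parasite, and on which axis?** For every pair of
   host species a blended distance

   *FPDist* = (*a*·*PDist*<sup>p</sup> + (1 − *a*)·*FDist*<sup>p</sup>)<sup>1/p</sup>

   mixes scaled phylogenetic distance (*PDist*, patristic) with ecological
   niche distance (*FDist*, cophenetic distance on dendrograms clustered
   from habitat or diet traits). A parasite's specificity index *STD\** is
   the mean pairwise *FPDist* among its hosts. A permutation null redraws
   the weight *a* ~ U(0,1), one of eight clustering dendrograms and an
   equal-size random host set each iteration; the observed-minus-expected
   differential is negative when the parasite's hosts are more similar than
   chance (clustered) and positive when overdispersed.

2. **Which host attributes drive infestation risk?** A Bayesian
   hierarchical logistic regression of species-level infestation on host
   body mass, diet diversity, cohabitation diversity, composite habitat-use
   indicators and citation counts, with phylogenetic and threat-status
   random intercepts (residual variance fixed at 1, as it is not
   identifiable for binary outcomes). Posterior modes, 95% highest-density
   intervals, Gelman–Rubin diagnostics, latent-scale variance partitioning
   (the logit link contributes π²/3), odds/probability effect
   transformations and per-species fitted probabilities come out of a
   single `fit()`.

The package is aimed at parasitologists and disease ecologists working with
compiled association databases (e.g. flea–mammal records); a synthetic-data
module generates host pools with the statistical structure the analyses
assume, so the full pipeline is testable without any external data.

## Worked example

```python
from hostspec import (AnalysisConfig, HostSpecificityModel,
                      PhyloLogisticModel, prepare_traits)
from hostspec.cli import build_distances
from hostspec.simulate import SimulationConfig, simulate_dataset

ds = simulate_dataset(SimulationConfig(n_species=300, seed=11))
prepared = prepare_traits(ds.traits)

# --- regression -----------------------------------------------------------
y = ds.associations.presence_vector("parasite_1", prepared.species)
model = PhyloLogisticModel.from_tables(prepared, ds.tree, y)
res = model.fit(n_chains=2, n_iter=20_000, burn_in=10_000, thin=10, seed=5)
print(res.summary().loc[["anthropogenic_use", "sigma2_phylo"],
                        ["mode", "hdi_low", "hdi_high", "psrf"]].round(3))
print(res.variance_partition()["summary"]["phylogeny"])
```

prints

```
                    mode  hdi_low  hdi_high   psrf
parameter
anthropogenic_use  1.179    0.070     2.183  1.004
sigma2_phylo       0.999    0.171     3.398  1.004
{'mode': 0.2145..., 'hdi_low': 0.0363..., 'hdi_high': 0.4195...}
```

The pool was simulated with a true anthropogenic-habitat effect of 1.5 on
the log-odds scale and unit phylogenetic variance: the 95% interval for
`anthropogenic_use` covers the truth with the right sign, the phylogenetic
variance mode sits at 1.0, and phylogeny accounts for a posterior-mode 21%
of latent-scale variance. Split-chain PSRF near 1 indicates the two chains
mixed.

```python
# --- host specificity -----------------------------------------------------
species, tree, _, pdist, ensembles = build_distances(ds.tree, ds.traits,
                                                      AnalysisConfig(seed=0))
spec = HostSpecificityModel(pdist, ensembles["habitat"], pool=species)
result = spec.fit(ds.associations.hosts_of("parasite_1"),
                  config=AnalysisConfig(seed=0, n_null_iterations=2000))
print(result.summarize(n_bins=10)[["alpha_low", "median", "q025", "q975",
                                   "significant"]].tail(2).round(3))
```

A parasite simulated without host preference shows differential intervals
straddling zero in every α bin (`significant` False); a clade-restricted
parasite turns significantly negative as α → 1.

The same pipeline runs from the shell: `hostspec simulate`, `prepare`,
`distances`, `specificity`, `regress` and `report`, each writing a
`manifest.json` with input digests and the seed for exact reproducibility.

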