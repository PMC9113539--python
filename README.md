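# elevassembly

Community-assembly analysis of soil bacterial OTU data across elevation
gradients — for microbial ecologists asking *why* communities differ
between sites: environmental selection, dispersal, or drift?

Steep elevation gradients compress large habitat shifts into small
horizontal distances, which makes them natural experiments for separating
these processes. Given a site-by-OTU count table, per-sample metadata
(elevation, pH, coordinates, ...) and a rooted phylogeny of the OTUs (for
taxon-specific markers such as *Streptomyces rpoB*, tips are species-level
99%-identity OTUs), the package computes:

* **Alpha/beta diversity** — observed richness, exact (hypergeometric)
  rarefaction, Bray–Curtis, unweighted UniFrac, and the Baselga partition
  of Sørensen dissimilarity into turnover (βsim) and nestedness (βsne),
  with βsor = βsim + βsne.
* **Gradient tests** — ANOSIM, Mantel and partial Mantel tests, and a
  Mantel correlogram for distance–decay, all seeded permutation tests.
* **Assembly-process partitioning** (the core). For each community pair:

  - βMNTD(j,k) = ½ [ Σᵢ f_ij · min_{i′∈k} d(i,i′) + Σ_{i′} f_{i′k} ·
    min_{i∈j} d(i,i′) ], the abundance-weighted mean nearest-taxon
    patristic distance;
  - **βNTI** = (βMNTD_obs − mean βMNTD_null) / sd βMNTD_null, with the
    null shuffling tip labels across the whole phylogeny;
  - **RC-Bray**: Raup–Crick on Bray–Curtis under a null preserving each
    sample's richness and library size (species drawn ∝ occupancy,
    individuals allocated ∝ regional abundance), rescaled to [−1, 1].

  Pairs classify as variable selection (βNTI > +2), homogeneous selection
  (βNTI < −2), dispersal limitation + drift (|βNTI| ≤ 2, RC > +0.95),
  homogenizing dispersal (|βNTI| ≤ 2, RC < −0.95) or drift (the rest),
  summarized per elevation zone (High > 1,000 m, Low < 500 m, Middle).
* **Indicator species & phylogenetic signal** — IndVal = √(A·B) with
  label-permutation p-values, preferred elevation (abundance-weighted mean
  detection elevation), bootstrap tests of phylogenetic clustering of
  indicator sets, clade-divergence permutation tests, root-to-tip
  contrasts, Cohen's d.
* **A synthetic-data generator** — Yule phylogenies, Brownian-motion
  elevation optima (phylogenetically conserved preference), Gaussian
  habitat filtering, within-zone dispersal mixing and multinomial
  sequencing noise, with sampling designs that mirror a 9-station
  mountain transect (400–1,200 m, 24 samples) and a 10-site low-relief
  watershed pair, including their published elevations and soil metadata.

## Worked example

```python
import elevassembly as ea

ds = ea.simulate_dataset(design="wm", regime="selection", seed=1)
norm = ea.normalize(ds.table, "css")
res = ea.assembly_analysis(
    ds.table, ds.tree, ds.metadata["elevation"],
    table_for_bnti=norm, n_null=999, seed=7,
)
print(res.classification["process"].value_counts(normalize=True))
```

prints (seed 1):

```
process
dispersal_limitation_drift    0.289855
variable_selection            0.257246
drift                         0.250000
homogenizing_dispersal        0.141304
homogeneous_selection         0.061594
Name: proportion, dtype: float64
```

Under the strong-selection regime, over a quarter of pairs — and 100% of
High-zone vs Low-zone pairs — show βNTI > 2: communities at opposite ends
of the gradient hold more phylogenetically divergent taxa than the
tip-shuffle null expects, exactly the signature of elevation-driven
ecological filtering. The same run's Sørensen partition is ~90% turnover,
and `examples/05_indicators_and_phylosignal.py` shows low-elevation
indicator OTUs clustering on the phylogeny (observed mean pairwise
distance 4.67 vs null interval [7.07, 8.40]) while preferred elevation
recovers the simulated habitat optima at Pearson r ≈ 0.97.

The `examples/` directory has one short script per capability; the
`elevassembly` command-line tool exposes the same stages
(`simulate`, `preprocess`, `beta`, `mantel`, `assembly`, `indicators`,
`phylosignal`, `run`).

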