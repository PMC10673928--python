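# topomaps

Spatially-aware statistics for voxel-grid proteomics of laser-capture
microdissected (LCM) tissue.

A tissue slice is segmented into a rectangular grid of square "voxels"
(e.g. 24 × 16 voxels of 833 µm, or a 9 × 9 grid at 40 µm), each voxel is
excised by LCM and quantified by LC-MS, and every protein becomes a spatial
map over the grid. `topomaps` turns a protein-group quantification table
(MaxQuant `proteinGroups.txt` or a DIA-NN protein matrix) plus a
sample → (row, col) mapping into those maps, and provides the downstream
spatial analysis:

* **Spatially variable proteins** — global Moran's *I* on a binary
  Queen's-case contiguity graph,

  *I* = (n/W) · Σᵢⱼ wᵢⱼ (xᵢ−x̄)(xⱼ−x̄) / Σᵢ (xᵢ−x̄)²,

  with pseudo-*p*-values from 999 random spatial permutations,
  *p* = (1 + #{I\* ≥ I}) / (1 + n_perm), and Benjamini–Hochberg FDR across
  proteins. Each protein is tested on the subgraph of its observed voxels.
* **Spatially-unaware clustering** — pairwise-complete Euclidean voxel
  distances, average-linkage (UPGMA) hierarchical clustering, and a
  top-down dynamic tree cut; 70 %-valid filtering, downshifted-normal
  imputation (width 0.3, downshift 1.8) and a 2-D embedding (UMAP backend
  or deterministic PCA) for visualisation.
* **Spatially-aware clustering** — affinity network fusion (ANF) of a
  proteomic view (Spearman correlation of the top-25 %-variance proteins,
  distance 1 − ρ) and a spatial view (grid-unit Euclidean distances), each
  kernelised with a locally-scaled Gaussian; spectral clustering with the
  cluster number chosen by the maximal Laplacian eigengap. The proteomic
  view can be restricted to an annotation list (e.g. core-matrisome
  proteins).
* **Cluster characterisation** — one-vs-rest Wilcoxon marker screens
  (BH 1 %), pairwise Welch-*t* volcanoes (BH 5 %, ±2-fold-change lines) and
  one-sided hypergeometric overrepresentation of GMT gene sets against the
  detected-protein background.
* **Feature gradients** — per-voxel distance to point features (blood
  vessels) and Spearman screening for distance-correlated proteins, plus
  summed/mean protein-set abundance maps.
* **Synthetic data** — a generator that plants contiguous regions, smooth
  autocorrelated fields, exponential vessel gradients, null proteins,
  left-censored (MNAR) missingness and empty voxels, with full ground
  truth, so every stage is testable end to end.

## Worked example

```python
from topomaps import synthetic, grid_io, spatial_stats, anf

# a 16x16 grid, 300 proteins: 100 region markers, 50 smooth fields,
# 20 vessel gradients, 130 nulls, 20% left-censored missingness
matrix, grid, features, truth = synthetic.generate(seed=11)

norm = grid_io.filter_min_voxels(grid_io.normalize(matrix))
results, untested = spatial_stats.batch_moran(norm, grid, n_perm=999, seed=11)
frame = spatial_stats.moran_results_to_frame(results)
print(f"tested {len(frame)} proteins, "
      f"{(frame.q <= 0.05).sum()} spatially autocorrelated at q<=0.05")

labels, record = anf.anf_cluster(norm, grid, seed=11)
print(f"ANF chose k={record['k']} clusters over {record['n_voxels']} voxels")
```

prints

```
tested 299 proteins, 174 spatially autocorrelated at q<=0.05
ANF chose k=3 clusters over 256 voxels
```

— the Moran screen flags essentially all planted fields, markers and
gradients (and almost no nulls), and the fused proteomic + spatial
clustering recovers the three planted regions (k = 3).

The command line mirrors the library:

```sh
topomaps simulate --out sim/ --seed 1        # write MaxQuant-style files
topomaps run --config run.yaml               # full pipeline from YAML config
```

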