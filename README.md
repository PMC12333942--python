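# lesionscape

Spatial analysis of immune organization around pancreatic lesions, for
researchers quantifying how lymphoid cells arrange themselves near
precursor (PanIN), tumor (PDAC), and chronically inflamed (CP) tissue.
The package covers two modalities end to end:

* **Segmented multiplexed-imaging cell tables** — phenotype gating from
  marker intensities, cell-type densities per region, nearest-neighbour
  interaction structure, and detection plus maturity grading of tertiary
  lymphoid structures (TLS).
* **Hex-lattice spot transcriptomics** — spot QC and TLS labelling,
  non-negative latent-pattern decomposition, a fractional-expression
  pattern-marker statistic, expression-bin-matched module scores, and
  preranked GSEA.

A first-class synthetic-data module plants known ground truth (phenotypes,
aggregates, latent patterns, signature elevations), so every stage is
testable without external downloads.

## The quantities at the core

**Densities and tests.** Cell-type density is count per mm² of analyzed
tissue; comparisons use the two-sided Wilcoxon rank-sum test (exact for
small untied samples) and Kruskal-Wallis across more than two groups,
without multiple-testing adjustment.

**Interaction structure.** For ordered phenotypes (A, B), the interaction
matrix entry is the mean distance from each A cell to its nearest B cell
(self-excluded on the diagonal); the top-2 contact matrix counts each
cell's two nearest neighbours by phenotype pair and is normalized by the
region's dominant phenotype count.

**TLS maturity.** An aggregate (DBSCAN over lymphoid cells) is *mature*
when it holds a sufficiently numerous germinal-centre B-cell population
(CD20+CD21+CD23+) whose centroid is interior to the aggregate hull;
dendritic-cell (DCSIGN+) and high-endothelial-venule (PDPN+) densities are
reported as supporting features. Aggregates associate to the nearest
lesion boundary within 250 μm, else they are excluded.

**Latent patterns and markers.** With counts `c`, the matrix
`D = log2(c + 1)` is factorized as `D ≈ A P` (`A` gene × K amplitudes,
`P` K × spot weights, both non-negative) by multiplicative updates on
`½‖D − AP‖²_F + α(‖A‖₁ + ‖P‖₁)`. Writing `r_k = Σ_j P_kj`, each gene's
fractional expression is

```
f_gk = A_gk r_k / Σ_k' A_gk' r_k'      (Σ_k f_gk = 1)
```

and a gene marks pattern k when `f_gk` exceeds the Tukey upper fence
(`Q3 + 1.5·IQR`) among genes of similar total reconstructed expression
(tertile strata of `T_g`). Because flags are independent per pattern, one
gene can mark several patterns. Module scores are the mean expression of
a signature minus the mean of expression-bin-matched control genes.

## Worked example

```bash
python examples/05_latent_patterns.py
```

prints, for a planted three-pattern spot experiment:

```
NMF: 3 patterns, objective 160861 -> 34692 over 245 iterations
TLS-coupled pattern: 0 (mean weight 0.77 in TLS spots vs 0.03 elsewhere)
TLS-pattern markers: 42 flagged, Jaccard vs planted anchors 0.95
chemokine module score vs TLS pattern weights: r = 0.545, R² = 0.297, p = 1.22e-24
```

The decomposition finds the planted TLS-coupled pattern (its spot weights
concentrate in TLS spots), the marker statistic recovers the genes planted
as that pattern's anchors, and the 12-chemokine module score — the
transcriptomic fingerprint of lymphoid organization — correlates with the
TLS pattern's weights. The other examples walk the imaging arm:
simulation (`01`), densities and rank tests (`02`), interaction networks
(`03`), and TLS profiling (`04`), each printing the numbers it computes
and what they mean.

A thin CLI wraps the config-driven pipeline for shell use:

```bash
lesionscape simulate --out demo/sim --seed 0
lesionscape proteomic --cells demo/sim/cells.csv --regions demo/sim/regions.geojson --out demo/prot
lesionscape transcriptomic --counts demo/sim/spots --tls demo/sim/tls_hulls.geojson \
    --genesets demo/sim/gene_sets.gmt --out demo/st
```

Each run writes tidy CSV/JSON artifacts and a `manifest.json` of SHA-256
checksums; reruns at a fixed seed reproduce the checksums bit for bit.

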