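"""Phenotype gating, per-region densities, and rank-sum comparisons.

Recovers phenotypes from marker intensities with ordered boolean gates,
computes cells/mm² per region and phenotype, contrasts the regulatory
T-cell density between precursor (PanIN) and tumor (PDAC) regions, and
prints the CD8/Treg density ratio — the quantity that separates an
immunologically favourable precursor environment from an immunosuppressed
tumor.
"""

import lesionscape as ls
from lesionscape import synthetic as syn

cfg = syn.demo_tissue_config(seed=0)
cells, regions, truth = syn.generate_cell_map(cfg)
cells = ls.phenotype_cells(cells, thresholds=cfg.marker_model.threshold())

dens = ls.cell_density(cells, regions)
treg = dens[dens.phenotype == "Treg"]
print("mean Treg density (cells/mm²) by region class:")
print(treg.groupby("region_class")["density"].mean().round(1).to_string())

groups = {
    cls: g["density"].to_numpy()
    for cls, g in treg.groupby("region_class")
    if cls in ("PanIN", "PDAC")
}
stat, p = ls.compare_groups(groups)
print(f"\nPanIN vs PDAC Treg density rank-sum: U = {stat:.0f}, p = {p:.3g}")
print("(unadjusted two-sided p, exact for these group sizes)")

ratio = ls.density_ratio(dens, "T_CD8", "Treg")
by_class = dens.drop_duplicates("region_id").set_index("region_id")["region_class"]
print("\nmean CD8/Treg ratio by region class (higher = less suppressed):")
print(ratio.groupby(by_class).mean().round(2).to_string())
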