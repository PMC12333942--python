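"""Cell-cell interaction structure from nearest-neighbour distances.

For the PDAC regions of the demo section, computes (a) the mean
nearest-neighbour distance between every ordered phenotype pair — small
values mean the two types are spatially integrated — and (b) the top-2
neighbour contact matrix, which counts who each cell's two closest
neighbours are.
"""

import lesionscape as ls
from lesionscape import synthetic as syn

cfg = syn.demo_tissue_config(seed=0)
cells, regions, _ = syn.generate_cell_map(cfg)
cells = ls.phenotype_cells(cells, thresholds=cfg.marker_model.threshold())

pdac_ids = [r.region_id for r in regions.of_class("PDAC")]
pdac = cells[cells.region_id.isin(pdac_ids)]

im = ls.interaction_matrix(pdac, min_frac=0.01)
print("mean shortest distance (μm), Treg row vs selected partners:")
for partner in ["T_cytotoxic", "T_CD8", "Fibroblast", "Epithelial"]:
    if partner in im.M.columns:
        print(f"  Treg -> {partner:12s} {im.M.loc['Treg', partner]:7.1f}")

edges, G = ls.interaction_network(im)
print(f"\ninteraction network: {G.number_of_nodes()} phenotypes, "
      f"{G.number_of_edges()} edges (symmetrized distances)")

contacts = ls.top2_neighbor_matrix(pdac, min_frac=0.01)
norm = ls.normalize_contacts(contacts, pdac)
row = norm.loc["Treg"].sort_values(ascending=False).head(3)
print("\nTreg top-2 contacts, normalized by dominant phenotype count:")
print(row.round(3).to_string())
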