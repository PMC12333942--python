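"""Generate a synthetic tissue section with planted immune architecture.

Builds the bundled demo configuration — normal / PanIN / PDAC / CP regions
with class-specific immune densities plus four planted lymphoid aggregates —
and prints what was planted.  Every downstream example starts from data like
this, so the ground truth is always known.
"""

import pandas as pd

from lesionscape import synthetic as syn

cfg = syn.demo_tissue_config(seed=0)
cells, regions, truth = syn.generate_cell_map(cfg)

print(f"cells generated: {len(cells)}")
print(f"regions: {len(regions)} "
      f"({pd.Series([r.region_class for r in regions]).value_counts().to_dict()})")
print("planted phenotype counts (top 8):")
print(pd.Series(truth.cell_phenotype).value_counts().head(8).to_string())
print("\nplanted aggregates:")
for t in truth.tls:
    print(f"  {t['tls_id']}: {t['maturity']:9s} near {t['lesion_class']}, "
          f"{len(t['member_cell_ids'])} cells")
# The marker intensities are lognormal around mu_pos for each phenotype's
# positive markers, so gating in example 02 can recover these labels.
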