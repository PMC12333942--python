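# Default phenotype gates for the simulated imaging panel.
# A cell matches a gate when all positive markers are called positive and all
# negative markers negative; more-specific gates take precedence, ties broken
# by the order below.  The regulatory T cell gate is CD4+FOXP3+PD1- per the
# standard definition.
gates:
  - name: T_exhausted
    positive: [CD4, CD45RO, TOX2, PD1]
  - name: T_central_memory
    positive: [CD4, CD45RO, CCR7, HLADR]
  - name: Treg
    positive: [CD3, CD4, FOXP3]
    negative: [PD1]
  - name: T_memory_CD57
    positive: [CD4, CD45RO, CD57]
  - name: T_cytotoxic
    positive: [CD3, CD8, GZMB]
  - name: B_GC
    positive: [CD20, CD21, CD23]
  - name: B_proliferating
    positive: [CD20, CD45RA, KI67]
  - name: Macrophage
    positive: [CD68, CD16, CD11c]
  - name: Fibroblast
    positive: [COL, SMA, VIM]
  - name: B
    positive: [CD20, CD45RA]
  - name: T_CD8
    positive: [CD3, CD8]
  - name: T_CD4
    positive: [CD3, CD4]
  - name: T
    positive: [CD3]
  - name: Dendritic
    positive: [DCSIGN]
  - name: Endothelial_HEV
    positive: [PDPN]
  - name: NK
    positive: [CD57]
  - name: Epithelial
    positive: [CK]
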