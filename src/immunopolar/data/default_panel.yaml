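Thelper:
  Th1:
  - CD4
  - IFNG
  - IL10
  - FASLG
  - EOMES
  - TBX21
  Th2:
  - CD4
  - IL4
  - IL5
  - IL6
  - IL10
  - GATA3
  - PPARG
  Th17:
  - CD4
  - IL17A
  - IL17F
  - RORA
  - RORC
  iTreg:
  - CD4
  - TGFB1
  - IL10
  - IL12A
  - EBI3
  - RORC
  - FOXP3
  - TBX21
  - CCR6
  - MYB
macrophage:
  M1:
  - IDO1
  - IL23A
  - IL12B
  - CCL17
  - IL1B
  M2:
  - ARG1
  - TIMP2
  - LYVE1
  - KLF4
  - CD163
  - STAB1
infiltration:
  NK:
  - KLRD1
  - KLRC2
  - KLRC3
  Tcell:
  - CD247
  - CD3G
  - CD3D
  - CD3E
  macrophage:
  - CD14
  - CPM
  - MRC1
  - ITGAM
other:
  Tcell_surface:
  - CD247
  - CD3D
  - CD3E
  - CD3G
  - ITGAL
  - ITGB2
  - ICAM1
  - CD2
  - CD28
  - THY1
  - PTPRC
  IL12_STAT4_pathway:
  - CD247
  - CD3D
  - CD3E
  - CD3G
  - JAK2
  - CCR5
  - CXCR3
  - ETV5
  - IFNG
  - IL12RB1
  - IL12RB2
  - IL12A
  - IL12B
  - IL18
  - IL18R1
  - JUN
  - MAPK14
  - MAPK8
  - MAP2K6
  - STAT4
  - TYK2
  CTL_response:
  - CD247
  - CD3D
  - CD3E
  - CD3G
  - CD8A
  - FAS
  - FASLG
  - B2M
  - GZMB
  - ITGAL
  - ITGB2
  - ICAM1
  - HLA-A
  - PRF1
  - HLA-B
  - HLA-C
  NK_cells:
  - KLRC1
  - KLRC2
  - KLRC3
  - KLRD1
  NK_cytotoxicity:
  - IFNA1
  - IFNA2
  - IFNG
  - CD247
  - FAS
  - FASLG
  - GZMB
  - ICAM1
  - KLRC1
  - KLRC2
  - KLRC3
  - KLRD1
  - PRF1
  - ITGAL
  - ITGB2
  NO2_IL12_NK:
  - CD247
  - CD2
  - CD4
  - JAK2
  - CCR5
  - CXCR3
  - IFNG
  - IL12RB1
  - IL12RB2
  - IL12A
  - IL12B
  - NOS2
  - STAT4
  - TYK2
  macrophage_markers:
  - CD14
  - MRC1
  - CPM
  - ITGAM
  - NOS2
  - HLA-DRA
  - HLA-DMA
  - HLA-DOA
  - HLA-DPA1
  - HLA-DQA1
  - HLA-DQA2
  IL12_family:
  - IL12A
  - IL12B
  - IL23A
  - EBI3
  immunosuppression:
  - CD274
  - PDCD1
  - CTNNB1
  - WISP1
  - HMGB1
  - HIF1A
  - BTLA
  - HAVCR2
  - LAG3
  - TGFB1
  - MICA
  - MICB
  - VTCN1
  proliferation:
  - MKI67
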