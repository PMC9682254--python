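"""Synthetic stand-in marker lists for 23 immune cell types.

The published reference marker lists for the immune cell types other than
CD8 T cells are not redistributed here.  The lists below are SYNTHETIC
stand-ins: short, curated panels of canonical lineage markers assembled
from general immunology knowledge so that the built-in registry is
complete and self-consistent for pipeline runs and tests.  Their exact
content is configurable input, not ground truth — any analysis meant to
reproduce a published result should load the reference lists from a GMT
file instead (``load_gmt``).
"""

# cell type -> canonical marker panel (synthetic stand-in, see module docstring)
SYNTHETIC_IMMUNE_MARKERS: dict[str, list[str]] = {
    "B cells": ["CD19", "MS4A1", "CD79A", "CD79B", "BLK", "TCL1A", "BLNK", "FCRL2", "IGHM", "PAX5"],
    "T cells": ["CD2", "CD3D", "CD3E", "CD3G", "CD6", "TRAC", "TRBC1", "LCK", "ITK", "SH2D1A"],
    "T helper cells": ["CD4", "ICOS", "CD28", "BATF", "ANP32B", "ASF1A", "FRYL", "GOLGA8A"],
    "Tcm": ["CCR7", "SELL", "TCF7", "IL7R", "AQP3", "ATF7IP", "CASP8", "MAP3K1"],
    "Tem": ["GZMK", "CCR5", "KLRG1", "EOMES", "AKT3", "CCR2", "EWSR1", "NFATC4"],
    "TFH": ["CXCR5", "CXCL13", "PDCD1", "BCL6", "ICA1", "MAF", "SH2D1A", "ST8SIA1"],
    "Tgd": ["TRDC", "TRGC1", "TRGC2", "KLRC1", "CD160", "FEZ1", "TARP"],
    "Th1": ["TBX21", "IFNG", "IL12RB2", "STAT4", "CXCR3", "HAVCR2", "LTA", "CTLA4"],
    "Th2": ["GATA3", "IL4", "IL5", "IL13", "CXCR6", "STAT6", "PTGDR2", "IL26"],
    "Th17": ["RORC", "IL17A", "IL17RA", "CCR6", "IL23R", "IL21R", "CTSL"],
    "Treg": ["FOXP3", "IL2RA", "IKZF2", "TNFRSF18", "CCR8", "TIGIT", "CTLA4"],
    "Cytotoxic cells": ["GZMA", "GZMB", "GZMH", "GNLY", "PRF1", "NKG7", "KLRB1", "KLRD1", "KLRK1", "CTSW"],
    "NK cells": ["NCR1", "KIR2DL1", "KIR2DL3", "KIR3DL1", "NCAM1", "XCL1", "XCL2", "SPON2"],
    "NK CD56dim cells": ["FCGR3A", "KIR2DL2", "KIR2DS5", "KIR3DS1", "S1PR5", "IL21R", "GTF3C1"],
    "NK CD56bright cells": ["KLRC3", "XCL1", "NCAM1", "GZMK", "DUSP4", "FOXJ1", "MPPED1", "PLA2G6"],
    "DC": ["CD1A", "CD1B", "CD1E", "CCL13", "CCL17", "CCL22", "HSD11B1", "NPR1"],
    "iDC": ["CD1A", "CD1C", "CLEC10A", "FCER1A", "F13A1", "SYT17", "GUCA1A", "MMP12"],
    "aDC": ["LAMP3", "CCL19", "CCR7", "EBI3", "CD83", "INDO", "OAS3"],
    "pDC": ["IL3RA", "CLEC4C", "LILRA4", "GZMB", "IRF7", "TCF4", "PLD4"],
    "Macrophages": ["CD68", "CD163", "MRC1", "MSR1", "MARCO", "CXCL5", "SCG5", "APOE"],
    "Mast cells": ["TPSAB1", "TPSB2", "CPA3", "MS4A2", "CMA1", "HDC", "SLC18A2", "KIT"],
    "Neutrophils": ["FCGR3B", "CSF3R", "CEACAM3", "FPR1", "CXCR1", "CXCR2", "S100A12", "SIGLEC5"],
    "Eosinophils": ["CCR3", "IL5RA", "PRG2", "EPX", "RNASE2", "RNASE3", "SIGLEC8", "GPR44"],
}
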