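"""Default gene panel, marker catalogs, gene sets and ligand-receptor pairs.

The catalogs mirror a kidney-biopsy taxonomy: 24 major cell types spanning
nephron parenchyma (podocytes through collecting duct), stroma/vasculature and
immune lineages, 9 major spatial niche types, and 7 immune niche subtypes.
Marker choices follow standard kidney and immunology usage (PODXL podocytes,
CUBN/LRP2 proximal tubule, UMOD/CASR thick ascending limb, HAVCR1/SOX9 injured
proximal tubule, CD8A/CD8B cytotoxic T cells, IL3RA/LILRA4 pDCs, ...).

The default panel is a reduced in-situ panel (~300 genes): every marker,
module gene and ligand/receptor plus background filler genes. All catalogs are
plain dicts so callers can supply their own.
"""

from __future__ import annotations

# --- cell types -------------------------------------------------------------

#: 24 major cell types -> unique scoring markers (all "up" direction).
CELL_TYPE_MARKERS: dict[str, list[str]] = {
    # nephron parenchyma
    "Podocyte": ["PODXL", "NPHS1", "NPHS2", "PTPRO"],
    "Parietal epithelial": ["WT1", "CLDN1", "PAX8", "AKAP12"],
    "Proximal tubule": ["CUBN", "LRP2", "SLC34A1", "GATM"],
    "Injured proximal tubule": ["HAVCR1", "SOX9", "VCAM1", "DCDC2"],
    "Thick ascending limb": ["UMOD", "CASR", "SLC12A1", "CLDN16"],
    "Distal convoluted tubule": ["TRPM6", "KCNJ10", "SLC12A3", "CNNM2"],
    "Collecting duct principal": ["SCNN1G", "HSD11B2", "AQP2", "GATA3"],
    "Collecting duct intercalated": ["SLC4A1", "ATP6V0D2", "SLC26A4", "FOXI1"],
    # stroma / vasculature
    "Endothelial": ["PECAM1", "CDH5", "EMCN", "FLT1"],
    "Vascular smooth muscle": ["ACTA2", "MYH11", "TAGLN", "PDGFRB"],
    "Fibroblast": ["PDGFRA", "COL5A1", "COL1A1", "DCN"],
    # immune
    "CD4 T": ["CD4", "IL7R", "CD40LG", "TRAT1"],
    "CD8 T": ["CD8A", "CD8B", "GZMK", "CCL5"],
    "Treg": ["FOXP3", "CTLA4", "IKZF2", "IL2RA"],
    "Proliferating T": ["MKI67", "TOP2A", "STMN1", "UBE2C"],
    "NK": ["NKG7", "GNLY", "KLRD1", "NCR1"],
    "B": ["CD19", "MS4A1", "CD79A", "CD79B"],
    "Plasma": ["XBP1", "FCRL5", "TNFRSF17", "MZB1"],
    "pDC": ["IL3RA", "LILRA4", "CLEC4C", "IRF7"],
    "cDC1": ["CLEC9A", "XCR1", "BATF3", "WDFY4"],
    "Monocyte": ["CD14", "FCN1", "S100A8", "S100A9"],
    "Inflammatory myeloid": ["CXCL9", "CIITA", "MMP9", "IDO1"],
    "Tissue-resident macrophage": ["CD163", "MRC1", "F13A1", "STAB1"],
    "Mast": ["TPSAB1", "CPA3", "KIT", "MS4A2"],
}

IMMUNE_CELL_TYPES: list[str] = [
    "CD4 T", "CD8 T", "Treg", "Proliferating T", "NK", "B", "Plasma", "pDC",
    "cDC1", "Monocyte", "Inflammatory myeloid", "Tissue-resident macrophage",
    "Mast",
]

TUBULE_CELL_TYPES: list[str] = [
    "Proximal tubule", "Injured proximal tubule", "Thick ascending limb",
    "Distal convoluted tubule", "Collecting duct principal",
    "Collecting duct intercalated",
]

#: extra program genes expressed by a type beyond its unique markers
#: (gene -> rate relative to the marker rate, applied in the generator).
SHARED_PROGRAMS: dict[str, dict[str, float]] = {
    t: {"PTPRC": 0.8, "B2M": 0.5} for t in IMMUNE_CELL_TYPES
}
for _t in ("CD4 T", "CD8 T", "Treg", "Proliferating T"):
    SHARED_PROGRAMS[_t].update({"CD3E": 0.8, "CD3D": 0.6})
SHARED_PROGRAMS["CD8 T"].update(
    {"GZMA": 0.5, "CXCR6": 0.4, "ZNF683": 0.3, "ITGAE": 0.3, "CXCR3": 0.5}
)
SHARED_PROGRAMS["CD4 T"].update({"CXCR5": 0.2, "CCR7": 0.3})
SHARED_PROGRAMS["NK"].update({"GZMA": 0.5})
SHARED_PROGRAMS["B"].update({"CXCR5": 0.4, "CCR7": 0.3})
SHARED_PROGRAMS["Plasma"].update(
    {"JCHAIN": 0.8, "CCR4": 0.3, "PRDM1": 0.3, "DERL3": 0.3})
SHARED_PROGRAMS["pDC"].update({"TCF4": 0.4, "GZMB": 0.4})
SHARED_PROGRAMS["Treg"].update({"CCR4": 0.4})
SHARED_PROGRAMS["Inflammatory myeloid"].update(
    {"CXCL10": 0.7, "CXCL11": 0.5, "CSF2RB": 0.5, "CD14": 0.3}
)
SHARED_PROGRAMS["Injured proximal tubule"] = {"CUBN": 0.15, "LRP2": 0.15}
# EGF is produced by the distal nephron (TAL and DCT)
SHARED_PROGRAMS["Thick ascending limb"] = {"EGF": 0.25}
SHARED_PROGRAMS["Distal convoluted tubule"] = {"EGF": 0.12}
SHARED_PROGRAMS["Parietal epithelial"] = {"PODXL": 0.15}

# --- gene sets --------------------------------------------------------------

GENE_SETS: dict[str, list[str]] = {
    "IFNg Response": [
        "STAT1", "GBP1", "GBP5", "IRF1", "TAP1", "PSMB9", "SLAMF7", "CD38",
        "IFIT1", "IFIT3", "ISG15", "MX1", "OAS1", "CXCL9", "CXCL10", "CXCL11",
    ],
    "Oxidative Phosphorylation": [
        "NDUFA4", "NDUFB2", "NDUFS4", "SDHB", "UQCRB", "UQCRH", "UQCR11",
        "COX4I1", "COX5A", "COX6C", "COX7B", "ATP5F1E", "ATP5MC1", "CYCS",
    ],
    "JAK-STAT Signaling": ["JAK1", "JAK2", "STAT1", "STAT3", "SOCS1", "SOCS3", "IRF9"],
    "Antigen Presentation": ["TAP1", "TAP2", "PSMB8", "PSMB9", "B2M", "CD74"],
    "Chemokine Signaling": [
        "CXCL9", "CXCL10", "CXCL11", "CXCL12", "CXCL13", "CCL19", "CCL21",
        "CXCR3", "CXCR5", "CCR7", "CCR4", "CCL5",
    ],
}

#: genes marking fibrotic tissue (used by the generator's fibrosis domain)
FIBROSIS_PROGRAM: list[str] = [
    "COL1A1", "COL3A1", "COL5A1", "FN1", "POSTN", "LUM", "PDGFRA",
]

HOUSEKEEPING: list[str] = [
    "ACTB", "GAPDH", "RPL13A", "TUBB", "EEF1A1", "RPS18", "PPIA", "UBC",
]

# --- niche catalogs ---------------------------------------------------------

#: 9 major spatial niche types -> marker genes.
NICHE_TYPE_MARKERS: dict[str, list[str]] = {
    "glomerular": ["PODXL", "NPHS1", "NPHS2", "WT1"],
    "proximal tubule": ["CUBN", "LRP2", "SLC34A1", "GATM"],
    "injured proximal tubule": ["HAVCR1", "SOX9", "VCAM1", "DCDC2"],
    "thick ascending limb": ["UMOD", "CASR", "SLC12A1", "CLDN16"],
    "distal convoluted tubule": ["TRPM6", "KCNJ10", "SLC12A3", "CNNM2"],
    "collecting duct": ["SCNN1G", "HSD11B2", "AQP2", "SLC4A1", "ATP6V0D2"],
    "immune": ["PTPRC", "CD3E", "CD3D", "CD8A", "MS4A1", "SLAMF7", "CD38"],
    "fibrotic": ["COL1A1", "COL3A1", "FN1", "POSTN", "LUM", "DCN"],
    "vascular": ["PECAM1", "CDH5", "EMCN", "MYH11", "TAGLN"],
}

#: 7 immune niche subtypes -> marker genes.
IMMUNE_SUBTYPE_MARKERS: dict[str, list[str]] = {
    "myeloid inflammation": ["CXCL9", "CXCL10", "CXCL11", "MMP9", "IDO1", "CSF2RB"],
    "TLS-like": ["CXCL13", "CCL19", "CCL21", "CXCR5", "CCR7", "CD28", "ICOS", "MS4A1"],
    "CD8 infiltrated kidney": ["CD8A", "CD8B", "GZMK", "CXCR3", "CXCR6",
                               "CUBN", "LRP2"],
    # niche-level plasma markers favour genes specific to plasma-cell
    # microenvironments over ubiquitous plasma-cell transcripts
    "plasma cell": ["FCRL5", "TNFRSF17", "CXCL12", "PRDM1", "DERL3"],
    "pDC": ["IL3RA", "LILRA4", "CLEC4C", "IRF7", "TCF4", "GZMB"],
    "M2-like": ["CD163", "MRC1", "F13A1", "STAB1"],
    "inflammation with fibrosis": ["COL5A1", "PDGFRA", "POSTN", "PTPRC", "CD14"],
}

# --- ligand-receptor pairs --------------------------------------------------

#: (ligand, receptor, axis name) for spatial crosstalk analysis.
LR_PAIRS: list[tuple[str, str, str]] = [
    ("CXCL9", "CXCR3", "CXCL9-CXCR3"),
    ("CXCL10", "CXCR3", "CXCL10-CXCR3"),
    ("CXCL11", "CXCR3", "CXCL11-CXCR3"),
    ("CXCL13", "CXCR5", "CXCL13-CXCR5"),
    ("CCL19", "CCR7", "CCL19-CCR7"),
    ("CXCL12", "CCR4", "CXCL12-CCR4"),
]

#: genes measured by the paired urine-proteomics panel (transcript side).
PROTEOMICS_GENES: list[str] = ["CXCL9", "CXCL10", "CXCL11", "FASLG", "GZMA", "EGF"]

# --- default cohort composition --------------------------------------------

#: expected cell-type proportions in the ATN condition (sums to 1).
BASE_PROPORTIONS: dict[str, float] = {
    "Proximal tubule": 0.230,
    "Thick ascending limb": 0.230,
    "Distal convoluted tubule": 0.036,
    "Collecting duct principal": 0.024,
    "Collecting duct intercalated": 0.010,
    "Injured proximal tubule": 0.050,
    "Podocyte": 0.015,
    "Parietal epithelial": 0.010,
    "Endothelial": 0.055,
    "Vascular smooth muscle": 0.025,
    "Fibroblast": 0.065,
    "CD4 T": 0.050,
    "CD8 T": 0.070,
    "Treg": 0.005,
    "Proliferating T": 0.005,
    "NK": 0.015,
    "B": 0.020,
    "Plasma": 0.005,
    "pDC": 0.005,
    "cDC1": 0.005,
    "Monocyte": 0.025,
    "Inflammatory myeloid": 0.008,
    "Tissue-resident macrophage": 0.025,
    "Mast": 0.004,
}

#: AIN/ATN pooled-proportion fold per type. The six headline immune and
#: podocyte enrichments carry the published magnitudes; the thick ascending
#: limb fold is None and is solved at config build time so AIN proportions
#: close to 1 (compositional closure).
AIN_FOLDS: dict[str, float | None] = {
    "Plasma": 27.0,
    "pDC": 8.0,
    "Proliferating T": 7.9,
    "Treg": 7.6,
    "Inflammatory myeloid": 3.6,
    "Podocyte": 3.4,
    "Collecting duct intercalated": 1.5,
    "Distal convoluted tubule": 1.15,
    "Collecting duct principal": 1.0,
    "Proximal tubule": 0.82,
    "Injured proximal tubule": 0.2,
    "Thick ascending limb": None,  # balance
    "Parietal epithelial": 0.9,
    "Endothelial": 0.6,
    "Vascular smooth muscle": 0.75,
    "Fibroblast": 1.0,
    "CD4 T": 0.8,
    "CD8 T": 0.95,
    "NK": 0.7,
    "B": 1.0,
    "cDC1": 0.8,
    "Monocyte": 0.55,
    "Tissue-resident macrophage": 1.4,
    "Mast": 0.6,
}

#: fraction of immune-cell IFNG transcripts emitted by each immune type.
IFNG_ATTRIBUTION: dict[str, float] = {
    "CD8 T": 0.751,
    "CD4 T": 0.100,
    "NK": 0.080,
    "Proliferating T": 0.040,
    "Inflammatory myeloid": 0.029,
}

_EXTRA_GENES: list[str] = [
    # pan-immune / T-cell program genes not in any unique marker list
    "PTPRC", "CD3E", "CD3D", "GZMA", "CXCR6", "ZNF683", "ITGAE", "JCHAIN",
    # chemokine receptors / ligands and TLS program
    "CXCR3", "CXCR5", "CCR7", "CCR4", "CXCL12", "CXCL13", "CCL19", "CCL21",
    "CXCL10", "CXCL11", "CD28", "ICOS", "CSF2RB",
    # cytokines / proteomics pairing
    "IFNG", "EGF", "FASLG", "SLAMF7", "CD38", "CD74",
    # exhaustion / residency / effector markers
    "PDCD1", "LAG3", "KLRG1", "CX3CR1", "GBP1", "GBP5",
    # second-tier lymphoid niche genes (annotation, not cell typing)
    "TCF4", "GZMB", "PRDM1", "DERL3",
]

N_BACKGROUND_GENES = 120


def build_default_panel() -> list[str]:
    """Assemble the reduced default gene panel (~300 genes, sorted, unique).

    Contains every marker, module gene, ligand/receptor and housekeeping gene
    plus ``N_BACKGROUND_GENES`` filler genes (``BG001`` ...) that carry only
    baseline noise, emulating the bulk of an in-situ panel.
    """
    genes: set[str] = set()
    for markers in CELL_TYPE_MARKERS.values():
        genes.update(markers)
    for prog in SHARED_PROGRAMS.values():
        genes.update(prog)
    for gs in GENE_SETS.values():
        genes.update(gs)
    for markers in NICHE_TYPE_MARKERS.values():
        genes.update(markers)
    for markers in IMMUNE_SUBTYPE_MARKERS.values():
        genes.update(markers)
    for lig, rec, _ in LR_PAIRS:
        genes.update((lig, rec))
    genes.update(FIBROSIS_PROGRAM)
    genes.update(HOUSEKEEPING)
    genes.update(PROTEOMICS_GENES)
    genes.update(_EXTRA_GENES)
    genes.update(f"BG{i:03d}" for i in range(1, N_BACKGROUND_GENES + 1))
    return sorted(genes)
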