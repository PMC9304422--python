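"""Controlled vocabularies shared across the package.

Category labels follow the conventions of Illumina 450k annotation
(island relation), the Roadmap Epigenomics 15-state ChromHMM model
(chromatin states) and the 12-cell-type sorted-blood reference panel.
"""

from __future__ import annotations

#: Roadmap 15-state ChromHMM mnemonics (core model, 111-epigenome release).
CHROMATIN_STATES: tuple[str, ...] = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk",
    "EnhG", "Enh", "ZNF_Rpts", "Het",
    "TssBiv", "BivFlnk", "EnhBiv",
    "ReprPC", "ReprPCWk", "Quies",
)

#: CpG position relative to CpG islands.
ISLAND_RELATIONS: tuple[str, ...] = ("Island", "Shore", "Shelf", "OpenSea")

#: 12 immune cell types of the sorted-blood reference panel.
CELL_TYPES: tuple[str, ...] = (
    "neutrophils", "eosinophils", "basophils", "monocytes",
    "naive_B", "memory_B",
    "naive_T_helper", "memory_T_helper", "regulatory_T",
    "naive_cytotoxic_CD8", "memory_cytotoxic_CD8", "NK",
)

#: Mean peripheral-blood fractions used as the Dirichlet centre of the
#: simulator; values reflect typical healthy-adult deconvolution estimates
#: (neutrophils dominate, basophils are near zero). They sum to 1.
MEAN_BLOOD_FRACTIONS: dict[str, float] = {
    "neutrophils": 0.50,
    "eosinophils": 0.03,
    "basophils": 0.01,
    "monocytes": 0.08,
    "naive_B": 0.02,
    "memory_B": 0.03,
    "naive_T_helper": 0.04,
    "memory_T_helper": 0.12,
    "regulatory_T": 0.02,
    "naive_cytotoxic_CD8": 0.02,
    "memory_cytotoxic_CD8": 0.08,
    "NK": 0.05,
}

#: Lymphocyte lineages, used for the neutrophil-to-lymphocyte ratio.
LYMPHOCYTE_TYPES: tuple[str, ...] = (
    "naive_B", "memory_B",
    "naive_T_helper", "memory_T_helper", "regulatory_T",
    "naive_cytotoxic_CD8", "memory_cytotoxic_CD8", "NK",
)

#: Outcome levels of the phenotype table.
OUTCOMES: tuple[str, ...] = ("control", "future_NHL")

#: Lymphoma subtype vocabulary ("none" marks controls).
NHL_SUBTYPES: tuple[str, ...] = (
    "B", "BCLL", "DLBCL", "FL", "LPL", "MM", "MCL", "LYM", "none",
)

#: Fixed order of the three-class outcome; ties in predicted probability
#: are broken in this order.
CLASS_LEVELS: tuple[str, ...] = ("control", "NHL_hi", "NHL_lo")
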