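"""Default gene exclusion lists.

Copy-number inference from expression assumes a roughly proportional
relationship between genomic dosage and transcript abundance.  Three gene
classes break that assumption and are excluded by default before binning:

* mitochondrially encoded genes — not on the nuclear genome at all;
* HLA genes — extreme allelic/expression variability across individuals
  and cell types;
* cell-cycle genes — expression tracks cycle phase, not dosage.

The lists are ordinary Python sets of HGNC symbols and can be replaced or
extended by the caller; mitochondrial genes are additionally recognised by
the ``MT-`` symbol prefix (case-insensitive) so that annotation dialects
without the canonical symbols still work.
"""

MITO_GENES = frozenset({
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CYB", "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8",
})

HLA_GENES = frozenset({
    "HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "HLA-G",
    "HLA-DRA", "HLA-DRB1", "HLA-DRB5", "HLA-DQA1", "HLA-DQA2",
    "HLA-DQB1", "HLA-DQB2", "HLA-DPA1", "HLA-DPB1",
    "HLA-DMA", "HLA-DMB", "HLA-DOA", "HLA-DOB",
})

# S-phase and G2/M signatures commonly used for cell-cycle scoring in
# single-cell analysis toolkits.
CELL_CYCLE_GENES = frozenset({
    # S phase
    "MCM5", "PCNA", "TYMS", "FEN1", "MCM2", "MCM4", "RRM1", "UNG", "GINS2",
    "MCM6", "CDCA7", "DTL", "PRIM1", "UHRF1", "CENPU", "HELLS", "RFC2",
    "RPA2", "NASP", "RAD51AP1", "GMNN", "WDR76", "SLBP", "CCNE2", "UBR7",
    "POLD3", "MSH2", "ATAD2", "RAD51", "RRM2", "CDC45", "CDC6", "EXO1",
    "TIPIN", "DSCC1", "BLM", "CASP8AP2", "USP1", "CLSPN", "POLA1", "CHAF1B",
    "BRIP1", "E2F8",
    # G2/M phase
    "HMGB2", "CDK1", "NUSAP1", "UBE2C", "BIRC5", "TPX2", "TOP2A", "NDC80",
    "CKS2", "NUF2", "CKS1B", "MKI67", "TMPO", "CENPF", "TACC3", "PIMREG",
    "SMC4", "CCNB2", "CKAP2L", "CKAP2", "AURKB", "BUB1", "KIF11", "ANP32E",
    "TUBB4B", "GTSE1", "KIF20B", "HJURP", "CDCA3", "JPT1", "CDC20", "TTK",
    "CDC25C", "KIF2C", "RANGAP1", "NCAPD2", "DLGAP5", "CDCA2", "CDCA8",
    "ECT2", "KIF23", "HMMR", "AURKA", "PSRC1", "ANLN", "LBR", "CKAP5",
    "CENPE", "CTCF", "NEK2", "G2E3", "GAS2L3", "CBX5", "CENPA",
})
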