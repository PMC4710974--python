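"""Published cross-platform fold-change validation measurements.

Log2 fold changes for validation gene panels from three RNA-seq studies —
human Alzheimer's-disease hippocampus vs control, embryonic (E17) vs adult
mouse cortex, and a rat liver toxicology experiment (aflatoxin B1, AFL, and
N-nitrosodimethylamine, NIT, vs vehicle) — each estimated with four
differential-expression workflows (Cuffdiff, edgeR GLM, edgeR exact test,
DESeq2) and independently measured by qRT-PCR.  These panels are the
standard desk-scale input for the concordance statistics in
:mod:`txpipe.de`.

Note: in the rat panel the qRT-PCR column is on a visibly different
fold-change scale from the RNA-seq columns (e.g. Cdkn1a-AFL: 23.5 vs ~4),
so rat correlations are scale-sensitive and reported for completeness only.
"""

from __future__ import annotations

METHOD_COLUMNS = ("cuffdiff", "edgeR_glm", "edgeR_exact", "deseq2")

#: gene -> (cuffdiff, edgeR_glm, edgeR_exact, deseq2, qrt_pcr) log2 fold changes
HUMAN_HIPPOCAMPUS = {
    "SERPINE1": (1.41, 1.71, 1.54, 0.98, 1.66),
    "TAC1": (-1.77, -1.65, -1.85, -1.56, -0.42),
    "ID2": (0.98, 1.07, 0.88, -0.73, 1.17),
    "GRM2": (0.86, 0.98, 0.78, 0.63, 0.44),
    "LINC01314": (-0.25, -1.19, -1.38, -1.05, -0.50),
    "RP11-87E22.2": (3.63, 2.01, 1.85, 1.31, 2.30),
}

MOUSE_CORTEX = {
    "Vax1": (-2.12, -2.02, -1.74, -1.71, -3.18),
    "Caly": (1.93, 1.79, 2.08, 2.09, 2.10),
    "Igf2bp1": (-9.40, -8.72, -8.45, -8.16, -5.61),
    "Draxin": (-5.98, -5.26, -4.98, -4.94, -6.80),
    "Nrp1": (-2.17, -2.22, -1.94, -1.92, -2.46),
    "Ttr": (11.04, 11.18, 11.46, 11.28, 11.63),
    "Mobp": (12.44, 12.08, 12.36, 12.24, 12.69),
    "Wipf1": (2.22, 1.74, 2.02, 2.03, 1.71),
}

RAT_LIVER = {
    "Bax-AFL": (1.78, 1.86, 1.75, 1.96, 2.62),
    "Cdkn1a-AFL": (4.19, 4.28, 3.30, 8.00, 23.50),
    "Myc-AFL": (0.97, 1.03, 0.82, 0.99, 2.10),
    "Met-AFL": (-1.02, -0.94, -0.88, -0.89, -1.90),
    "Bax-NIT": (1.62, 1.22, 1.19, 1.25, 1.98),
    "Cdkn1a-NIT": (3.22, 2.82, 2.56, 3.05, 8.07),
    "Figf-NIT": (4.18, 3.76, 3.51, 3.72, 10.27),
    "Fzd4-NIT": (-0.30, -0.70, -0.69, -0.73, -2.07),
}

DATASETS = {
    "human_hippocampus": HUMAN_HIPPOCAMPUS,
    "mouse_cortex": MOUSE_CORTEX,
    "rat_liver": RAT_LIVER,
}


def method_vs_qpcr(dataset: str, method: str) -> tuple[list[float], list[float]]:
    """Paired (method, qRT-PCR) log2 fold-change vectors for one dataset."""
    table = DATASETS[dataset]
    col = METHOD_COLUMNS.index(method)
    genes = list(table)
    return (
        [table[g][col] for g in genes],
        [table[g][4] for g in genes],
    )
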