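"""Differential-expression result unification and concordance.

Three upstream tool dialects are parsed into a common record: Cuffdiff's
``gene_exp.diff`` (FPKM-based, with per-group abundance), and the
count-based edgeR (logFC/PValue/FDR) and DESeq2 (log2FoldChange/pvalue/padj)
result tables.  All fold changes are expressed as log2; adjusted p-values
are taken as emitted by each tool, not recomputed.  The unified per-method
table joins in gene metadata (name, biotype, location from the annotated
loci) and per-sample counts, and a DE-only GTF restricts the annotation to
genes below an FDR threshold.

Concordance between two fold-change vectors (e.g. an RNA-seq method vs
qRT-PCR) is summarised by the Pearson correlation r, the coefficient of
determination r², and the fraction of pairs whose fold changes agree in
sign (zero counting as positive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._io import PathLike
from .models import GeneLocus

logger = logging.getLogger(__name__)

METHODS = ("cuffdiff", "edgeR_glm", "edgeR_exact", "deseq2")


class DialectError(ValueError):
    """Input table does not match the declared tool dialect."""


@dataclass
class DERecord:
    """One gene's differential-expression result in unified form."""

    gene_id: str
    log2fc: float
    p_value: float
    fdr: float
    method: str
    gene_name: str = ""
    biotype: str = ""
    chrom_location: str = ""
    counts_by_sample: dict[str, float] = field(default_factory=dict)
    abundance_by_group: dict[str, float] = field(default_factory=dict)
    fdr_was_na: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (0 <= self.p_value <= 1) and not math.isnan(self.p_value):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.fdr < 0:
            raise ValueError("FDR must be non-negative")


_CUFFDIFF_COLS = (
    "gene_id",
    "gene",
    "locus",
    "value_1",
    "value_2",
    "log2(fold_change)",
    "p_value",
    "q_value",
)
_EDGER_COLS = ("logFC", "PValue", "FDR")
_DESEQ2_COLS = ("log2FoldChange", "pvalue", "padj")


def _require_columns(df: pd.DataFrame, needed: Sequence[str], dialect: str) -> None:
    for col in needed:
        if col not in df.columns:
            raise DialectError(
                f"column {col!r} required for dialect {dialect!r} not found; "
                f"file has columns {list(df.columns)}"
            )


def parse_de_output(
    path: PathLike,
    dialect: str,
    method: Optional[str] = None,
) -> list[DERecord]:
    """Parse one tool's result table into unified records.

    ``method`` labels the records; it defaults to the dialect (for edgeR,
    ``edgeR_glm`` unless stated otherwise).  Missing adjusted p-values (NA)
    become 1.0 with ``fdr_was_na`` set — an untestable gene is reported,
    not silently significant.
    """
    if dialect not in ("cuffdiff", "edger", "deseq2"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t")
    records: list[DERecord] = []
    if dialect == "cuffdiff":
        _require_columns(df, _CUFFDIFF_COLS, dialect)
        method = method or "cuffdiff"
        for row in df.itertuples(index=False, name=None):
            d = dict(zip(df.columns, row))
            fdr = d["q_value"]
            was_na = pd.isna(fdr)
            records.append(
                DERecord(
                    gene_id=str(d["gene_id"]),
                    gene_name=str(d["gene"]),
                    chrom_location=str(d["locus"]),
                    abundance_by_group={
                        "group_1": float(d["value_1"]),
                        "group_2": float(d["value_2"]),
                    },
                    log2fc=float(d["log2(fold_change)"]),
                    p_value=float(d["p_value"]),
                    fdr=1.0 if was_na else float(fdr),
                    fdr_was_na=bool(was_na),
                    method=method,
                )
            )
        return records

    if dialect == "edger":
        needed, fc_col, p_col, q_col = _EDGER_COLS, "logFC", "PValue", "FDR"
        method = method or "edgeR_glm"
    else:
        needed, fc_col, p_col, q_col = _DESEQ2_COLS, "log2FoldChange", "pvalue", "padj"
        method = method or "deseq2"
    _require_columns(df, needed, dialect)
    id_col = df.columns[0] if df.columns[0] not in needed else None
    for i, row in df.iterrows():
        gene_id = str(row[id_col]) if id_col else str(i)
        fdr = row[q_col]
        was_na = pd.isna(fdr)
        pval = row[p_col]
        records.append(
            DERecord(
                gene_id=gene_id,
                log2fc=float(row[fc_col]),
                p_value=1.0 if pd.isna(pval) else float(pval),
                fdr=1.0 if was_na else float(fdr),
                fdr_was_na=bool(was_na),
                method=method,
            )
        )
    return records


UNIFIED_COLUMNS = (
    "gene_id",
    "gene_name",
    "biotype",
    "chrom_location",
    "log2fc",
    "p_value",
    "fdr",
    "method",
)


def build_unified_table(
    records: list[DERecord],
    loci: list[GeneLocus],
    counts: Optional[Mapping[str, Mapping[str, float]]] = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[GeneLocus]]:
    """Annotate records with gene metadata and select DE-only loci.

    Returns the unified table (sorted by FDR then gene_id) and the loci
    with fdr < ``alpha``, ready to be written as a DE-only GTF.  Gene ids
    absent from ``loci`` keep biotype "unknown" and are logged.
    """
    by_id = {locus.gene_id: locus for locus in loci}
    counts = counts or {}
    rows = []
    de_gene_ids = set()
    for rec in records:
        locus = by_id.get(rec.gene_id)
        if locus is None:
            if not rec.biotype:
                logger.warning("gene %s not found in annotation", rec.gene_id)
            biotype = rec.biotype or "unknown"
            name, location = rec.gene_name, rec.chrom_location
        else:
            biotype = locus.biotype
            name = rec.gene_name or locus.gene_name
            chrom, start, end, strand = locus.span
            location = f"{chrom}:{start}-{end}({strand})"
        row = {
            "gene_id": rec.gene_id,
            "gene_name": name,
            "biotype": biotype,
            "chrom_location": location,
            "log2fc": rec.log2fc,
            "p_value": rec.p_value,
            "fdr": rec.fdr,
            "method": rec.method,
        }
        for sample, value in sorted(counts.get(rec.gene_id, {}).items()):
            row[f"count_{sample}"] = value
        for group, value in sorted(rec.abundance_by_group.items()):
            row[f"fpkm_{group}"] = value
        rows.append(row)
        if rec.fdr < alpha and locus is not None:
            de_gene_ids.add(rec.gene_id)
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["fdr", "gene_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        table = pd.DataFrame(columns=list(UNIFIED_COLUMNS))
    de_loci = sorted(
        (by_id[g] for g in de_gene_ids),
        key=lambda l: (l.chrom, l.span[1], l.gene_id),
    )
    return table, de_loci


@dataclass(frozen=True)
class ConcordanceResult:
    n: int
    r: float
    r_squared: float
    sign_agreement: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("concordance needs at least 3 pairs")


def concordance(x: Sequence[float], y: Sequence[float]) -> ConcordanceResult:
    """Pearson correlation, r² and sign agreement of paired fold changes.

    Non-finite pairs (e.g. Cuffdiff's ±inf fold changes for on/off genes)
    are excluded with a warning; at least three finite pairs must remain.
    Zero counts as positive for sign agreement.
    """
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    finite = np.isfinite(xa) & np.isfinite(ya)
    if not finite.all():
        logger.warning(
            "excluding %d non-finite fold-change pair(s)", int((~finite).sum())
        )
    xa, ya = xa[finite], ya[finite]
    if len(xa) < 3:
        raise ValueError("fewer than 3 finite pairs")
    if np.allclose(xa, xa[0]) or np.allclose(ya, ya[0]):
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(xa, ya).statistic)
    sign_agreement = float(np.mean((xa >= 0) == (ya >= 0)))
    return ConcordanceResult(
        n=len(xa), r=r, r_squared=r * r, sign_agreement=sign_agreement
    )
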