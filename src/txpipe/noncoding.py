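"""Classify novel loci as coding candidates, lincRNAs or antisense RNAs.

Decision rule, per locus of transcripts absent from the reference:

* any isoform with a significant ORF        → novel_coding_candidate
  (one coding isoform disqualifies the whole locus from being noncoding);
* else any isoform classified antisense     → novel_antisense;
* else                                      → novel_lincRNA.

The ORF rule can be overridden per transcript with an external coding
score file (transcript_id TAB coding|noncoding), the plug-in point for a
sequence-intrinsic classifier.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Mapping, Optional

from pyfaidx import Fasta

from ._io import PathLike, open_text
from .classify import ClassCode
from .models import GeneLocus
from .orf import CodingConfig, ORFResult, find_longest_orf
from .sequences import extract_sequence

logger = logging.getLogger(__name__)


class NotNovelError(ValueError):
    """A locus offered for novel classification contains a known transcript."""


def classify_novel_locus(
    locus: GeneLocus,
    codes: Mapping[str, ClassCode],
    genome: PathLike | Fasta,
    cfg: Optional[CodingConfig] = None,
    external_labels: Optional[Mapping[str, str]] = None,
) -> tuple[str, dict[str, ORFResult]]:
    """Assign a novel locus class; returns (class, per-isoform ORF results).

    ``external_labels`` (transcript_id → "coding"/"noncoding"), when given,
    replaces the ORF rule for the labelled transcripts.
    """
    cfg = cfg or CodingConfig()
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    orf_results: dict[str, ORFResult] = {}
    any_coding = False
    any_antisense = False
    for tx in locus.transcripts:
        code = codes.get(tx.transcript_id)
        if code is not None and code.code == "equal":
            raise NotNovelError(
                f"transcript {tx.transcript_id} is equal to a reference "
                f"transcript; locus {locus.gene_id} is not novel"
            )
        if code is not None and code.code == "antisense":
            any_antisense = True
        label = (external_labels or {}).get(tx.transcript_id)
        if label is not None:
            if label not in ("coding", "noncoding"):
                raise ValueError(f"invalid external label {label!r}")
            if label == "coding":
                any_coding = True
            continue
        seq = extract_sequence(fasta, tx.exons)
        result = find_longest_orf(seq, cfg)
        orf_results[tx.transcript_id] = result
        if result.has_significant_orf:
            any_coding = True
    if any_coding:
        locus_class = "novel_coding_candidate"
    elif any_antisense:
        locus_class = "novel_antisense"
    else:
        locus_class = "novel_lincRNA"
    return locus_class, orf_results


def read_external_labels(path: PathLike) -> dict[str, str]:
    """Read a transcript_id TAB {coding,noncoding} override file."""
    labels: dict[str, str] = {}
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tid, label = line.split("\t")[:2]
            labels[tid] = label
    return labels


def annotate_biotypes(
    loci: list[GeneLocus],
    reference: list[GeneLocus],
    codes: Mapping[str, ClassCode],
    novel_classes: Optional[Mapping[str, str]] = None,
) -> list[GeneLocus]:
    """Attach gene ids, names and biotypes from the reference.

    Loci containing a transcript matched to a reference gene (equal or
    novel isoform) inherit that gene's id, name and biotype.  Novel loci
    receive ids ``NOVEL_LOC_%06d`` in (chrom, start) order and a biotype
    equal to their novel class.
    """
    ref_by_id = {locus.gene_id: locus for locus in reference}
    annotated: list[GeneLocus] = []
    novel: list[GeneLocus] = []
    for locus in loci:
        matched_gene = None
        for tx in locus.transcripts:
            code = codes.get(tx.transcript_id)
            if code and code.code in ("equal", "novel_isoform"):
                matched_gene = code.matched_gene_id
                break
        if matched_gene is not None:
            ref = ref_by_id.get(matched_gene)
            if ref is None or not ref.biotype or ref.biotype == "novel":
                logger.warning(
                    "matched gene %s has no biotype; using 'unknown'",
                    matched_gene,
                )
                biotype, name = "unknown", ref.gene_name if ref else ""
            else:
                biotype, name = ref.biotype, ref.gene_name
            for tx in locus.transcripts:
                tx.gene_id = matched_gene
            annotated.append(
                GeneLocus(
                    gene_id=matched_gene,
                    transcripts=locus.transcripts,
                    gene_name=name,
                    biotype=biotype,
                    locus_class="annotated",
                )
            )
        else:
            novel.append(locus)

    novel.sort(key=lambda l: (l.chrom, l.span[1], l.gene_id))
    renamed: list[GeneLocus] = []
    for i, locus in enumerate(novel, start=1):
        gid = f"NOVEL_LOC_{i:06d}"
        cls = (novel_classes or {}).get(locus.gene_id, locus.locus_class)
        if cls == "annotated":  # no class computed for this locus
            cls = "novel_lincRNA"
        for tx in locus.transcripts:
            tx.gene_id = gid
        renamed.append(
            GeneLocus(
                gene_id=gid,
                transcripts=locus.transcripts,
                gene_name=gid,
                biotype=cls,
                locus_class=cls,
            )
        )
    out = annotated + renamed
    out.sort(key=lambda l: (l.chrom, l.span[1], l.gene_id))
    return out


def write_classification_report(
    loci: list[GeneLocus],
    orf_results: Mapping[str, Mapping[str, ORFResult]],
    path: PathLike,
) -> None:
    """Tab-delimited per-locus classification summary."""
    with open_text(path, "wt") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["locus_id", "class", "biotype", "best_orf_codons", "n_isoforms", "coords"]
        )
        for locus in loci:
            per_tx = orf_results.get(locus.gene_id, {})
            best = max(
                (r.best_orf_length_codons for r in per_tx.values()), default=""
            )
            chrom, start, end, strand = locus.span
            writer.writerow(
                [
                    locus.gene_id,
                    locus.locus_class,
                    locus.biotype,
                    best,
                    len(locus.transcripts),
                    f"{chrom}:{start}-{end}({strand})",
                ]
            )
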