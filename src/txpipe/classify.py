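"""Compare assembled transcripts to the reference annotation.

The full Cuffcompare class-code alphabet is reduced to the five outcomes the
downstream decisions need, applied in strict precedence order:

1. ``equal``          — intron chain identical to a reference transcript on
                        the same strand (single-exon transcripts must also
                        overlap the matched single-exon reference transcript,
                        since an empty intron chain alone is uninformative);
2. ``novel_isoform``  — shares at least one intron with a same-strand
                        reference transcript, or overlaps the exons of a
                        same-strand reference gene (a fragment or contained
                        transcript of an annotated gene);
3. ``intronic``       — falls entirely inside a single intron of a
                        same-strand reference transcript;
4. ``antisense``      — exonic overlap with a reference gene on the opposite
                        strand only;
5. ``intergenic``     — no exonic overlap with any reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from intervaltree import IntervalTree

from .models import GeneLocus, TranscriptModel

CLASS_CODES = ("equal", "novel_isoform", "intronic", "antisense", "intergenic")


@dataclass(frozen=True)
class ClassCode:
    """Outcome of comparing one assembled transcript to the reference."""

    code: str
    matched_gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.code not in CLASS_CODES:
            raise ValueError(f"unknown class code {self.code!r}")
        if (self.matched_gene_id is None) != (self.code == "intergenic"):
            raise ValueError(
                "matched_gene_id must be None exactly for intergenic codes"
            )


class ReferenceIndex:
    """Interval indexes over a reference annotation, built once per run."""

    def __init__(self, reference: list[GeneLocus]):
        self.exon_tree: dict[str, IntervalTree] = {}
        self.intron_chains: dict[tuple, list[tuple[str, TranscriptModel]]] = {}
        self.introns: dict[tuple[int, int, str, str], set[str]] = {}
        self.ref_transcripts: list[tuple[GeneLocus, TranscriptModel]] = []
        for locus in reference:
            for tx in locus.transcripts:
                self.ref_transcripts.append((locus, tx))
                self.intron_chains.setdefault(tx.intron_chain, []).append(
                    (locus.gene_id, tx)
                )
                for intron in tx.introns:
                    key = (intron[0], intron[1], tx.chrom, tx.strand)
                    self.introns.setdefault(key, set()).add(locus.gene_id)
                tree = self.exon_tree.setdefault(tx.chrom, IntervalTree())
                for exon in tx.exons:
                    # half-open interval tree; payload = (gene_id, strand)
                    tree.addi(exon.start, exon.end + 1, (locus.gene_id, tx.strand))

    def exon_overlaps(self, tx: TranscriptModel) -> set[tuple[str, str]]:
        """(gene_id, strand) of reference exons overlapping tx's exons."""
        tree = self.exon_tree.get(tx.chrom)
        if tree is None:
            return set()
        hits: set[tuple[str, str]] = set()
        for exon in tx.exons:
            for iv in tree.overlap(exon.start, exon.end + 1):
                hits.add(iv.data)
        return hits


def classify_vs_reference(
    tx: TranscriptModel,
    reference: list[GeneLocus] | ReferenceIndex,
) -> ClassCode:
    """Assign one of the five class codes to an assembled transcript."""
    index = (
        reference
        if isinstance(reference, ReferenceIndex)
        else ReferenceIndex(reference)
    )

    # 1. equal: identical intron chain (plus overlap for single-exon)
    matches = index.intron_chains.get(tx.intron_chain, [])
    for gene_id, ref_tx in matches:
        if tx.is_multi_exon or tx.exonic_overlap(ref_tx):
            return ClassCode("equal", gene_id)

    # 2. novel_isoform: shared intron or same-strand exonic overlap
    for intron in tx.introns:
        genes = index.introns.get((intron[0], intron[1], tx.chrom, tx.strand))
        if genes:
            return ClassCode("novel_isoform", sorted(genes)[0])
    same_strand = sorted(
        g for g, s in index.exon_overlaps(tx) if s == tx.strand
    )
    if same_strand:
        return ClassCode("novel_isoform", same_strand[0])

    # 3. intronic: wholly inside one intron of a same-strand reference tx
    intronic_genes = []
    for locus, ref_tx in index.ref_transcripts:
        if ref_tx.chrom != tx.chrom or ref_tx.strand != tx.strand:
            continue
        for donor, acceptor in ref_tx.introns:
            if donor < tx.start and tx.end < acceptor:
                intronic_genes.append(locus.gene_id)
                break
    if intronic_genes:
        return ClassCode("intronic", sorted(intronic_genes)[0])

    # 4. antisense: exonic overlap with the opposite strand only
    opposite = sorted(
        g for g, s in index.exon_overlaps(tx) if s != tx.strand
    )
    if opposite:
        return ClassCode("antisense", opposite[0])

    # 5. intergenic
    return ClassCode("intergenic", None)


def classify_all(
    loci: list[GeneLocus], reference: list[GeneLocus]
) -> dict[str, ClassCode]:
    """Class codes for every transcript in ``loci``, keyed by transcript_id."""
    index = ReferenceIndex(reference)
    return {
        tx.transcript_id: classify_vs_reference(tx, index)
        for locus in loci
        for tx in locus.transcripts
    }
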