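"""Core transcript data model shared by every stage of the toolkit.

Coordinates are GTF-native: 1-based, inclusive on both ends.  Any half-open
arithmetic is internal to the interval routines that need it.  A transcript is
an ordered chain of exons on one strand of one chromosome; the gaps between
consecutive exons are its introns, and the (donor, acceptor) pairs of those
gaps — the genomic coordinates of the last exonic base before the gap and the
first exonic base after it — form the intron chain that identifies a splice
structure independently of how far transcription start/end extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

VALID_STRANDS = ("+", "-")


class ValidationError(ValueError):
    """An object violates a data-model invariant."""


@dataclass(frozen=True, order=True)
class Exon:
    """A single exon: 1-based inclusive interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"invalid exon interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Exon") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """One assembled or reference transcript.

    ``attributes`` preserves GTF attribute key/value pairs verbatim so that a
    read-write cycle is lossless; ``fpkm_by_sample`` carries per-sample
    abundance parsed from Cufflinks-style ``FPKM`` attributes.
    """

    transcript_id: str
    gene_id: str
    exons: list[Exon]
    fpkm_by_sample: dict[str, float] = field(default_factory=dict)
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"transcript {self.transcript_id}: exons span multiple "
                f"chromosomes or strands"
            )
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            # introns must have length >= 1: next exon starts at least 2 past
            if b.start <= a.end + 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping or abutting "
                    f"exons {a.start}-{a.end} and {b.start}-{b.end}"
                )
        for s, fpkm in self.fpkm_by_sample.items():
            if fpkm < 0:
                raise ValidationError(
                    f"transcript {self.transcript_id}: negative FPKM in {s}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) genomic pairs, in genomic order.

        donor = last base of the upstream exon, acceptor = first base of the
        downstream exon; donor < acceptor always, whatever the strand.
        """
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def intron_chain(self) -> tuple:
        """Hashable splice-structure key: chrom, strand and all introns."""
        return (self.chrom, self.strand, self.introns)

    def exonic_overlap(self, other: "TranscriptModel") -> bool:
        """True when any exon of self overlaps any exon of other."""
        if self.chrom != other.chrom:
            return False
        return any(a.overlaps(b) for a in self.exons for b in other.exons)


LOCUS_CLASSES = (
    "annotated",
    "novel_coding_candidate",
    "novel_lincRNA",
    "novel_antisense",
)


@dataclass
class GeneLocus:
    """A group of transcripts sharing a genomic locus.

    ``biotype`` uses the ENSEMBL vocabulary for annotated genes
    (protein_coding, lincRNA, antisense, ...) and the ``novel_*`` labels for
    loci absent from the reference.
    """

    gene_id: str
    transcripts: list[TranscriptModel]
    gene_name: str = ""
    biotype: str = "novel"
    locus_class: str = "annotated"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"locus {self.gene_id}: no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"locus {self.gene_id}: transcripts span multiple "
                f"chromosomes or strands"
            )
        if self.locus_class not in LOCUS_CLASSES:
            raise ValidationError(
                f"locus {self.gene_id}: unknown class {self.locus_class!r}"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> tuple[str, int, int, str]:
        """(chrom, min start, max end, strand) covering every exon."""
        return (
            self.chrom,
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
            self.strand,
        )

    def iter_transcripts(self) -> Iterable[TranscriptModel]:
        return iter(self.transcripts)


def group_into_loci(
    transcripts: Iterable[TranscriptModel],
    gene_name: Optional[dict[str, str]] = None,
    biotype: Optional[dict[str, str]] = None,
) -> list[GeneLocus]:
    """Group transcripts by gene_id into GeneLocus objects, genomic order."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    loci = []
    for gid, txs in by_gene.items():
        txs.sort(key=lambda t: (t.start, t.transcript_id))
        loci.append(
            GeneLocus(
                gene_id=gid,
                transcripts=txs,
                gene_name=(gene_name or {}).get(gid, ""),
                biotype=(biotype or {}).get(gid, "novel"),
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.span[1], l.gene_id))
    return loci
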