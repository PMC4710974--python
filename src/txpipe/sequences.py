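"""Spliced-sequence extraction from an indexed genome FASTA."""

from __future__ import annotations

from Bio.Seq import Seq
from pyfaidx import Fasta

from ._io import PathLike
from .models import Exon


class SequenceRangeError(ValueError):
    """Requested coordinates fall outside the contig."""


class UnknownContigError(KeyError):
    """Requested chromosome is absent from the FASTA."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_sequence(genome: PathLike | Fasta, exons: list[Exon]) -> str:
    """Spliced transcript sequence for an exon chain.

    Exon sequences are concatenated in genomic order and the whole spliced
    sequence is reverse-complemented when the chain is on the minus strand,
    so the result always reads 5'→3' in transcript orientation.
    """
    if not exons:
        return ""
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    pieces = []
    for exon in sorted(exons, key=lambda e: e.start):
        if exon.chrom not in fasta:
            raise UnknownContigError(exon.chrom)
        contig = fasta[exon.chrom]
        if exon.end > len(contig):
            raise SequenceRangeError(
                f"{exon.chrom}:{exon.start}-{exon.end} exceeds contig "
                f"length {len(contig)}"
            )
        # pyfaidx slices are 0-based half-open
        pieces.append(str(contig[exon.start - 1 : exon.end]).upper())
    seq = "".join(pieces)
    if exons[0].strand == "-":
        seq = reverse_complement(seq)
    return seq
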