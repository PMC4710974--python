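"""qRT-PCR primer-template selection and primer picking.

Template selection follows the junction-first strategy: find a splice
junction shared by every isoform of the gene, so a primer pair spanning it
amplifies cDNA from any isoform but not genomic DNA.  When no common
junction exists (e.g. the gene has a single-exon isoform), fall back to an
exonic region common to all isoforms.  The chosen template sequence, in
transcript orientation, is then handed to a primer-picking engine; the
built-in engine enumerates candidate 18–24-mers, scores them on melting
temperature (nearest-neighbour, via Biopython) and GC content, and enforces
that junction-spanning amplicons actually cross the junction.  Any callable
with the same signature can replace the built-in engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

from Bio.SeqUtils import MeltingTemp, gc_fraction
from pyfaidx import Fasta

from ._io import PathLike
from .models import Exon, GeneLocus, TranscriptModel
from .sequences import extract_sequence, reverse_complement

MIN_COMMON_EXONIC_BP = 40  # two ~20-mers must fit
MIN_TEMPLATE_LEN = 60


@dataclass(frozen=True, order=True)
class JunctionKey:
    """A splice junction: donor = last exonic base upstream (genomically),
    acceptor = first exonic base downstream; donor < acceptor."""

    chrom: str
    donor: int
    acceptor: int
    strand: str

    def __post_init__(self) -> None:
        if self.acceptor - self.donor < 2:
            raise ValueError("junction must span an intron of length >= 1")


@dataclass
class PrimerTarget:
    gene_id: str
    kind: str  # junction_spanning | common_exonic
    template_seq: str
    junction_pos: Optional[int]  # 0-based offset of first base after junction
    flank: int

    def __post_init__(self) -> None:
        if (self.kind == "junction_spanning") != (self.junction_pos is not None):
            raise ValueError("junction_pos must be set iff junction_spanning")


@dataclass(frozen=True)
class DesignFailure:
    gene_id: str
    reason: str


@dataclass(frozen=True)
class PrimerPair:
    left_seq: str
    right_seq: str
    left_start: int  # 0-based on template
    right_end: int  # 0-based inclusive, on template (3' end of amplicon)
    product_size: int


class StrandMixError(ValueError):
    pass


def _junction_set(tx: TranscriptModel) -> set[JunctionKey]:
    return {
        JunctionKey(tx.chrom, donor, acceptor, tx.strand)
        for donor, acceptor in tx.introns
    }


def _check_consistent(isoforms: list[TranscriptModel]) -> None:
    if not isoforms:
        raise ValueError("no isoforms given")
    if len({(t.chrom, t.strand) for t in isoforms}) > 1:
        raise StrandMixError("isoforms on mixed chromosomes/strands")


def common_junctions(isoforms: list[TranscriptModel]) -> list[JunctionKey]:
    """Junctions present in every isoform, sorted by genomic position.

    A single-exon isoform has no junctions, so its presence forces an
    empty intersection.
    """
    _check_consistent(isoforms)
    common = _junction_set(isoforms[0])
    for tx in isoforms[1:]:
        common &= _junction_set(tx)
    return sorted(common, key=lambda j: (j.donor, j.acceptor))


def _interval_union(tx: TranscriptModel) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in tx.exons]


def _intersect(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo, hi = max(a[i][0], b[j][0]), min(a[i][1], b[j][1])
        if lo <= hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def common_exonic_region(isoforms: list[TranscriptModel]) -> Optional[Exon]:
    """Longest genomic interval exonic in every isoform (ties: smaller start)."""
    _check_consistent(isoforms)
    acc = _interval_union(isoforms[0])
    for tx in isoforms[1:]:
        acc = _intersect(acc, _interval_union(tx))
        if not acc:
            return None
    best = max(acc, key=lambda iv: (iv[1] - iv[0], -iv[0]))
    return Exon(isoforms[0].chrom, best[0], best[1], isoforms[0].strand)


def _flank_availability(
    junction: JunctionKey, isoforms: list[TranscriptModel]
) -> tuple[int, int]:
    """(upstream bp, downstream bp) of flanking-exon sequence available in
    every isoform, measured genomically from the junction."""
    up = down = None
    for tx in isoforms:
        up_exon = next(e for e in tx.exons if e.end == junction.donor)
        down_exon = next(e for e in tx.exons if e.start == junction.acceptor)
        up = up_exon.length if up is None else min(up, up_exon.length)
        down = down_exon.length if down is None else min(down, down_exon.length)
    return up, down


def build_primer_target(
    gene: GeneLocus,
    genome: PathLike | Fasta,
    flank: int = 150,
) -> PrimerTarget | DesignFailure:
    """Select a primer template for a gene.

    Junction-spanning when possible: among the junctions common to all
    isoforms, pick the one maximizing the smaller of the two flanking-exon
    lengths available in every isoform (both primers must sit in sequence
    every isoform contains), extract up to ``flank`` bases each side, and
    mark the junction offset in transcript orientation.  Otherwise fall
    back to the longest common exonic region, which must be at least
    40 bp.  Returns a DesignFailure (never raises) when neither exists.
    """
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    isoforms = gene.transcripts
    junctions = common_junctions(isoforms)
    if junctions:
        scored = [
            (min(*_flank_availability(j, isoforms)), j) for j in junctions
        ]
        best_score, best = max(scored, key=lambda s: (s[0], -s[1].donor))
        up_avail, down_avail = _flank_availability(best, isoforms)
        up_take = min(flank, up_avail)
        down_take = min(flank, down_avail)
        up_exon = Exon(best.chrom, best.donor - up_take + 1, best.donor, best.strand)
        down_exon = Exon(
            best.chrom, best.acceptor, best.acceptor + down_take - 1, best.strand
        )
        template = extract_sequence(fasta, [up_exon, down_exon])
        # transcript orientation: on '-' the genomically-downstream piece
        # comes first, so the junction sits after down_take bases
        junction_pos = up_take if best.strand == "+" else down_take
        return PrimerTarget(
            gene_id=gene.gene_id,
            kind="junction_spanning",
            template_seq=template,
            junction_pos=junction_pos,
            flank=flank,
        )
    region = common_exonic_region(isoforms)
    if region is not None and region.length >= MIN_COMMON_EXONIC_BP:
        template = extract_sequence(fasta, [region])
        return PrimerTarget(
            gene_id=gene.gene_id,
            kind="common_exonic",
            template_seq=template,
            junction_pos=None,
            flank=flank,
        )
    return DesignFailure(
        gene.gene_id,
        "no common junction and no common exonic region >= "
        f"{MIN_COMMON_EXONIC_BP} bp",
    )


DEFAULT_PARAMS = {
    "primer_len_min": 18,
    "primer_len_max": 24,
    "tm_opt": 60.0,
    "tm_min": 54.0,
    "tm_max": 66.0,
    "gc_min": 0.35,
    "gc_max": 0.65,
    "product_min": 70,
    "product_max": 200,
}


def _candidate_primers(template: str, lo: int, hi: int, params: dict):
    """Yield (start, length, seq, tm) for acceptable primers in [lo, hi)."""
    for start in range(lo, hi):
        for length in range(params["primer_len_min"], params["primer_len_max"] + 1):
            if start + length > hi:
                break
            seq = template[start : start + length]
            if "N" in seq:
                continue
            gc = gc_fraction(seq)
            if not (params["gc_min"] <= gc <= params["gc_max"]):
                continue
            tm = MeltingTemp.Tm_NN(seq)
            if params["tm_min"] <= tm <= params["tm_max"]:
                yield start, length, seq, tm


def pick_primers(
    target: PrimerTarget,
    params: Optional[dict] = None,
    engine: Optional[Callable[..., PrimerPair | DesignFailure]] = None,
) -> PrimerPair | DesignFailure:
    """Pick a left/right primer pair on a template.

    For junction-spanning targets the amplicon must contain the junction:
    the left primer ends before ``junction_pos`` and the right primer
    starts at or after it.  A custom ``engine`` callable replaces the
    built-in picker.
    """
    if len(target.template_seq) < MIN_TEMPLATE_LEN:
        raise ValueError(
            f"template too short ({len(target.template_seq)} < {MIN_TEMPLATE_LEN})"
        )
    p = dict(DEFAULT_PARAMS)
    if params:
        p.update(params)
    if engine is not None:
        return engine(target, p)
    template = target.template_seq.upper()
    n = len(template)
    jpos = target.junction_pos

    left_hi = jpos if jpos is not None else n
    right_lo = jpos if jpos is not None else 0
    lefts = list(_candidate_primers(template, 0, left_hi, p))
    rights = [
        (start, length, reverse_complement(seq), tm)
        for start, length, seq, tm in _candidate_primers(template, right_lo, n, p)
    ]
    best = None
    best_score = None
    for ls, ll, lseq, ltm in lefts:
        for rs, rl, rseq, rtm in rights:
            product = rs + rl - ls
            if not (p["product_min"] <= product <= p["product_max"]):
                continue
            if rs < ls + ll:  # primers must not overlap
                continue
            if jpos is not None and not (ls + ll - 1 < jpos and rs > jpos):
                continue
            score = (
                abs(ltm - p["tm_opt"])
                + abs(rtm - p["tm_opt"])
                + 2 * abs(ltm - rtm)
                + 0.01 * abs(product - p["product_min"] * 1.5)
            )
            if best_score is None or score < best_score:
                best_score = score
                best = PrimerPair(
                    left_seq=lseq,
                    right_seq=rseq,
                    left_start=ls,
                    right_end=rs + rl - 1,
                    product_size=product,
                )
    if best is None:
        return DesignFailure(target.gene_id, "no acceptable primer pair found")
    return best


def design_for_genes(
    loci: list[GeneLocus],
    genome: PathLike | Fasta,
    flank: int = 150,
    params: Optional[dict] = None,
) -> list[tuple[str, str, PrimerPair | DesignFailure]]:
    """Design one primer pair per gene; rows of (gene_id, kind, result)."""
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    rows = []
    for locus in loci:
        target = build_primer_target(locus, fasta, flank=flank)
        if isinstance(target, DesignFailure):
            rows.append((locus.gene_id, "failed", target))
            continue
        result = pick_primers(target, params) if len(
            target.template_seq
        ) >= MIN_TEMPLATE_LEN else DesignFailure(locus.gene_id, "template too short")
        rows.append((locus.gene_id, target.kind, result))
    return rows
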