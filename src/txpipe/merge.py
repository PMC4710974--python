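"""Merge per-sample assembled transcripts into a non-redundant set.

Two multi-exon transcripts are the same isoform when their intron chains are
identical (same chrom, strand and ordered (donor, acceptor) pairs); their
terminal exons may differ in extent, so the merged representative takes the
union of the first-exon starts and last-exon ends.  Single-exon transcripts
on the same strand merge when their exons overlap (by at least one base, or
by a configurable fraction of the shorter exon); overlap clusters collapse
to their spanning interval.  Each merged transcript records which samples
contributed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import Exon, GeneLocus, TranscriptModel


@dataclass
class SamplePresence:
    """Which samples an assembled transcript was observed in."""

    transcript_key: str
    present_in: set[str] = field(default_factory=set)
    n_samples: int = 0

    @property
    def n_present(self) -> int:
        return len(self.present_in)


class MergeError(ValueError):
    pass


def _single_exon_clusters(
    items: list[tuple[str, TranscriptModel]], min_overlap_fraction: float
) -> list[list[tuple[str, TranscriptModel]]]:
    """Cluster same-strand single-exon transcripts by exon overlap (sweep)."""
    items = sorted(items, key=lambda it: (it[1].start, it[1].end))
    clusters: list[list[tuple[str, TranscriptModel]]] = []
    cur: list[tuple[str, TranscriptModel]] = []
    cur_end = -1
    for item in items:
        tx = item[1]
        if cur:
            ov = min(cur_end, tx.end) - tx.start + 1
            shorter = min(tx.spliced_length, min(t.spliced_length for _, t in cur))
            needed = max(1, int(min_overlap_fraction * shorter))
            if ov >= needed:
                cur.append(item)
                cur_end = max(cur_end, tx.end)
                continue
            clusters.append(cur)
        cur = [item]
        cur_end = tx.end
    if cur:
        clusters.append(cur)
    return clusters


def merge_samples(
    per_sample: dict[str, list[GeneLocus]],
    min_overlap_fraction: float = 0.0,
) -> tuple[list[GeneLocus], dict[str, SamplePresence]]:
    """Collapse per-sample assemblies into merged loci with presence info.

    Returns ``(loci, presence)`` where presence maps each merged
    transcript_id to the set of contributing samples.  Merged transcripts
    get ids ``MERGED_TX_%06d`` and loci ``MERGED_LOC_%06d``, both assigned
    in genomic order so the result is invariant to sample ordering.  The
    originating ids are preserved in the ``contained_ids`` attribute.
    """
    if not per_sample:
        raise MergeError("no samples provided")
    n_samples = len(per_sample)
    samples = sorted(per_sample)

    multi: dict[tuple, list[tuple[str, TranscriptModel]]] = {}
    single: dict[tuple[str, str], list[tuple[str, TranscriptModel]]] = {}
    for sample in samples:
        for locus in per_sample[sample]:
            for tx in locus.transcripts:
                if tx.is_multi_exon:
                    multi.setdefault(tx.intron_chain, []).append((sample, tx))
                else:
                    single.setdefault((tx.chrom, tx.strand), []).append((sample, tx))

    merged: list[tuple[TranscriptModel, set[str]]] = []

    for chain, members in multi.items():
        chrom, strand, introns = chain
        first_start = min(tx.exons[0].start for _, tx in members)
        last_end = max(tx.exons[-1].end for _, tx in members)
        bounds = [first_start]
        for donor, acceptor in introns:
            bounds.extend([donor, acceptor])
        bounds.append(last_end)
        exons = [
            Exon(chrom, s, e, strand) for s, e in zip(bounds[::2], bounds[1::2])
        ]
        fpkm: dict[str, float] = {}
        for sample, tx in members:
            for k, v in tx.fpkm_by_sample.items():
                fpkm[sample if k == "sample" else k] = max(
                    fpkm.get(sample if k == "sample" else k, 0.0), v
                )
        rep = TranscriptModel(
            transcript_id="",
            gene_id="",
            exons=exons,
            fpkm_by_sample=fpkm,
            attributes={
                "contained_ids": ",".join(
                    sorted({tx.transcript_id for _, tx in members})
                )
            },
        )
        merged.append((rep, {sample for sample, _ in members}))

    for (chrom, strand), items in single.items():
        for cluster in _single_exon_clusters(items, min_overlap_fraction):
            start = min(tx.start for _, tx in cluster)
            end = max(tx.end for _, tx in cluster)
            fpkm = {}
            for sample, tx in cluster:
                for v in tx.fpkm_by_sample.values():
                    fpkm[sample] = max(fpkm.get(sample, 0.0), v)
            rep = TranscriptModel(
                transcript_id="",
                gene_id="",
                exons=[Exon(chrom, start, end, strand)],
                fpkm_by_sample=fpkm,
                attributes={
                    "contained_ids": ",".join(
                        sorted({tx.transcript_id for _, tx in cluster})
                    )
                },
            )
            merged.append((rep, {sample for sample, _ in cluster}))

    # deterministic genomic order, then assign ids
    merged.sort(
        key=lambda m: (m[0].chrom, m[0].start, m[0].end, m[0].attributes["contained_ids"])
    )
    presence: dict[str, SamplePresence] = {}
    for i, (tx, present) in enumerate(merged, start=1):
        tx.transcript_id = f"MERGED_TX_{i:06d}"
        presence[tx.transcript_id] = SamplePresence(
            transcript_key=tx.transcript_id,
            present_in=present,
            n_samples=n_samples,
        )

    loci = _cluster_loci([tx for tx, _ in merged])
    return loci, presence


def _cluster_loci(transcripts: list[TranscriptModel]) -> list[GeneLocus]:
    """Group merged transcripts into loci by same-strand span overlap."""
    by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
    for tx in transcripts:
        by_key.setdefault((tx.chrom, tx.strand), []).append(tx)
    groups: list[list[TranscriptModel]] = []
    for key in sorted(by_key):
        txs = sorted(by_key[key], key=lambda t: (t.start, t.end))
        cur: list[TranscriptModel] = []
        cur_end = -1
        for tx in txs:
            if cur and tx.start <= cur_end:
                cur.append(tx)
                cur_end = max(cur_end, tx.end)
            else:
                if cur:
                    groups.append(cur)
                cur = [tx]
                cur_end = tx.end
        if cur:
            groups.append(cur)
    groups.sort(key=lambda g: (g[0].chrom, min(t.start for t in g)))
    loci = []
    for i, group in enumerate(groups, start=1):
        gid = f"MERGED_LOC_{i:06d}"
        for tx in group:
            tx.gene_id = gid
        loci.append(GeneLocus(gene_id=gid, transcripts=group, biotype="novel"))
    return loci
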