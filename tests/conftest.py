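"""Shared fixtures: a tiny genome on disk and a full synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from txpipe.fixtures import FixtureConfig, make_fixture
from txpipe.models import Exon, GeneLocus, TranscriptModel


def write_fasta(path, contigs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@pytest.fixture
def tiny_genome(tmp_path):
    """One 6-base contig, handy for hand-checked sequence extraction."""
    path = tmp_path / "tiny.fa"
    write_fasta(path, {"ctg": "ACGTAA"})
    return path


@pytest.fixture(scope="session")
def fixture_manifest(tmp_path_factory):
    """Default noisy synthetic dataset, generated once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture(FixtureConfig(seed=7), outdir)


def make_tx(
    tid: str,
    exons: list[tuple[int, int]],
    chrom: str = "chr1",
    strand: str = "+",
    gene_id: str | None = None,
    fpkm: dict | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"g_{tid}",
        exons=[Exon(chrom, s, e, strand) for s, e in exons],
        fpkm_by_sample=fpkm or {},
    )


def make_locus(gene_id: str, txs: list[TranscriptModel], **kw) -> GeneLocus:
    return GeneLocus(gene_id=gene_id, transcripts=txs, **kw)


def random_transcript(
    rng: np.random.Generator,
    chrom: str,
    strand: str,
    region: int = 10_000,
    max_exons: int = 4,
    tid: str = "tx",
) -> TranscriptModel:
    """A random valid transcript inside [1, region]."""
    n_exons = int(rng.integers(1, max_exons + 1))
    pos = int(rng.integers(1, max(2, region - n_exons * 120)))
    exons = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 80))
        exons.append(Exon(chrom, pos, pos + length - 1, strand))
        pos += length + int(rng.integers(2, 60))
    return TranscriptModel(transcript_id=tid, gene_id=f"g_{tid}", exons=exons)


def random_reference(
    rng: np.random.Generator, n_genes: int, region: int = 10_000
) -> list[GeneLocus]:
    loci = []
    for g in range(n_genes):
        strand = str(rng.choice(["+", "-"]))
        n_iso = int(rng.integers(1, 3))
        txs = [
            random_transcript(
                rng, "chr1", strand, region=region, tid=f"ref{g}_{i}"
            )
            for i in range(n_iso)
        ]
        for tx in txs:
            tx.gene_id = f"refgene{g}"
        loci.append(GeneLocus(gene_id=f"refgene{g}", transcripts=txs))
    return loci
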