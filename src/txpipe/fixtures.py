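"""Self-contained synthetic inputs for every stage of the toolkit.

One seeded generator emits a coherent miniature study: a random genome, a
multi-exon reference annotation with biotypes, per-sample assembled GTFs
that embed exact reference copies plus planted novel features with known
truth labels, FASTQ reads with adapter contamination at a known rate,
HTSeq-style count files, and toy differential-expression tables in all
three tool dialects.

Planted features and their expected downstream classes:

* intergenic multi-exon loci                 → novel_lincRNA;
* opposite-strand loci overlapping a
  reference gene's exons                     → novel_antisense;
* one intergenic locus whose spliced
  sequence carries a long stop-free ORF
  spanning its splice junction               → novel_coding_candidate;
* single-exon transcripts present in a
  minority of samples                        → removed by filtering.

Default sizes mirror the validation studies the toolkit's statistics are
exercised on: 4 samples (two groups of two), a handful of reference genes
per chromosome, 3 planted lincRNAs and 2 antisense RNAs.  Everything is a
pure function of the seed; running twice produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gtf import write_gtf
from .models import Exon, GeneLocus, TranscriptModel
from .orf import CodingConfig, find_longest_orf
from .readprep import DEFAULT_ADAPTER

_BASES = np.array(list("ACGT"))
# sense codons only: sampling from these guarantees a stop-free run
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


class GenerationError(RuntimeError):
    pass


@dataclass
class FixtureConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len: int = 100_000
    n_ref_genes: int = 8
    n_novel_linc: int = 3
    n_novel_antisense: int = 2
    n_novel_coding: int = 1
    n_noise_single_exon: int = 5
    noise_present_in: int = 1
    n_samples: int = 4
    adapter_seq: str = DEFAULT_ADAPTER
    reads_per_sample: int = 100
    read_len: int = 75
    adapter_fraction: float = 0.3
    orf_codons: int = 120  # planted ORF length, above the 100-codon floor

    def __post_init__(self) -> None:
        counts = (
            self.n_ref_genes,
            self.n_novel_linc,
            self.n_novel_antisense,
            self.n_novel_coding,
            self.n_noise_single_exon,
        )
        if any(c < 0 for c in counts):
            raise ValueError("feature counts must be non-negative")
        if not (0 < self.noise_present_in <= self.n_samples):
            raise ValueError("noise_present_in must be in [1, n_samples]")

    @property
    def samples(self) -> list[str]:
        return [f"S{i:02d}" for i in range(1, self.n_samples + 1)]


@dataclass
class PlantedFeature:
    feature_id: str
    kind: str  # reference | novel_lincRNA | novel_antisense |
    #            novel_coding_candidate | noise_single_exon
    transcripts: list[TranscriptModel]
    present_in: list[str]
    biotype: str = ""

    @property
    def span(self) -> tuple[str, int, int, str]:
        tx = self.transcripts
        return (
            tx[0].chrom,
            min(t.start for t in tx),
            max(t.end for t in tx),
            tx[0].strand,
        )


@dataclass
class FixtureManifest:
    outdir: Path
    genome_fasta: Path
    reference_gtf: Path
    sample_gtfs: dict[str, Path]
    fastq_by_sample: dict[str, Path]
    counts_by_sample: dict[str, Path]
    de_tables: dict[str, Path]
    truth_tsv: Path
    features: list[PlantedFeature] = field(default_factory=list)
    reads_with_adapter: dict[str, int] = field(default_factory=dict)
    de_truth_log2fc: dict[str, float] = field(default_factory=dict)


def _random_exon_chain(
    rng: np.random.Generator,
    chrom: str,
    start: int,
    strand: str,
    n_exons: int,
    exon_len: tuple[int, int] = (150, 400),
    intron_len: tuple[int, int] = (100, 500),
) -> list[Exon]:
    exons = []
    pos = start
    for i in range(n_exons):
        length = int(rng.integers(*exon_len))
        exons.append(Exon(chrom, pos, pos + length - 1, strand))
        pos += length + int(rng.integers(*intron_len))
    return exons


def _spliced_write(genome: dict[str, np.ndarray], exons: list[Exon], seq: str) -> None:
    """Write a spliced sequence into the genome along an exon chain ('+')."""
    offset = 0
    for exon in exons:
        piece = seq[offset : offset + exon.length]
        genome[exon.chrom][exon.start - 1 : exon.start - 1 + len(piece)] = list(piece)
        offset += exon.length


def _spliced_read(genome: dict[str, np.ndarray], exons: list[Exon]) -> str:
    return "".join(
        "".join(genome[e.chrom][e.start - 1 : e.end]) for e in exons
    )


def make_fixture(cfg: FixtureConfig, outdir: str | Path) -> FixtureManifest:
    """Generate all fixture files under ``outdir``; returns the manifest."""
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = {
        f"chr{i + 1}": rng.choice(_BASES, size=cfg.chrom_len)
        for i in range(cfg.n_chroms)
    }
    chroms = sorted(genome)

    slot, gap = 4000, 2000
    n_features = (
        cfg.n_ref_genes
        + cfg.n_novel_linc
        + cfg.n_novel_coding
        + cfg.n_noise_single_exon
    )
    per_chrom = -(-n_features // cfg.n_chroms)
    if per_chrom * (slot + gap) + gap > cfg.chrom_len:
        raise GenerationError(
            f"chrom_len {cfg.chrom_len} too small for {n_features} features"
        )
    cursors = {c: 1000 for c in chroms}
    next_chrom = iter(chroms * (per_chrom + 1))

    def take_slot() -> tuple[str, int]:
        chrom = next(next_chrom)
        start = cursors[chrom]
        cursors[chrom] += slot + gap
        return chrom, start

    features: list[PlantedFeature] = []
    samples = cfg.samples
    coding_cfg = CodingConfig()

    # --- reference genes (1-2 isoforms, multi-exon) -----------------------
    ref_loci: list[GeneLocus] = []
    for g in range(cfg.n_ref_genes):
        chrom, start = take_slot()
        strand = str(rng.choice(["+", "-"]))
        gid = f"ENSG{g + 1:06d}"
        n_exons = int(rng.integers(3, 5))
        exons = _random_exon_chain(rng, chrom, start, strand, n_exons)
        txs = [TranscriptModel(f"{gid}.t1", gid, exons)]
        if rng.random() < 0.5 and n_exons >= 3:
            skipped = exons[:1] + exons[2:]  # skip one internal exon
            txs.append(TranscriptModel(f"{gid}.t2", gid, skipped))
        biotype = "protein_coding" if g % 3 else "lincRNA"
        ref_loci.append(
            GeneLocus(
                gene_id=gid,
                transcripts=txs,
                gene_name=f"GENE{g + 1:03d}",
                biotype=biotype,
            )
        )
        features.append(
            PlantedFeature(gid, "reference", txs, list(samples), biotype)
        )

    # --- antisense loci: opposite strand over a reference gene's exon -----
    for a in range(cfg.n_novel_antisense):
        host = ref_loci[a % len(ref_loci)]
        host_exon = host.transcripts[0].exons[0]
        strand = "-" if host.strand == "+" else "+"
        e1 = Exon(host_exon.chrom, host_exon.start - 50, host_exon.end + 20, strand)
        gap_after = host.transcripts[0].exons[1].start - host_exon.end
        e2_start = host_exon.end + 20 + max(40, gap_after // 3)
        e2 = Exon(host_exon.chrom, e2_start, e2_start + 120, strand)
        tx = TranscriptModel(f"AS{a + 1:03d}.t1", f"AS{a + 1:03d}", [e1, e2])
        features.append(
            PlantedFeature(
                f"AS{a + 1:03d}", "novel_antisense", [tx], list(samples)
            )
        )

    # --- intergenic lincRNA loci ------------------------------------------
    linc_features = []
    for l in range(cfg.n_novel_linc):
        chrom, start = take_slot()
        strand = str(rng.choice(["+", "-"]))
        exons = _random_exon_chain(
            rng, chrom, start, strand, int(rng.integers(2, 4))
        )
        tx = TranscriptModel(f"LINC{l + 1:03d}.t1", f"LINC{l + 1:03d}", [exons[0]] + exons[1:])
        feat = PlantedFeature(
            f"LINC{l + 1:03d}", "novel_lincRNA", [tx], list(samples)
        )
        features.append(feat)
        linc_features.append(feat)

    # --- one (or more) planted coding loci: long ORF across a junction ----
    for c in range(cfg.n_novel_coding):
        chrom, start = take_slot()
        e1 = Exon(chrom, start, start + 199, "+")
        e2 = Exon(chrom, start + 400, start + 400 + 249, "+")
        exons = [e1, e2]
        orf = "ATG" + "".join(
            rng.choice(_SENSE_CODONS, size=cfg.orf_codons - 1)
        ) + "TAA"
        spliced_len = sum(e.length for e in exons)
        pad_len = spliced_len - len(orf) - 10
        if pad_len < 0:
            raise GenerationError("planted ORF longer than its transcript")
        spliced = (
            "".join(rng.choice(_BASES, size=10)) + orf
            + "".join(rng.choice(_BASES, size=pad_len))
        )
        _spliced_write(genome, exons, spliced)
        tx = TranscriptModel(f"CODE{c + 1:03d}.t1", f"CODE{c + 1:03d}", exons)
        features.append(
            PlantedFeature(
                f"CODE{c + 1:03d}", "novel_coding_candidate", [tx], list(samples)
            )
        )

    # --- minority single-exon noise ---------------------------------------
    for s in range(cfg.n_noise_single_exon):
        chrom, start = take_slot()
        strand = str(rng.choice(["+", "-"]))
        exon = Exon(chrom, start, start + int(rng.integers(200, 400)), strand)
        tx = TranscriptModel(f"NOISE{s + 1:03d}.t1", f"NOISE{s + 1:03d}", [exon])
        present = sorted(
            rng.choice(samples, size=cfg.noise_present_in, replace=False)
        )
        features.append(
            PlantedFeature(f"NOISE{s + 1:03d}", "noise_single_exon", [tx], present)
        )

    # noncoding truth labels must hold for the generated sequence: reroll
    # the genome bases under any noncoding feature that drew a long ORF
    for feat in features:
        if feat.kind not in ("novel_lincRNA", "novel_antisense"):
            continue
        for tx in feat.transcripts:
            for attempt in range(10):
                seq = _spliced_read(genome, tx.exons)
                if tx.strand == "-":
                    comp = str.maketrans("ACGT", "TGCA")
                    seq = seq.translate(comp)[::-1]
                if not find_longest_orf(seq, coding_cfg).has_significant_orf:
                    break
                for e in tx.exons:
                    genome[e.chrom][e.start - 1 : e.end] = rng.choice(
                        _BASES, size=e.length
                    )
            else:
                raise GenerationError(
                    f"could not make {feat.feature_id} ORF-free"
                )

    # --- write genome ------------------------------------------------------
    genome_fasta = outdir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        for chrom in chroms:
            fh.write(f">{chrom}\n")
            seq = "".join(genome[chrom])
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    # --- write reference annotation ----------------------------------------
    reference_gtf = outdir / "reference.gtf"
    write_gtf(ref_loci, reference_gtf, source="reference")

    # --- per-sample assembled GTFs -----------------------------------------
    sample_gtfs: dict[str, Path] = {}
    for sample in samples:
        loci = []
        for feat in features:
            if sample not in feat.present_in:
                continue
            txs = []
            for tx in feat.transcripts:
                fpkm = round(float(rng.lognormal(2.0, 1.0)), 4)
                txs.append(
                    TranscriptModel(
                        transcript_id=f"{sample}.{tx.transcript_id}",
                        gene_id=f"{sample}.{tx.gene_id}",
                        exons=list(tx.exons),
                        fpkm_by_sample={sample: fpkm},
                        attributes={"FPKM": f"{fpkm:.4f}"},
                    )
                )
            loci.append(
                GeneLocus(gene_id=f"{sample}.{feat.feature_id}", transcripts=txs)
            )
        path = outdir / f"assembled_{sample}.gtf"
        write_gtf(loci, path, source="assembler")
        sample_gtfs[sample] = path

    # --- reads with adapter contamination ----------------------------------
    fastq_by_sample: dict[str, Path] = {}
    reads_with_adapter: dict[str, int] = {}
    for sample in samples:
        path = outdir / f"reads_{sample}.fastq"
        n_adapter = 0
        with open(path, "w") as fh:
            for r in range(cfg.reads_per_sample):
                chrom = chroms[int(rng.integers(len(chroms)))]
                pos = int(rng.integers(0, cfg.chrom_len - cfg.read_len - 1))
                seq = "".join(genome[chrom][pos : pos + cfg.read_len])
                if rng.random() < cfg.adapter_fraction:
                    insert_len = int(rng.integers(30, cfg.read_len - 5))
                    seq = (seq[:insert_len] + cfg.adapter_seq + seq)[: cfg.read_len]
                    n_adapter += 1
                qual = "I" * len(seq)
                fh.write(f"@{sample}_read{r + 1}\n{seq}\n+\n{qual}\n")
        fastq_by_sample[sample] = path
        reads_with_adapter[sample] = n_adapter

    # --- HTSeq-style count files -------------------------------------------
    counts_by_sample: dict[str, Path] = {}
    base_expr = {
        locus.gene_id: float(rng.uniform(50, 500)) for locus in ref_loci
    }
    group2 = set(samples[len(samples) // 2 :])
    de_truth: dict[str, float] = {}
    for i, locus in enumerate(ref_loci):
        de_truth[locus.gene_id] = float(rng.choice([-2.0, 0.0, 0.0, 2.0]))
    for sample in samples:
        path = outdir / f"counts_{sample}.tsv"
        with open(path, "w") as fh:
            for locus in ref_loci:
                mu = base_expr[locus.gene_id]
                if sample in group2:
                    mu *= 2.0 ** de_truth[locus.gene_id]
                fh.write(f"{locus.gene_id}\t{int(rng.poisson(mu))}\n")
            fh.write(f"__no_feature\t{int(rng.poisson(100))}\n")
        counts_by_sample[sample] = path

    # --- toy DE tables in the three dialects --------------------------------
    de_tables: dict[str, Path] = {}
    rows = []
    for locus in ref_loci:
        lfc = de_truth[locus.gene_id] + float(rng.normal(0, 0.15))
        p = float(rng.uniform(1e-6, 1e-3)) if de_truth[locus.gene_id] else float(
            rng.uniform(0.2, 0.9)
        )
        rows.append((locus, lfc, p))

    cuffdiff = outdir / "gene_exp.diff"
    with open(cuffdiff, "w") as fh:
        fh.write(
            "test_id\tgene_id\tgene\tlocus\tsample_1\tsample_2\tstatus\t"
            "value_1\tvalue_2\tlog2(fold_change)\ttest_stat\tp_value\t"
            "q_value\tsignificant\n"
        )
        for locus, lfc, p in rows:
            chrom, start, end, _ = locus.span
            v1 = base_expr[locus.gene_id]
            v2 = v1 * 2.0 ** lfc
            q = min(1.0, p * 2)
            sig = "yes" if q < 0.05 else "no"
            fh.write(
                f"{locus.gene_id}\t{locus.gene_id}\t{locus.gene_name}\t"
                f"{chrom}:{start}-{end}\tg1\tg2\tOK\t{v1:.4f}\t{v2:.4f}\t"
                f"{lfc:.4f}\t0.0\t{p:.6g}\t{q:.6g}\t{sig}\n"
            )
    de_tables["cuffdiff"] = cuffdiff

    for name, fc_col, p_col, q_col in (
        ("edger_glm", "logFC", "PValue", "FDR"),
        ("edger_exact", "logFC", "PValue", "FDR"),
        ("deseq2", "log2FoldChange", "pvalue", "padj"),
    ):
        path = outdir / f"{name}.tsv"
        with open(path, "w") as fh:
            if name == "deseq2":
                fh.write(f"gene_id\tbaseMean\t{fc_col}\tlfcSE\tstat\t{p_col}\t{q_col}\n")
            else:
                fh.write(f"gene_id\t{fc_col}\tlogCPM\t{p_col}\t{q_col}\n")
            for locus, lfc, p in rows:
                jitter = lfc + float(rng.normal(0, 0.05))
                q = min(1.0, p * 2)
                if name == "deseq2":
                    fh.write(
                        f"{locus.gene_id}\t{base_expr[locus.gene_id]:.2f}\t"
                        f"{jitter:.4f}\t0.1\t0.0\t{p:.6g}\t{q:.6g}\n"
                    )
                else:
                    fh.write(
                        f"{locus.gene_id}\t{jitter:.4f}\t5.0\t{p:.6g}\t{q:.6g}\n"
                    )
        de_tables[name] = path

    # --- truth manifest ------------------------------------------------------
    truth_tsv = outdir / "truth_manifest.tsv"
    with open(truth_tsv, "w") as fh:
        fh.write("feature_id\tkind\tchrom\tstart\tend\tstrand\tpresent_in\n")
        for feat in features:
            chrom, start, end, strand = feat.span
            fh.write(
                f"{feat.feature_id}\t{feat.kind}\t{chrom}\t{start}\t{end}\t"
                f"{strand}\t{','.join(feat.present_in)}\n"
            )

    return FixtureManifest(
        outdir=outdir,
        genome_fasta=genome_fasta,
        reference_gtf=reference_gtf,
        sample_gtfs=sample_gtfs,
        fastq_by_sample=fastq_by_sample,
        counts_by_sample=counts_by_sample,
        de_tables=de_tables,
        truth_tsv=truth_tsv,
        features=features,
        reads_with_adapter=reads_with_adapter,
        de_truth_log2fc=de_truth,
    )
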