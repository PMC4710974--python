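"""Synthetic dataset generator: determinism and truth recovery end to end."""

import filecmp

import pytest

from txpipe.fixtures import FixtureConfig, make_fixture
from txpipe.gtf import read_gtf
from txpipe.pipeline import run_discovery
from txpipe.readprep import TrimConfig, trim_fastq


def _overlaps(span_a, span_b):
    return (
        span_a[0] == span_b[0]
        and span_a[1] <= span_b[2]
        and span_b[1] <= span_a[2]
    )


def _run_pipeline(manifest):
    reference = read_gtf(manifest.reference_gtf)
    per_sample = {
        s: read_gtf(p, dialect="assembled", sample_id=s)
        for s, p in manifest.sample_gtfs.items()
    }
    return run_discovery(per_sample, reference, manifest.genome_fasta)


def test_same_seed_produces_byte_identical_outputs(tmp_path):
    m1 = make_fixture(FixtureConfig(seed=3), tmp_path / "a")
    m2 = make_fixture(FixtureConfig(seed=3), tmp_path / "b")
    names = [p.name for p in sorted(m1.outdir.iterdir()) if p.suffix != ".fai"]
    match, mismatch, errors = filecmp.cmpfiles(
        m1.outdir, m2.outdir, names, shallow=False
    )
    assert not mismatch and not errors and len(match) == len(names)


def test_truth_manifest_lists_every_planted_feature(fixture_manifest):
    cfg = FixtureConfig(seed=7)
    lines = fixture_manifest.truth_tsv.read_text().splitlines()[1:]
    assert len(lines) == (
        cfg.n_ref_genes
        + cfg.n_novel_linc
        + cfg.n_novel_antisense
        + cfg.n_novel_coding
        + cfg.n_noise_single_exon
    )


def test_noise_free_fixture_classes_recovered_exactly(tmp_path):
    """With no single-exon noise, every truth class is recovered."""
    cfg = FixtureConfig(seed=11, n_noise_single_exon=0)
    manifest = make_fixture(cfg, tmp_path / "clean")
    result = _run_pipeline(manifest)
    truth = [f for f in manifest.features if f.kind != "reference"]
    assert len(result.novel_loci) == len(truth)
    for feat in truth:
        hits = [
            l
            for l in result.novel_loci
            if _overlaps(l.span, feat.span) and l.span[3] == feat.span[3]
        ]
        assert len(hits) == 1, f"{feat.feature_id} not uniquely recovered"
        assert hits[0].locus_class == feat.kind
    # reference genes all come back annotated under their own ids
    ref_ids = {f.feature_id for f in manifest.features if f.kind == "reference"}
    assert {l.gene_id for l in result.annotated_loci} == ref_ids


def test_noisy_fixture_recovers_planted_loci_and_drops_noise(fixture_manifest):
    result = _run_pipeline(fixture_manifest)
    planted = [
        f
        for f in fixture_manifest.features
        if f.kind in ("novel_lincRNA", "novel_antisense")
    ]
    for feat in planted:
        hits = [
            l
            for l in result.novel_loci
            if _overlaps(l.span, feat.span) and l.span[3] == feat.span[3]
        ]
        assert len(hits) == 1
        assert hits[0].locus_class == feat.kind
    noise = [
        f for f in fixture_manifest.features if f.kind == "noise_single_exon"
    ]
    assert noise, "fixture should plant noise by default"
    for feat in noise:
        hits = [
            l
            for l in result.loci
            if _overlaps(l.span, feat.span) and l.span[3] == feat.span[3]
        ]
        assert hits == [], f"{feat.feature_id} survived filtering"
    removed = {r.item_id for r in result.filter_report if r.action == "removed"}
    assert len(removed) >= len(noise)


def test_planted_orf_locus_is_classified_coding(fixture_manifest):
    result = _run_pipeline(fixture_manifest)
    coding_truth = [
        f
        for f in fixture_manifest.features
        if f.kind == "novel_coding_candidate"
    ]
    assert coding_truth
    for feat in coding_truth:
        hits = [
            l
            for l in result.novel_loci
            if _overlaps(l.span, feat.span) and l.span[3] == feat.span[3]
        ]
        assert len(hits) == 1
        assert hits[0].locus_class == "novel_coding_candidate"


def test_adapter_contamination_rate_matches_trim_report(fixture_manifest):
    cfg = FixtureConfig(seed=7)
    sample = sorted(fixture_manifest.fastq_by_sample)[0]
    fastq = fixture_manifest.fastq_by_sample[sample]
    out = fixture_manifest.outdir / f"trimmed_{sample}.fastq"
    report = trim_fastq(fastq, out, TrimConfig(adapter_seq=cfg.adapter_seq))
    # every contaminated read must be trimmed; spurious short-prefix hits may
    # trim a few clean reads too, so the count bounds from below
    assert report.reads_processed == cfg.reads_per_sample
    assert report.reads_trimmed >= fixture_manifest.reads_with_adapter[sample]


def test_infeasible_layout_raises(tmp_path):
    with pytest.raises(Exception, match="too small"):
        make_fixture(
            FixtureConfig(seed=0, chrom_len=5000, n_ref_genes=20),
            tmp_path / "x",
        )
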