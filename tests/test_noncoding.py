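"""Novel-locus classing (coding candidate / lincRNA / antisense) and biotypes."""

import numpy as np
import pytest

from txpipe.classify import ClassCode
from txpipe.models import Exon, GeneLocus, TranscriptModel
from txpipe.noncoding import NotNovelError, annotate_biotypes, classify_novel_locus
from txpipe.orf import CodingConfig

from conftest import make_locus, make_tx, write_fasta

SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@pytest.fixture
def planted_genome(tmp_path):
    """chrZ carries a 150-codon ORF at 101..553; chrQ is ORF-free."""
    rng = np.random.default_rng(42)
    orf = "ATG" + "".join(rng.choice([c for c in SENSE if c != "ATG"], 149)) + "TAA"
    chrz = "".join(rng.choice(list("ACGT"), 100)) + orf + "".join(
        rng.choice(list("ACGT"), 100)
    )
    # stopping every few codons keeps chrQ free of long ORFs
    chrq = ("".join(rng.choice(SENSE, 3)) + "TAA") * 60
    path = tmp_path / "genome.fa"
    write_fasta(path, {"chrZ": chrz, "chrQ": chrq})
    return path


def test_locus_with_long_orf_isoform_is_coding_candidate(planted_genome):
    coding = make_tx("c1", [(101, 553)], chrom="chrZ")
    short = make_tx("c2", [(601, 650)], chrom="chrZ")
    locus = make_locus("L", [coding, short])
    codes = {
        "c1": ClassCode("intergenic", None),
        "c2": ClassCode("intergenic", None),
    }
    cls, orfs = classify_novel_locus(locus, codes, planted_genome)
    assert cls == "novel_coding_candidate"
    assert orfs["c1"].best_orf_length_codons == 150


def test_intergenic_locus_without_orf_is_lincRNA(planted_genome):
    tx = make_tx("t", [(1, 300), (400, 700)], chrom="chrQ")
    locus = make_locus("L", [tx])
    cls, _ = classify_novel_locus(locus, {"t": ClassCode("intergenic", None)},
                                  planted_genome)
    assert cls == "novel_lincRNA"


def test_antisense_code_without_orf_gives_novel_antisense(planted_genome):
    tx = make_tx("t", [(1, 300)], chrom="chrQ", strand="-")
    locus = make_locus("L", [tx])
    cls, _ = classify_novel_locus(locus, {"t": ClassCode("antisense", "HOST")},
                                  planted_genome)
    assert cls == "novel_antisense"


def test_external_coding_label_overrides_orf_rule(planted_genome):
    tx = make_tx("t", [(1, 120)], chrom="chrQ")
    locus = make_locus("L", [tx])
    codes = {"t": ClassCode("intergenic", None)}
    cls, _ = classify_novel_locus(
        locus, codes, planted_genome, external_labels={"t": "coding"}
    )
    assert cls == "novel_coding_candidate"


def test_locus_containing_known_transcript_is_rejected(planted_genome):
    tx = make_tx("t", [(1, 120)], chrom="chrQ")
    locus = make_locus("L", [tx])
    with pytest.raises(NotNovelError):
        classify_novel_locus(locus, {"t": ClassCode("equal", "G")}, planted_genome)


def test_raising_orf_threshold_never_adds_coding_candidates(planted_genome):
    tx = make_tx("t", [(101, 553)], chrom="chrZ")
    codes = {"t": ClassCode("intergenic", None)}
    candidates = []
    for threshold in (50, 150, 151):
        locus = make_locus("L", [make_tx("t", [(101, 553)], chrom="chrZ")])
        cls, _ = classify_novel_locus(
            locus, codes, planted_genome, CodingConfig(min_orf_codons=threshold)
        )
        candidates.append(cls == "novel_coding_candidate")
    assert candidates == [True, True, False]


def test_matched_loci_inherit_biotype_and_novel_loci_get_ordered_ids():
    ref = [
        make_locus(
            "ENSG1",
            [make_tx("r1", [(100, 200), (300, 400)], gene_id="ENSG1")],
            gene_name="Alpha",
            biotype="protein_coding",
        )
    ]
    matched = make_locus("m", [make_tx("mt", [(100, 200), (300, 400)])])
    novel_chr2 = make_locus(
        "n2", [make_tx("nt2", [(50, 150)], chrom="chr2")]
    )
    novel_chr1 = make_locus("n1", [make_tx("nt1", [(9000, 9100)])])
    codes = {
        "mt": ClassCode("equal", "ENSG1"),
        "nt1": ClassCode("intergenic", None),
        "nt2": ClassCode("intergenic", None),
    }
    out = annotate_biotypes(
        [matched, novel_chr2, novel_chr1],
        ref,
        codes,
        novel_classes={"n1": "novel_lincRNA", "n2": "novel_lincRNA"},
    )
    by_id = {l.gene_id: l for l in out}
    assert by_id["ENSG1"].biotype == "protein_coding"
    assert by_id["ENSG1"].gene_name == "Alpha"
    # (chrom, start) lexicographic: chr1:9000 before chr2:50
    assert by_id["NOVEL_LOC_000001"].span[0] == "chr1"
    assert by_id["NOVEL_LOC_000002"].span[0] == "chr2"
    assert by_id["NOVEL_LOC_000001"].biotype == "novel_lincRNA"


def test_every_locus_receives_exactly_one_class():
    ref = [
        make_locus(
            "ENSG1",
            [make_tx("r1", [(100, 200), (300, 400)], gene_id="ENSG1")],
            biotype="protein_coding",
        )
    ]
    matched = make_locus("m", [make_tx("mt", [(100, 200), (300, 400)])])
    novel = make_locus("n", [make_tx("nt", [(9000, 9100)])])
    codes = {"mt": ClassCode("equal", "ENSG1"), "nt": ClassCode("intergenic", None)}
    out = annotate_biotypes([matched, novel], ref, codes,
                            novel_classes={"n": "novel_antisense"})
    from txpipe.models import LOCUS_CLASSES

    assert len(out) == 2
    for locus in out:
        assert locus.locus_class in LOCUS_CLASSES
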