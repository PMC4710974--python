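"""Junction/common-exon template selection and primer picking."""

import numpy as np
import pytest

from txpipe.models import Exon
from txpipe.primers import (
    DesignFailure,
    JunctionKey,
    PrimerTarget,
    build_primer_target,
    common_exonic_region,
    common_junctions,
    pick_primers,
)
from txpipe.sequences import extract_sequence

from conftest import make_locus, make_tx, write_fasta
from oracles import common_junctions_oracle


def test_common_junctions_is_the_intersection():
    a = make_tx("a", [(100, 200), (300, 400), (500, 600)])  # J1, J2
    b = make_tx("b", [(100, 200), (300, 600)])  # J1 only
    got = common_junctions([a, b])
    assert [(j.donor, j.acceptor) for j in got] == [(200, 300)]


def test_identical_isoforms_share_all_junctions():
    a = make_tx("a", [(100, 200), (300, 400), (500, 600)])
    b = make_tx("b", [(100, 200), (300, 400), (500, 600)])
    assert [(j.donor, j.acceptor) for j in common_junctions([a, b])] == [
        (200, 300),
        (400, 500),
    ]


def test_single_exon_isoform_forces_empty_junction_set():
    a = make_tx("a", [(100, 200), (300, 400)])
    b = make_tx("b", [(120, 380)])
    assert common_junctions([a, b]) == []


def test_mixed_strand_isoforms_raise():
    a = make_tx("a", [(100, 200), (300, 400)], strand="+")
    b = make_tx("b", [(100, 200), (300, 400)], strand="-")
    with pytest.raises(ValueError):
        common_junctions([a, b])


def test_junction_intersection_matches_brute_force_on_random_genes():
    rng = np.random.default_rng(17)
    for _ in range(100):
        # isoforms drawn from one pool of exon boundaries on one gene
        bounds = sorted(rng.choice(np.arange(100, 4000, 10), 10, replace=False))
        exons = [(int(bounds[i]), int(bounds[i + 1]) - 2) for i in range(0, 10, 2)]
        isoforms = []
        for i in range(int(rng.integers(2, 5))):
            keep = sorted(
                rng.choice(5, size=int(rng.integers(2, 6)), replace=False)
            )
            isoforms.append(make_tx(f"i{i}", [exons[k] for k in keep]))
        got = {(j.donor, j.acceptor) for j in common_junctions(isoforms)}
        assert got == common_junctions_oracle(isoforms)
        # result is a subset of every isoform's junctions, order-invariant
        for tx in isoforms:
            assert got <= set(tx.introns)
        rev = {(j.donor, j.acceptor) for j in common_junctions(isoforms[::-1])}
        assert rev == got


def test_common_exonic_region_intersects_and_takes_longest():
    a = make_tx("a", [(100, 300)])
    b = make_tx("b", [(200, 400)])
    region = common_exonic_region([a, b])
    assert (region.start, region.end) == (200, 300)


def test_disjoint_isoforms_have_no_common_region():
    a = make_tx("a", [(100, 200)])
    b = make_tx("b", [(300, 400)])
    assert common_exonic_region([a, b]) is None


def test_identical_single_exon_isoforms_return_their_exon():
    txs = [make_tx(f"t{i}", [(50, 150)]) for i in range(3)]
    region = common_exonic_region(txs)
    assert (region.start, region.end) == (50, 150)


@pytest.fixture
def primer_genome(tmp_path):
    rng = np.random.default_rng(8)
    # balanced GC so candidate primers pass composition filters
    seq = "".join(rng.choice(list("ACGT"), size=3000))
    path = tmp_path / "pg.fa"
    write_fasta(path, {"chr1": seq})
    return path


def test_junction_target_arithmetic(primer_genome):
    # two isoforms share junction 400/601 with 200/300 bp exonic flanks
    a = make_tx("a", [(201, 400), (601, 900)])
    b = make_tx("b", [(201, 400), (601, 900), (1001, 1100)])
    gene = make_locus("G", [a, b])
    target = build_primer_target(gene, primer_genome, flank=150)
    assert isinstance(target, PrimerTarget)
    assert target.kind == "junction_spanning"
    assert len(target.template_seq) == 300
    assert target.junction_pos == 150


def test_junction_choice_maximizes_minimum_flank(primer_genome):
    # J1 flanks: 100/50; J2 flanks: 50/200 -> min 50 each; lengthen exon2
    # upstream of J2 to 300: J2 min flank = 200 > J1 min flank 50
    a = make_tx("a", [(101, 200), (251, 550), (751, 950)])
    gene = make_locus("G", [a])
    target = build_primer_target(gene, primer_genome, flank=400)
    # chosen junction must be (550, 751): min(300, 200) beats min(100, 300)
    up = a.exons[1].length
    assert target.junction_pos == min(400, up)


def test_fallback_to_common_exonic_region(primer_genome):
    a = make_tx("a", [(101, 700)])
    b = make_tx("b", [(151, 800)])
    gene = make_locus("G", [a, b])
    target = build_primer_target(gene, primer_genome)
    assert target.kind == "common_exonic"
    assert len(target.template_seq) == 550  # 151..700
    assert target.junction_pos is None


def test_no_junction_and_no_region_reports_failure(primer_genome):
    a = make_tx("a", [(101, 200)])
    b = make_tx("b", [(301, 400)])
    gene = make_locus("G", [a, b])
    result = build_primer_target(gene, primer_genome)
    assert isinstance(result, DesignFailure)


def test_minus_strand_template_is_transcript_oriented(primer_genome):
    a = make_tx("a", [(201, 400), (601, 900)], strand="-")
    gene = make_locus("G", [a])
    target = build_primer_target(gene, primer_genome, flank=150)
    expected = extract_sequence(
        primer_genome,
        [Exon("chr1", 251, 400, "-"), Exon("chr1", 601, 750, "-")],
    )
    assert target.template_seq == expected
    assert target.junction_pos == 150


def test_picked_primers_span_the_junction(primer_genome):
    a = make_tx("a", [(201, 400), (601, 900)])
    gene = make_locus("G", [a])
    target = build_primer_target(gene, primer_genome, flank=150)
    pair = pick_primers(target)
    assert not isinstance(pair, DesignFailure)
    left_end = pair.left_start + len(pair.left_seq) - 1
    right_start = pair.right_end - len(pair.right_seq) + 1
    assert left_end < target.junction_pos < right_start
    assert pair.product_size == pair.right_end - pair.left_start + 1
    assert target.template_seq[pair.left_start:].startswith(pair.left_seq)


def test_common_exonic_primers_stay_inside_template(primer_genome):
    a = make_tx("a", [(101, 700)])
    gene = make_locus("G", [a])
    target = build_primer_target(gene, primer_genome)
    pair = pick_primers(target)
    assert not isinstance(pair, DesignFailure)
    assert 0 <= pair.left_start < pair.right_end < len(target.template_seq)


def test_short_template_is_a_precondition_error():
    target = PrimerTarget("G", "common_exonic", "ACGT" * 10, None, 150)
    with pytest.raises(ValueError, match="template too short"):
        pick_primers(target)


def test_junction_key_requires_an_intron():
    with pytest.raises(ValueError):
        JunctionKey("chr1", 100, 101, "+")
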