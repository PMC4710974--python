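"""DE-table parsing, unification and fold-change concordance."""

import numpy as np
import pytest

from txpipe.de import (
    DialectError,
    build_unified_table,
    concordance,
    parse_de_output,
)

from conftest import make_locus, make_tx

CUFFDIFF_HEADER = (
    "test_id\tgene_id\tgene\tlocus\tsample_1\tsample_2\tstatus\t"
    "value_1\tvalue_2\tlog2(fold_change)\ttest_stat\tp_value\tq_value\t"
    "significant\n"
)


def _cuffdiff_file(tmp_path):
    rows = [
        ("g1", "A", "chr1:1-100", 10.0, 40.0, 2.0, 0.001, 0.004),
        ("g2", "B", "chr1:200-400", 5.0, 5.0, 0.0, 0.9, 0.95),
        ("g3", "C", "chr2:1-50", 8.0, 2.0, -2.0, 0.01, 0.03),
    ]
    path = tmp_path / "gene_exp.diff"
    with open(path, "w") as fh:
        fh.write(CUFFDIFF_HEADER)
        for gid, name, locus, v1, v2, lfc, p, q in rows:
            fh.write(
                f"{gid}\t{gid}\t{name}\t{locus}\tg1\tg2\tOK\t{v1}\t{v2}\t"
                f"{lfc}\t0\t{p}\t{q}\tyes\n"
            )
    return path


def test_cuffdiff_rows_parse_with_abundance(tmp_path):
    records = parse_de_output(_cuffdiff_file(tmp_path), dialect="cuffdiff")
    assert len(records) == 3
    rec = records[0]
    assert rec.method == "cuffdiff"
    assert rec.abundance_by_group == {"group_1": 10.0, "group_2": 40.0}
    assert rec.log2fc == 2.0 and rec.fdr == 0.004


def test_deseq2_na_padj_becomes_one_with_flag(tmp_path):
    path = tmp_path / "deseq2.tsv"
    path.write_text(
        "gene_id\tbaseMean\tlog2FoldChange\tlfcSE\tstat\tpvalue\tpadj\n"
        "g1\t100\t1.5\t0.1\t3.2\t0.001\t0.01\n"
        "g2\t2\t0.5\t0.4\t0.9\t0.4\tNA\n"
    )
    records = parse_de_output(path, dialect="deseq2")
    by_id = {r.gene_id: r for r in records}
    assert by_id["g2"].fdr == 1.0 and by_id["g2"].fdr_was_na
    assert not by_id["g1"].fdr_was_na


def test_wrong_dialect_raises_naming_the_missing_column(tmp_path):
    path = tmp_path / "edger.tsv"
    path.write_text("gene_id\tlogFC\tlogCPM\tPValue\tFDR\ng1\t1.0\t5\t0.01\t0.05\n")
    with pytest.raises(DialectError, match="log2FoldChange"):
        parse_de_output(path, dialect="deseq2")
    records = parse_de_output(path, dialect="edger", method="edgeR_exact")
    assert records[0].method == "edgeR_exact"


@pytest.fixture
def annotated_loci():
    return [
        make_locus("g1", [make_tx("t1", [(1, 100)], gene_id="g1")],
                   gene_name="A", biotype="protein_coding"),
        make_locus("g2", [make_tx("t2", [(200, 400)], gene_id="g2")],
                   gene_name="B", biotype="lincRNA"),
        make_locus("g3", [make_tx("t3", [(500, 700)], gene_id="g3")],
                   gene_name="C", biotype="protein_coding"),
    ]


def test_unified_table_annotates_sorts_and_selects_de_genes(tmp_path, annotated_loci):
    records = parse_de_output(_cuffdiff_file(tmp_path), dialect="cuffdiff")
    table, de_loci = build_unified_table(records, annotated_loci, alpha=0.05)
    assert list(table["gene_id"]) == ["g1", "g3", "g2"]  # by fdr then id
    assert table.loc[0, "biotype"] == "protein_coding"
    assert {l.gene_id for l in de_loci} == {"g1", "g3"}  # fdr < 0.05


def test_alpha_one_selects_every_resolvable_gene(tmp_path, annotated_loci):
    records = parse_de_output(_cuffdiff_file(tmp_path), dialect="cuffdiff")
    _, de_loci = build_unified_table(records, annotated_loci, alpha=1.01)
    assert len(de_loci) == 3


def test_de_gene_set_is_monotone_in_alpha(tmp_path, annotated_loci):
    records = parse_de_output(_cuffdiff_file(tmp_path), dialect="cuffdiff")
    previous: set = set()
    for alpha in (0.001, 0.01, 0.05, 0.5, 1.0):
        _, de_loci = build_unified_table(records, annotated_loci, alpha=alpha)
        current = {l.gene_id for l in de_loci}
        assert previous <= current
        previous = current


def test_empty_records_give_empty_table(annotated_loci):
    table, de_loci = build_unified_table([], annotated_loci)
    assert table.empty and de_loci == []


def test_concordance_identity_case():
    result = concordance([1, 2, 3], [1, 2, 3])
    assert result.r_squared == pytest.approx(1.0)
    assert result.sign_agreement == 1.0 and result.n == 3


def test_concordance_r_squared_is_r_times_r():
    x = [1.0, -2.0, 0.5, 3.0]
    y = [0.8, -1.0, 0.1, 2.0]
    result = concordance(x, y)
    assert result.r_squared == pytest.approx(result.r**2)


def test_concordance_symmetric_and_affine_invariant():
    rng = np.random.default_rng(6)
    for _ in range(25):
        x = rng.normal(size=8)
        y = x * 0.7 + rng.normal(scale=0.5, size=8)
        a = concordance(list(x), list(y))
        b = concordance(list(y), list(x))
        assert a.r_squared == pytest.approx(b.r_squared)
        scaled = concordance(list(2.5 * x + 1.0), list(y))
        assert scaled.r_squared == pytest.approx(a.r_squared)


def test_infinite_fold_changes_are_excluded():
    x = [1.0, 2.0, 3.0, float("inf")]
    y = [1.1, 2.2, 2.9, 5.0]
    assert concordance(x, y).n == 3


def test_zero_variance_is_an_error():
    with pytest.raises(ValueError, match="variance"):
        concordance([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
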