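"""Unify differential-expression tables from three tools into one format.

Cuffdiff, edgeR and DESeq2 emit differently-shaped result files; this
example parses each dialect, joins in gene metadata from the annotation,
and selects the genes below the FDR threshold for a DE-only GTF.
"""

from tempfile import TemporaryDirectory

from txpipe import (
    FixtureConfig,
    build_unified_table,
    make_fixture,
    parse_de_output,
    read_gtf,
    write_gtf,
)

with TemporaryDirectory() as tmp:
    manifest = make_fixture(FixtureConfig(seed=5), tmp)
    loci = read_gtf(manifest.reference_gtf)

    for dialect, method, path in (
        ("cuffdiff", None, manifest.de_tables["cuffdiff"]),
        ("edger", "edgeR_glm", manifest.de_tables["edger_glm"]),
        ("edger", "edgeR_exact", manifest.de_tables["edger_exact"]),
        ("deseq2", None, manifest.de_tables["deseq2"]),
    ):
        records = parse_de_output(path, dialect=dialect, method=method)
        table, de_loci = build_unified_table(records, loci, alpha=0.05)
        write_gtf(de_loci, f"{tmp}/de_{records[0].method}.gtf")
        print(f"{records[0].method:12s} {len(table)} genes, "
              f"{len(de_loci)} with FDR < 0.05")
    print()
    print(table.head(3).to_string(index=False))

# Every method's table carries the same columns (gene id, name, biotype,
# location, log2 fold change, p, FDR), so results rank and compare directly.
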