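"""Design junction-spanning qRT-PCR primers for annotated genes.

For each gene the template is a splice junction common to every isoform
(so the amplicon crosses an exon-exon boundary and cannot amplify genomic
DNA); genes without a common junction fall back to an exonic region shared
by all isoforms.
"""

from tempfile import TemporaryDirectory

from txpipe import FixtureConfig, make_fixture, read_gtf
from txpipe.primers import DesignFailure, design_for_genes

with TemporaryDirectory() as tmp:
    manifest = make_fixture(FixtureConfig(seed=3), tmp)
    genes = read_gtf(manifest.reference_gtf)
    rows = design_for_genes(genes, manifest.genome_fasta)

    print(f"{'gene':12s} {'template':18s} {'left primer':26s} "
          f"{'right primer':26s} product")
    for gene_id, kind, result in rows:
        if isinstance(result, DesignFailure):
            print(f"{gene_id:12s} {kind:18s} FAILED: {result.reason}")
        else:
            print(f"{gene_id:12s} {kind:18s} {result.left_seq:26s} "
                  f"{result.right_seq:26s} {result.product_size} bp")

# junction_spanning rows amplify across a splice junction present in every
# isoform; common_exonic rows are the fallback when no such junction exists
# (e.g. genes with a single-exon or exon-skipping isoform).
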