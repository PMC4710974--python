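"""Fold-change concordance between RNA-seq methods and qRT-PCR.

Uses the published validation panels (human hippocampus, mouse cortex, rat
liver) to compute, per differential-expression method, the coefficient of
determination r² against qRT-PCR and the fraction of genes whose direction
of change agrees.
"""

from txpipe import concordance
from txpipe.qpcr_tables import DATASETS, METHOD_COLUMNS, method_vs_qpcr

for dataset in DATASETS:
    print(dataset)
    for method in METHOD_COLUMNS:
        x, y = method_vs_qpcr(dataset, method)
        result = concordance(x, y)
        print(f"  {method:12s} n={result.n}  r2={result.r_squared:.2f}  "
              f"sign agreement={result.sign_agreement:.2f}")

# r2 close to 1 means the RNA-seq fold-change magnitudes track qRT-PCR;
# sign agreement 1.0 means every up/down call matches.  The rat panel's
# qRT-PCR column is on a different fold-change scale, so its r2 values are
# not comparable across methods at face value.
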