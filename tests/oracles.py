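"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives a result by the most direct method available —
exhaustive enumeration, regex scanning, naive substring search, pairwise
loops without index structures — and deliberately shares no code with the
implementation path it checks.
"""

from __future__ import annotations

import re

from txpipe.models import GeneLocus, TranscriptModel


# --- classification oracle -------------------------------------------------

def _exons_overlap(a, b) -> bool:
    return a.chrom == b.chrom and a.start <= b.end and b.start <= a.end


def classify_oracle(tx: TranscriptModel, reference: list[GeneLocus]) -> str:
    """All-pairs re-derivation of the five-way class code (no index)."""
    ref_txs = [(l, t) for l in reference for t in l.transcripts]

    for _, rt in ref_txs:
        if rt.intron_chain == tx.intron_chain:
            if tx.is_multi_exon:
                return "equal"
            if any(_exons_overlap(a, b) for a in tx.exons for b in rt.exons):
                return "equal"

    same_strand_overlap = False
    opposite_overlap = False
    shared_intron = False
    for _, rt in ref_txs:
        if rt.chrom != tx.chrom:
            continue
        overlap = any(
            _exons_overlap(a, b) for a in tx.exons for b in rt.exons
        )
        if rt.strand == tx.strand:
            same_strand_overlap = same_strand_overlap or overlap
            if set(rt.introns) & set(tx.introns):
                shared_intron = True
        else:
            opposite_overlap = opposite_overlap or overlap
    if shared_intron or same_strand_overlap:
        return "novel_isoform"

    for _, rt in ref_txs:
        if rt.chrom != tx.chrom or rt.strand != tx.strand:
            continue
        for donor, acceptor in rt.introns:
            if donor < tx.start and tx.end < acceptor:
                return "intronic"

    if opposite_overlap:
        return "antisense"
    return "intergenic"


# --- ORF oracle ------------------------------------------------------------

_ORF_RE = re.compile(r"(?=(ATG(?:[ACGT]{3})*?(?:TAA|TAG|TGA)))")


def longest_orf_oracle(seq: str) -> int:
    """Longest ATG..stop run (codons, stop excluded) by regex enumeration."""
    best = 0
    for m in _ORF_RE.finditer(seq.upper()):
        best = max(best, (len(m.group(1)) - 3) // 3)
    return best


# --- junction intersection oracle ------------------------------------------

def common_junctions_oracle(isoforms: list[TranscriptModel]) -> set[tuple[int, int]]:
    sets = [set(tx.introns) for tx in isoforms]
    common = sets[0]
    for s in sets[1:]:
        common = {j for j in common if j in s}
    return common


# --- trimming oracle --------------------------------------------------------

def naive_trim_oracle(seq: str, adapter: str, min_overlap: int) -> str:
    """Exact-match trimming: leftmost full occurrence, else the longest
    adapter prefix (>= min_overlap) that is a suffix of the read."""
    idx = seq.upper().find(adapter.upper())
    if idx >= 0:
        return seq[:idx]
    s = seq.upper()
    a = adapter.upper()
    for length in range(min(len(a), len(s)), min_overlap - 1, -1):
        if s.endswith(a[:length]):
            return seq[: len(seq) - length]
    return seq
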