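"""Open-reading-frame scanning as a coding-potential proxy.

A locus with at least one isoform carrying a long ORF (default >= 100
codons, ATG-initiated and stop-terminated) is treated as a candidate
protein-coding gene rather than a noncoding RNA.  Only the three
sense-strand frames of the spliced transcript sequence are scanned —
assembled transcripts are stranded, so the antisense frames belong to a
different (hypothetical) transcript.  The 100-codon floor is the classical
heuristic separating most annotated proteins from the short spurious ORFs
random sequence produces; it is configurable, and an external per-transcript
coding/noncoding call file can override the rule entirely (see
``noncoding.classify_novel_locus``).
"""

from __future__ import annotations

from dataclasses import dataclass

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_ALPHABET = frozenset("ACGTN")


@dataclass
class CodingConfig:
    min_orf_codons: int = 100
    require_start_codon: bool = True
    require_stop_codon: bool = True

    def __post_init__(self) -> None:
        if self.min_orf_codons < 1:
            raise ValueError("min_orf_codons must be >= 1")


@dataclass(frozen=True)
class ORFResult:
    """Longest ORF found in a spliced transcript sequence.

    ``best_orf_length_codons`` excludes the stop codon; ``start_offset`` is
    the 0-based position of the first base of the start codon in the spliced
    sequence, and ``frame`` is that offset mod 3.
    """

    best_orf_length_codons: int
    frame: int
    start_offset: int
    has_significant_orf: bool


def find_longest_orf(seq: str, cfg: CodingConfig | None = None) -> ORFResult:
    """Scan the three sense frames for the longest ORF.

    Codons containing N are treated as non-matching: they are neither start
    nor stop and break any ORF spanning them.  Ties on length resolve to the
    smallest start offset.
    """
    cfg = cfg or CodingConfig()
    seq = seq.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")

    best_len = 0
    best_start = -1
    n = len(seq)
    for frame in range(3):
        open_start = -1  # offset of current candidate ATG, -1 = closed
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if "N" in codon:
                open_start = -1  # broken run: no ORF may span this codon
                continue
            if open_start < 0:
                if codon == START_CODON or not cfg.require_start_codon:
                    open_start = pos
                if codon in STOP_CODONS:
                    open_start = -1
                    continue
            if open_start >= 0 and codon in STOP_CODONS:
                length = (pos - open_start) // 3
                if length > best_len or (
                    length == best_len and 0 <= open_start < best_start
                ):
                    best_len = length
                    best_start = open_start
                open_start = -1
        if open_start >= 0 and not cfg.require_stop_codon:
            length = (n - open_start - (n - open_start) % 3) // 3
            if length > best_len or (
                length == best_len and 0 <= open_start < best_start
            ):
                best_len = length
                best_start = open_start

    if best_len == 0:
        return ORFResult(0, 0, -1, False)
    return ORFResult(
        best_orf_length_codons=best_len,
        frame=best_start % 3,
        start_offset=best_start,
        has_significant_orf=best_len >= cfg.min_orf_codons,
    )
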