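"""Adapter trimming of FASTQ reads and insert-size arithmetic.

The trimmer uses 3'-adapter semantics (cutadapt-style): the read is searched
for the leftmost occurrence of the adapter, allowing a bounded mismatch
fraction, where an occurrence at the read's 3' end may be a partial adapter
prefix of at least ``min_overlap`` bases.  Everything from the match
position onward is removed from both sequence and qualities.

Insert-size statistics convert library metadata into aligner parameters:
with adapters of length a ligated on both fragment ends, the sequenced
insert averages fragment_mean − 2a (standard deviation unchanged, adapter
length being a constant), and the mate inner distance subtracts both read
lengths from the insert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

from ._io import PathLike, open_text

DEFAULT_ADAPTER = "AGATCGGAAGAGC"  # Illumina TruSeq universal adapter stem


@dataclass
class TrimConfig:
    adapter_seq: str = DEFAULT_ADAPTER
    min_overlap: int = 3
    max_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        if not self.adapter_seq:
            raise ValueError("adapter sequence must be nonempty")
        if not (1 <= self.min_overlap <= len(self.adapter_seq)):
            raise ValueError("min_overlap must be in [1, adapter length]")
        if not (0 <= self.max_mismatch_rate < 1):
            raise ValueError("max_mismatch_rate must be in [0, 1)")
        self.adapter_seq = self.adapter_seq.upper()


def _mismatches(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_read(seq: str, qual: str, cfg: Optional[TrimConfig] = None) -> tuple[str, str]:
    """Trim a 3' adapter occurrence from one read.

    Scans positions left to right; at each position the adapter (or, near
    the 3' end, its prefix of length >= min_overlap) is compared and the
    read truncated at the first position whose mismatch fraction is within
    budget.  The mismatch budget is floor(rate × compared length).
    """
    cfg = cfg or TrimConfig()
    if len(seq) != len(qual):
        raise ValueError("sequence and quality strings differ in length")
    seq_u = seq.upper()
    adapter = cfg.adapter_seq
    n = len(seq_u)
    for pos in range(0, n - cfg.min_overlap + 1):
        compare_len = min(len(adapter), n - pos)
        budget = int(cfg.max_mismatch_rate * compare_len)
        if _mismatches(seq_u[pos : pos + compare_len], adapter[:compare_len]) <= budget:
            return seq[:pos], qual[:pos]
    return seq, qual


@dataclass
class TrimReport:
    reads_processed: int = 0
    reads_trimmed: int = 0
    bases_trimmed: int = 0

    @property
    def mean_trimmed_bases(self) -> float:
        return self.bases_trimmed / self.reads_processed if self.reads_processed else 0.0


def _iter_fastq(path: PathLike) -> Iterator[tuple[str, str, str]]:
    """Yield (header, seq, qual) from a 4-line FASTQ (gz/bz2 accepted)."""
    with open_text(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not seq:
                raise ValueError("truncated FASTQ record")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record near {header!r}")
            yield header[1:], seq, qual


def trim_fastq(
    in_path: PathLike,
    out_path: PathLike,
    cfg: Optional[TrimConfig] = None,
) -> TrimReport:
    """Trim every read of a FASTQ file; returns a summary report."""
    cfg = cfg or TrimConfig()
    report = TrimReport()
    with open_text(out_path, "wt") as out:
        for name, seq, qual in _iter_fastq(in_path):
            tseq, tqual = trim_read(seq, qual, cfg)
            report.reads_processed += 1
            if len(tseq) < len(seq):
                report.reads_trimmed += 1
                report.bases_trimmed += len(seq) - len(tseq)
            out.write(f"@{name}\n{tseq}\n+\n{tqual}\n")
    return report


@dataclass(frozen=True)
class InsertStats:
    insert_mean: float
    insert_sd: float
    mate_inner_distance: float

    def __post_init__(self) -> None:
        if self.insert_mean <= 0:
            raise ValueError("insert mean must be positive")
        if self.insert_sd < 0:
            raise ValueError("insert sd must be non-negative")


def insert_stats(
    fragment_mean: float,
    fragment_sd: float,
    adapter_len: int,
    read_len: int,
) -> InsertStats:
    """Insert-size statistics from fragment-length library metadata.

    insert_mean = fragment_mean − 2 × adapter_len (adapters flank the
    fragment); insert_sd passes through; mate inner distance additionally
    subtracts both read lengths (it may be negative for overlapping mates).
    """
    if fragment_sd < 0 or adapter_len < 0 or read_len < 0:
        raise ValueError("negative library metadata")
    mean = fragment_mean - 2 * adapter_len
    if mean <= 0:
        raise ValueError(
            f"fragment mean {fragment_mean} too short for adapter length "
            f"{adapter_len} (insert would be {mean})"
        )
    return InsertStats(
        insert_mean=mean,
        insert_sd=fragment_sd,
        mate_inner_distance=mean - 2 * read_len,
    )
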