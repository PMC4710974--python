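"""Filters that remove likely-spurious transcripts and under-covered loci.

Two rules, applied after merging and classification:

* single-exon filtering — any transcript containing a splice junction is
  kept unconditionally; a single-exon transcript is kept only when it was
  observed in a strict majority of samples (> majority_fraction × n), and
  single-exon transcripts lying inside reference introns are dropped
  regardless of presence (pre-mRNA / intronic noise);
* coverage filtering — a locus enters differential-expression testing only
  when its total read count across samples meets a floor and its best
  per-sample abundance meets an FPKM floor.

Both filters emit a report row (transcript/locus id, action, reason) so
removals are auditable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from ._io import PathLike, open_text
from .classify import ClassCode
from .merge import SamplePresence
from .models import GeneLocus


@dataclass
class FilterConfig:
    """Thresholds for the transcript/locus filters.

    majority_fraction:
        fraction of samples a single-exon transcript must exceed (strict)
        to be retained; 0.5 means "a strict majority".
    min_locus_reads:
        minimum total read count, summed across all samples, for a locus
        to be tested for differential expression.
    min_fpkm:
        minimum of the per-sample maximum FPKM over the locus.
    """

    majority_fraction: float = 0.5
    min_locus_reads: int = 10
    min_fpkm: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.majority_fraction <= 1):
            raise ValueError("majority_fraction must lie in (0, 1]")
        if self.min_locus_reads < 0 or self.min_fpkm < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class FilterAction:
    item_id: str
    action: str  # kept / removed
    reason: str


def filter_single_exon(
    loci: list[GeneLocus],
    presence: Mapping[str, SamplePresence],
    cfg: Optional[FilterConfig] = None,
    codes: Optional[Mapping[str, ClassCode]] = None,
) -> tuple[list[GeneLocus], list[FilterAction]]:
    """Drop minority single-exon transcripts and intronic single-exon noise.

    Multi-exon (junction-containing) transcripts are never removed.  Loci
    whose transcripts are all removed disappear from the output.
    """
    cfg = cfg or FilterConfig()
    codes = codes or {}
    out: list[GeneLocus] = []
    report: list[FilterAction] = []
    for locus in loci:
        kept = []
        for tx in locus.transcripts:
            if tx.is_multi_exon:
                kept.append(tx)
                report.append(
                    FilterAction(tx.transcript_id, "kept", "has splice junction")
                )
                continue
            code = codes.get(tx.transcript_id)
            if code is not None and code.code == "intronic":
                report.append(
                    FilterAction(
                        tx.transcript_id, "removed", "single-exon intronic"
                    )
                )
                continue
            pres = presence.get(tx.transcript_id)
            if pres is None:
                raise KeyError(
                    f"no sample-presence record for {tx.transcript_id}"
                )
            threshold = cfg.majority_fraction * pres.n_samples
            if pres.n_present > threshold:
                kept.append(tx)
                report.append(
                    FilterAction(
                        tx.transcript_id,
                        "kept",
                        f"single-exon in {pres.n_present}/{pres.n_samples} samples",
                    )
                )
            else:
                reason = (
                    f"single-exon in {pres.n_present}/{pres.n_samples} samples"
                )
                if pres.n_present == threshold:
                    reason += " (tie fails strict majority)"
                report.append(FilterAction(tx.transcript_id, "removed", reason))
        if kept:
            out.append(
                GeneLocus(
                    gene_id=locus.gene_id,
                    transcripts=kept,
                    gene_name=locus.gene_name,
                    biotype=locus.biotype,
                    locus_class=locus.locus_class,
                )
            )
    return out, report


def filter_low_coverage(
    loci: list[GeneLocus],
    counts: Mapping[str, Sequence[float] | Mapping[str, float]],
    cfg: Optional[FilterConfig] = None,
) -> tuple[list[GeneLocus], list[FilterAction]]:
    """Keep loci with enough reads (and FPKM) for expression testing.

    ``counts`` maps gene_id to per-sample read counts (sequence or mapping);
    a locus with no entry is treated as zero-count.
    """
    cfg = cfg or FilterConfig()
    out: list[GeneLocus] = []
    report: list[FilterAction] = []
    for locus in loci:
        raw = counts.get(locus.gene_id, ())
        values = list(raw.values()) if isinstance(raw, Mapping) else list(raw)
        if any(v < 0 for v in values):
            raise ValueError(f"locus {locus.gene_id}: negative read count")
        total = sum(values)
        max_fpkm = max(
            (
                f
                for tx in locus.transcripts
                for f in tx.fpkm_by_sample.values()
            ),
            default=0.0,
        )
        if total >= cfg.min_locus_reads and max_fpkm >= cfg.min_fpkm:
            out.append(locus)
            report.append(FilterAction(locus.gene_id, "kept", f"{total:g} reads"))
        else:
            if total < cfg.min_locus_reads:
                reason = f"total reads {total:g} < {cfg.min_locus_reads}"
            else:
                reason = f"max FPKM {max_fpkm:g} < {cfg.min_fpkm:g}"
            report.append(FilterAction(locus.gene_id, "removed", reason))
    return out, report


def write_filter_report(report: list[FilterAction], path: PathLike) -> None:
    with open_text(path, "wt") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["item_id", "action", "reason"])
        for row in report:
            writer.writerow([row.item_id, row.action, row.reason])


def read_counts_file(path: PathLike) -> dict[str, float]:
    """Read an HTSeq-style two-column (gene_id TAB count) file.

    HTSeq's trailing ``__no_feature``-style summary rows are skipped.
    """
    counts: dict[str, float] = {}
    with open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene_id, value = line.split("\t")[:2]
            if gene_id.startswith("__"):
                continue
            counts[gene_id] = float(value)
    return counts


def combine_counts(
    per_sample: Mapping[str, Mapping[str, float]]
) -> dict[str, dict[str, float]]:
    """Pivot {sample: {gene: count}} into {gene: {sample: count}}."""
    combined: dict[str, dict[str, float]] = {}
    for sample in sorted(per_sample):
        for gene, value in per_sample[sample].items():
            combined.setdefault(gene, {})[sample] = value
    return combined
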