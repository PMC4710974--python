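"""End-to-end transcript filtering, classification and discovery.

Chains the post-assembly stages in their canonical order: merge per-sample
assemblies, classify each merged transcript against the reference, filter
single-exon noise (and optionally under-covered loci), split annotated from
novel loci, decide coding potential of novel loci, and attach biotypes and
stable ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from pyfaidx import Fasta

from ._io import PathLike
from .classify import ClassCode, classify_all
from .filtering import FilterAction, FilterConfig, filter_low_coverage, filter_single_exon
from .merge import SamplePresence, merge_samples
from .models import GeneLocus
from .noncoding import annotate_biotypes, classify_novel_locus
from .orf import CodingConfig, ORFResult


@dataclass
class DiscoveryResult:
    loci: list[GeneLocus]  # annotated + novel, with biotypes and stable ids
    codes: dict[str, ClassCode]  # per merged transcript
    presence: dict[str, SamplePresence]
    filter_report: list[FilterAction] = field(default_factory=list)
    orf_results: dict[str, dict[str, ORFResult]] = field(default_factory=dict)

    @property
    def novel_loci(self) -> list[GeneLocus]:
        return [l for l in self.loci if l.locus_class != "annotated"]

    @property
    def annotated_loci(self) -> list[GeneLocus]:
        return [l for l in self.loci if l.locus_class == "annotated"]


def run_discovery(
    per_sample: Mapping[str, list[GeneLocus]],
    reference: list[GeneLocus],
    genome: PathLike | Fasta,
    filter_cfg: Optional[FilterConfig] = None,
    coding_cfg: Optional[CodingConfig] = None,
    counts: Optional[Mapping[str, Mapping[str, float]]] = None,
    external_labels: Optional[Mapping[str, str]] = None,
) -> DiscoveryResult:
    """Run merge → classify → filter → noncoding discovery → annotation."""
    filter_cfg = filter_cfg or FilterConfig()
    coding_cfg = coding_cfg or CodingConfig()
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))

    merged, presence = merge_samples(dict(per_sample))
    codes = classify_all(merged, reference)
    filtered, report = filter_single_exon(merged, presence, filter_cfg, codes)
    if counts is not None:
        filtered, cov_report = filter_low_coverage(filtered, counts, filter_cfg)
        report = report + cov_report

    # decide coding potential for loci with no annotated transcript
    novel_classes: dict[str, str] = {}
    orf_results: dict[str, dict[str, ORFResult]] = {}
    for locus in filtered:
        tx_codes = [codes[tx.transcript_id] for tx in locus.transcripts]
        if any(c.code in ("equal", "novel_isoform") for c in tx_codes):
            continue
        cls, per_tx = classify_novel_locus(
            locus, codes, fasta, coding_cfg, external_labels
        )
        novel_classes[locus.gene_id] = cls
        orf_results[locus.gene_id] = per_tx

    annotated = annotate_biotypes(filtered, reference, codes, novel_classes)
    # re-key ORF results by the stable NOVEL_LOC ids
    stable_orfs: dict[str, dict[str, ORFResult]] = {}
    for locus in annotated:
        if locus.locus_class == "annotated":
            continue
        per_tx = {}
        for tx in locus.transcripts:
            for old in orf_results.values():
                if tx.transcript_id in old:
                    per_tx[tx.transcript_id] = old[tx.transcript_id]
        stable_orfs[locus.gene_id] = per_tx

    return DiscoveryResult(
        loci=annotated,
        codes=codes,
        presence=presence,
        filter_report=report,
        orf_results=stable_orfs,
    )
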