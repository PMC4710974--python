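"""GTF 2.2 reading and writing.

Reading accepts both reference annotations (ENSEMBL-style, with
``gene_biotype``/``gene_name`` attributes) and per-sample assembled
transcript files (Cufflinks-style, with an ``FPKM`` attribute).  Attribute
parsing delegates to gffutils' line parser; serialization is done here so
that output is deterministic: records ordered by (chrom, start,
transcript_id) and attributes ordered gene_id, transcript_id, then the
remaining keys alphabetically.  gzip/bzip2 inputs are decompressed
transparently.
"""

from __future__ import annotations

import logging
from typing import Optional

from gffutils.feature import feature_from_line

from ._io import PathLike, open_text
from .models import Exon, GeneLocus, TranscriptModel, ValidationError, group_into_loci

logger = logging.getLogger(__name__)

GTF_HEADER = "##gtf — txpipe output"

#: attribute keys that are materialised on the locus rather than kept
#: per-transcript verbatim
_LOCUS_KEYS = ("gene_id", "transcript_id")


class GtfParseError(ValueError):
    """A line could not be parsed as GTF; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def read_gtf(
    path: PathLike,
    dialect: str = "reference",
    sample_id: Optional[str] = None,
) -> list[GeneLocus]:
    """Read a GTF file into gene loci.

    Parameters
    ----------
    path:
        GTF file, optionally gzip/bzip2 compressed.
    dialect:
        ``"reference"`` for an annotation GTF or ``"assembled"`` for a
        Cufflinks-style per-sample assembly.  The only behavioural
        difference is that assembled files are expected to carry an FPKM
        attribute; its absence is logged.
    sample_id:
        Sample under which parsed FPKM values are stored in
        ``fpkm_by_sample`` (defaults to ``"sample"``).

    Only ``exon`` feature rows contribute coordinates; other feature types
    (``transcript``, ``CDS``, ...) are ignored.
    """
    if dialect not in ("reference", "assembled"):
        raise ValueError(f"unknown GTF dialect {dialect!r}")
    sample = sample_id or "sample"

    exons_by_tx: dict[str, list[Exon]] = {}
    meta_by_tx: dict[str, dict] = {}
    gene_names: dict[str, str] = {}
    biotypes: dict[str, str] = {}

    with open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    lineno, f"expected 9 tab-delimited fields, got {len(fields)}"
                )
            if fields[2] != "exon":
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(lineno, f"unparseable GTF line: {exc}") from exc
            attrs = {k: v[0] if v else "" for k, v in feat.attributes.items()}
            if "gene_id" not in attrs:
                raise GtfParseError(lineno, "record missing gene_id attribute")
            if "transcript_id" not in attrs:
                raise GtfParseError(lineno, "record missing transcript_id attribute")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GtfParseError(lineno, f"non-integer coordinate: {exc}") from exc
            if end < start:
                raise ValidationError(
                    f"line {lineno}: exon start {start} > end {end}"
                )
            try:
                exon = Exon(feat.seqid, start, end, feat.strand)
            except ValidationError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc

            tid = attrs["transcript_id"]
            exons_by_tx.setdefault(tid, []).append(exon)
            meta = meta_by_tx.setdefault(
                tid, {"gene_id": attrs["gene_id"], "attributes": {}}
            )
            for k, v in attrs.items():
                if k not in _LOCUS_KEYS:
                    meta["attributes"].setdefault(k, v)
            gid = attrs["gene_id"]
            if "gene_name" in attrs:
                gene_names.setdefault(gid, attrs["gene_name"])
            if "gene_biotype" in attrs:
                biotypes.setdefault(gid, attrs["gene_biotype"])

    transcripts = []
    for tid, exons in exons_by_tx.items():
        meta = meta_by_tx[tid]
        fpkm_by_sample: dict[str, float] = {}
        if "FPKM" in meta["attributes"]:
            try:
                fpkm_by_sample[sample] = float(meta["attributes"]["FPKM"])
            except ValueError:
                logger.warning("transcript %s: non-numeric FPKM attribute", tid)
                fpkm_by_sample[sample] = 0.0
        elif dialect == "assembled":
            logger.warning("transcript %s: no FPKM attribute, assuming 0.0", tid)
            fpkm_by_sample[sample] = 0.0
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=meta["gene_id"],
                exons=exons,
                fpkm_by_sample=fpkm_by_sample,
                attributes=dict(meta["attributes"]),
            )
        )

    return group_into_loci(transcripts, gene_name=gene_names, biotype=biotypes)


def _format_attributes(tx: TranscriptModel, locus: GeneLocus) -> str:
    attrs = dict(tx.attributes)
    if locus.gene_name and "gene_name" not in attrs:
        attrs["gene_name"] = locus.gene_name
    if locus.biotype not in ("", "novel") and "gene_biotype" not in attrs:
        attrs["gene_biotype"] = locus.biotype
    parts = [f'gene_id "{tx.gene_id}";', f'transcript_id "{tx.transcript_id}";']
    for key in sorted(attrs):
        parts.append(f'{key} "{attrs[key]}";')
    return " ".join(parts)


def write_gtf(
    loci: list[GeneLocus], path: PathLike, source: str = "txpipe"
) -> None:
    """Write loci as GTF 2.2, one row per exon, deterministically ordered."""
    rows = []
    for locus in loci:
        for tx in locus.transcripts:
            attr_str = _format_attributes(tx, locus)
            for exon in tx.exons:
                rows.append(
                    (
                        exon.chrom,
                        exon.start,
                        tx.transcript_id,
                        exon.end,
                        exon.strand,
                        attr_str,
                    )
                )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
    with open_text(path, "wt") as fh:
        fh.write(GTF_HEADER + "\n")
        for chrom, start, _tid, end, strand, attr_str in rows:
            fh.write(
                f"{chrom}\t{source}\texon\t{start}\t{end}\t.\t{strand}\t.\t{attr_str}\n"
            )
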