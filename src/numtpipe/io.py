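"""File-format boundaries: SAM, VCF 4.2, bedGraph, TSV, YAML.

pysam handles the alignment and variant formats; pandas handles the
tabular ones.  Internally all coordinates are 0-based half-open; VCF POS
is converted to/from 1-based at this boundary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .caller import AlignmentRecord
from .callset import UnifiedCallSet
from .genome import GenomeModel

__all__ = [
    "write_sam", "read_sam", "write_calls_vcf", "read_calls_vcf",
    "write_merged_vcf", "read_population_refs", "read_bedgraph",
    "load_config", "save_config",
]


def _sam_header(model: GenomeModel) -> pysam.AlignmentHeader:
    names = [*model.names, model.mt_name]
    lengths = [*model.lengths.tolist(), model.mt_length]
    return pysam.AlignmentHeader.from_references(names, lengths)


def write_sam(records: list[AlignmentRecord], path, model: GenomeModel) -> None:
    """Write alignment records as coordinate-sorted SAM with @SQ lines."""
    header = _sam_header(model)
    tid = {name: i for i, name in enumerate(header.references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header)
            a.query_name = rec.qname
            a.flag = (
                0x1
                | (0x10 if rec.is_reverse else 0)
                | (0x20 if not rec.is_reverse else 0)
                | (0x40 if not rec.is_reverse else 0x80)
            )
            a.reference_id = tid[rec.chrom]
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            clip = rec.read_len - rec.span
            a.cigarstring = f"{rec.span}M{clip}S" if clip > 0 else f"{rec.span}M"
            a.next_reference_id = tid[rec.mate_chrom]
            a.next_reference_start = rec.mate_pos
            out.write(a)


def read_sam(path) -> list[AlignmentRecord]:
    """Load SAM records into the caller's lightweight representation."""
    out = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for a in sam:
            if a.is_unmapped or a.reference_name is None:
                continue
            span = a.reference_length or 0
            out.append(
                AlignmentRecord(
                    qname=a.query_name, chrom=a.reference_name,
                    pos=a.reference_start, is_reverse=a.is_reverse,
                    mapq=a.mapping_quality,
                    read_len=a.infer_read_length() or span,
                    span=span,
                    mate_chrom=a.next_reference_name or "*",
                    mate_pos=a.next_reference_start,
                )
            )
    return out


_INFO_LINES = [
    ("MSTART", "1", "Integer", "Start of the inserted mtDNA segment (1-based)"),
    ("MEND", "1", "Integer", "End of the inserted mtDNA segment (1-based)"),
    ("MLEN", "1", "Integer", "Inferred insertion length in bp"),
    ("SR", "1", "Integer", "Supporting read pairs"),
    ("DP", "1", "Float", "Local read depth around the insertion point"),
    ("VAF", "1", "Float", "Variant allele fraction"),
    ("CIPOS", "2", "Integer", "Confidence interval around the breakpoint"),
]
_FILTER_LINES = [
    ("min_support", "Fewer than the required supporting read pairs"),
    ("min_depth", "Local depth below the required minimum"),
    ("min_qual", "Phred-scaled call quality below threshold"),
    ("one_sided", "Evidence from a single flank only"),
    ("anchor_lt150", "Less than 150 bp anchored to nuclear sequence"),
]


def _vcf_header(model: GenomeModel, samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in zip(
        [*model.names, model.mt_name], [*model.lengths.tolist(), model.mt_length]
    ):
        header.contigs.add(name, length=length)
    for ident, number, vtype, desc in _INFO_LINES:
        header.info.add(ident, number, vtype, desc)
    for ident, desc in _FILTER_LINES:
        header.filters.add(ident, None, None, desc)
    header.formats.add("GT", "1", "String", "Presence of the merged locus")
    for s in samples:
        header.add_sample(s)
    return header


def write_calls_vcf(calls: pd.DataFrame, path, model: GenomeModel) -> None:
    """One VCF 4.2 record per call row (columns as in ``calls_to_frame``)."""
    sample_ids = list(dict.fromkeys(calls.get("sample_id", pd.Series(["sample"]))))
    header = _vcf_header(model, sample_ids)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in calls.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=int(row.pos), stop=int(row.pos) + 1,
                alleles=("N", "<INS:MT>"),
            )
            rec.info["MSTART"] = int(row.mt_start) + 1
            rec.info["MEND"] = int(row.mt_end)
            rec.info["MLEN"] = int(row.length)
            if hasattr(row, "support"):
                rec.info["SR"] = int(row.support)
            if hasattr(row, "depth"):
                rec.info["DP"] = float(row.depth)
            rec.info["VAF"] = float(row.vaf)
            if hasattr(row, "ci_lo"):
                rec.info["CIPOS"] = (int(row.ci_lo) - int(row.pos),
                                     int(row.ci_hi) - int(row.pos))
            filt = getattr(row, "filter", "PASS")
            for f in str(filt).split(";"):
                rec.filter.add(f)
            sid = getattr(row, "sample_id", sample_ids[0])
            for s in sample_ids:
                rec.samples[s]["GT"] = (0, 1) if s == sid else (0, 0)
            out.write(rec)


def read_calls_vcf(path) -> pd.DataFrame:
    """Read a per-sample or merged call VCF back into a call table."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            carriers = [
                s for s in rec.samples
                if 1 in (rec.samples[s].get("GT") or ())
            ] or [None]
            filt = ";".join(rec.filter.keys()) or "PASS"
            for sid in carriers:
                rows.append(
                    dict(sample_id=sid, chrom=rec.contig, pos=rec.start,
                         mt_start=int(rec.info["MSTART"]) - 1,
                         mt_end=int(rec.info["MEND"]),
                         length=int(rec.info["MLEN"]),
                         support=int(rec.info.get("SR", 0)),
                         depth=float(rec.info.get("DP", 0.0)),
                         vaf=float(rec.info["VAF"]), filter=filt)
                )
    return pd.DataFrame(
        rows, columns=["sample_id", "chrom", "pos", "mt_start", "mt_end",
                       "length", "support", "depth", "vaf", "filter"],
    )


def write_merged_vcf(unified: UnifiedCallSet, path, model: GenomeModel) -> None:
    """Merged cohort loci with GT-style per-sample presence columns."""
    samples = list(unified.presence.columns)
    header = _vcf_header(model, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in unified.loci.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom, start=int(row.pos), stop=int(row.pos) + 1,
                alleles=("N", "<INS:MT>"),
            )
            rec.info["SR"] = int(row.n_members)
            rec.info["VAF"] = 0.0
            rec.info["MSTART"] = 1
            rec.info["MEND"] = 1
            rec.info["MLEN"] = 0
            present = unified.presence.loc[row.locus_id]
            for s in samples:
                rec.samples[s]["GT"] = (0, 1) if bool(present[s]) else (0, 0)
            out.write(rec)


def read_population_refs(path) -> pd.DataFrame:
    """Population Numt reference: VCF (POS 1-based) or TSV (chrom, pos, id).

    TSV positions are taken as 0-based breakpoints; VCF POS is converted.
    """
    path = Path(path)
    if path.suffix == ".vcf" or str(path).endswith(".vcf.gz"):
        rows = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                rows.append(dict(chrom=rec.contig, pos=rec.start,
                                 id=rec.id or f"ref_{len(rows)}"))
        return pd.DataFrame(rows, columns=["chrom", "pos", "id"])
    df = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :3]
    df.columns = ["chrom", "pos", "id"]
    return df


def read_bedgraph(path, model: GenomeModel) -> dict[str, np.ndarray]:
    """Expand a bedGraph coverage file into per-base arrays per contig."""
    lengths = {**model.chromosomes, model.mt_name: model.mt_length}
    tracks = {c: np.zeros(l, dtype=np.float64) for c, l in lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.chrom in tracks:
            tracks[row.chrom][int(row.start):int(row.end)] = float(row.value)
    return tracks


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
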