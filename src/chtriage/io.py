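"""Readers and writers for the tabular formats the pipeline touches.

Call tables come in two dialects: VCF 4.2 with per-sample allele depths
(read through cyvcf2; multi-allelic records are split into one record
per alternate allele) and a minimal TSV dialect with columns
``chrom pos ref alt depth alt_reads`` (1-based positions).  Blacklist
regions are BED (0-based half-open, converted at this boundary).
Annotations, the actionable-variant knowledge base, and classified
output are keyed TSVs.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .model import (
    AlleleCounts,
    Annotation,
    ClassifiedVariant,
    Clinvar,
    Consequence,
    DEFAULT_ANNOTATION,
    Label,
    VariantKey,
)

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_reads"]
ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "maf_gnomad",
    "maf_exac", "in_dbsnp", "in_cosmic", "is_hla", "in_blacklist", "clinvar",
]
CLASSIFIED_COLUMNS = [
    "patient_id", "chrom", "pos", "ref", "alt", "label", "p_value",
    "odds_ratio", "reasons",
]
MISSING = "."


def _parse_error(path, lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_calls(path, format: Optional[str] = None) -> list[tuple[VariantKey, AlleleCounts]]:
    """Read one sample's calls from a VCF or call-table TSV.

    ``format`` is ``"vcf"`` or ``"tsv"``; when omitted it is inferred
    from the file extension.  Multi-allelic VCF records yield one
    record per alternate allele, each with that allele's alt-read count
    and the summed allele depths as the site depth.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if ".vcf" in path.suffixes else "tsv"
    if format == "vcf":
        return _read_calls_vcf(path)
    if format == "tsv":
        return _read_calls_tsv(path)
    raise ValueError(f"unknown call format {format!r}")


def _read_calls_tsv(path: Path) -> list[tuple[VariantKey, AlleleCounts]]:
    out: list[tuple[VariantKey, AlleleCounts]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["chrom", "pos"]:
                continue  # optional header
            if len(fields) != len(CALL_COLUMNS):
                raise _parse_error(path, lineno, f"expected {len(CALL_COLUMNS)} columns, got {len(fields)}")
            chrom, pos_s, ref, alt, depth_s, alt_s = fields
            try:
                key = VariantKey(chrom, int(pos_s), ref, alt)
                counts = AlleleCounts(int(depth_s), int(alt_s))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
            out.append((key, counts))
    return out


def _read_calls_vcf(path: Path) -> list[tuple[VariantKey, AlleleCounts]]:
    from cyvcf2 import VCF

    out: list[tuple[VariantKey, AlleleCounts]] = []
    vcf = VCF(str(path))
    try:
        if len(vcf.samples) != 1:
            raise ValueError(f"{path}: expected exactly one sample, found {len(vcf.samples)}")
        for rec in vcf:
            ad = rec.format("AD")
            if ad is None:
                raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} lacks FORMAT/AD allele depths")
            depths = [int(x) for x in ad[0] if int(x) >= 0]
            depth = sum(depths)
            for i, alt in enumerate(rec.ALT):
                alt_reads = depths[i + 1] if i + 1 < len(depths) else 0
                if alt_reads > depth:
                    raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} has alt_reads > depth")
                out.append((
                    VariantKey(rec.CHROM, rec.POS, rec.REF, alt),
                    AlleleCounts(depth, alt_reads),
                ))
    finally:
        vcf.close()
    return out


class Blacklist:
    """Interval-set membership for blacklist regions.

    Built from BED (0-based half-open); a 1-based variant position p is
    blacklisted iff p-1 falls inside an interval on the same chromosome.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"BED interval start ({start}) must be < end ({end})")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def __contains__(self, variant: VariantKey) -> bool:
        tree = self._trees.get(variant.chrom)
        return bool(tree is not None and tree.overlaps_point(variant.pos - 1))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())


def read_blacklist(path) -> Blacklist:
    bl = Blacklist()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, "BED line needs >= 3 columns")
            try:
                bl.add(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
    return bl


class AnnotationMap:
    """VariantKey -> Annotation with a default for unknown variants."""

    def __init__(self, mapping: Optional[dict[VariantKey, Annotation]] = None) -> None:
        self._map = dict(mapping or {})

    def __getitem__(self, key: VariantKey) -> Annotation:
        return self._map.get(key, DEFAULT_ANNOTATION)

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(self._map)

    def items(self):
        return self._map.items()


def _parse_optional_float(s: str) -> Optional[float]:
    return None if s in (MISSING, "", "NA", "nan") else float(s)


def _fmt_optional(v: Optional[float]) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return MISSING
    return repr(v)


_BOOL = {"True": True, "False": False, "1": True, "0": False,
         "true": True, "false": False}


def read_annotations(path) -> AnnotationMap:
    mapping: dict[VariantKey, Annotation] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(ANNOTATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
                ann = Annotation(
                    gene=row["gene"],
                    consequence=Consequence(row["consequence"]),
                    maf_gnomad=_parse_optional_float(row["maf_gnomad"]),
                    maf_exac=_parse_optional_float(row["maf_exac"]),
                    in_dbsnp=_BOOL[row["in_dbsnp"]],
                    in_cosmic=_BOOL[row["in_cosmic"]],
                    is_hla=_BOOL[row["is_hla"]],
                    in_blacklist=_BOOL[row["in_blacklist"]],
                    clinvar=Clinvar(row["clinvar"]),
                )
            except (ValueError, KeyError) as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
            if key in mapping and mapping[key] != ann:
                raise _parse_error(path, lineno, f"conflicting duplicate annotation for {key}")
            mapping[key] = ann
    return AnnotationMap(mapping)


def write_annotations(path, mapping: AnnotationMap | dict[VariantKey, Annotation]) -> None:
    items = mapping.items() if hasattr(mapping, "items") else mapping
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for key, ann in sorted(items):
            w.writerow([
                key.chrom, key.pos, key.ref, key.alt, ann.gene,
                ann.consequence.value, _fmt_optional(ann.maf_gnomad),
                _fmt_optional(ann.maf_exac), ann.in_dbsnp, ann.in_cosmic,
                ann.is_hla, ann.in_blacklist, ann.clinvar.value,
            ])


def read_knowledge_base(path) -> dict[VariantKey, str]:
    """Actionable-variant knowledge base: VariantKey -> assertion text."""
    kb: dict[VariantKey, str] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt"}
        if not required <= set(reader.fieldnames or []):
            raise ValueError(f"{path}: knowledge base needs columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
            assertion = row.get("assertion") or row.get("drug") or ""
            if key in kb and kb[key] != assertion:
                raise _parse_error(path, lineno, f"conflicting duplicate knowledge-base row for {key}")
            kb[key] = assertion
    return kb


def write_classified(path, records: Iterable[ClassifiedVariant]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLASSIFIED_COLUMNS)
        for r in records:
            w.writerow([
                r.patient_id, r.variant.chrom, r.variant.pos, r.variant.ref,
                r.variant.alt, r.label.value, _fmt_optional(r.p_value),
                _fmt_optional(r.odds_ratio), ";".join(r.reasons) or MISSING,
            ])


def read_classified(path) -> list[ClassifiedVariant]:
    out: list[ClassifiedVariant] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                odds = row["odds_ratio"]
                out.append(ClassifiedVariant(
                    patient_id=row["patient_id"],
                    variant=VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                    label=Label(row["label"]),
                    p_value=_parse_optional_float(row["p_value"]),
                    odds_ratio=math.inf if odds == "inf" else _parse_optional_float(odds),
                    reasons=tuple(row["reasons"].split(";")) if row["reasons"] != MISSING else (),
                ))
            except (ValueError, KeyError) as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
    return out


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; '#' comments and blanks ignored."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split("\t")[0])
    return genes


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> genes...; name -> genes."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _parse_error(path, lineno, "GMT line needs name, description and >=1 gene")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets
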