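"""Domain types shared by every stage of the CH-triage pipeline.

The pipeline distinguishes three biological origins for a variant seen in
plasma cell-free DNA (cfDNA): tumor-derived somatic mutations, inherited
germline variants, and clonal hematopoiesis (CH) — somatic mutations of
hematopoietic stem cells whose DNA appears in both the white-blood-cell
fraction (PBL) and plasma cfDNA at matched allele fractions.  All
coordinates are 1-based (VCF convention); BED input is converted at the
boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic position plus ref/alt alleles identifying one mutation."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name in ("ref", "alt"):
            allele = getattr(self, name)
            if not allele or any(b not in "ACGT" for b in allele):
                raise ValueError(f"{name} must be a non-empty A/C/G/T string, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)


@dataclass(frozen=True)
class AlleleCounts:
    """Total depth and variant-supporting read count at one site."""

    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise ValueError("depth and alt_reads must be non-negative")
        if self.alt_reads > self.depth:
            raise ValueError(
                f"alt_reads ({self.alt_reads}) exceeds depth ({self.depth})"
            )

    @property
    def ref_reads(self) -> int:
        return self.depth - self.alt_reads

    @property
    def vaf(self) -> float:
        """Variant allele fraction; only defined for depth > 0."""
        if self.depth == 0:
            raise ZeroDivisionError("VAF undefined at zero depth")
        return self.alt_reads / self.depth


@dataclass(frozen=True)
class PairedObservation:
    """Per-compartment counts for one variant in one patient.

    ``None`` for a compartment means the variant was not called there —
    a different state from "called with 0 alt reads".  cfDNA is the
    anchoring compartment and is always present.
    """

    variant: VariantKey
    cfdna: AlleleCounts
    pbl: Optional[AlleleCounts] = None
    tumor: Optional[AlleleCounts] = None


class Consequence(str, enum.Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    OTHER = "other"


class Clinvar(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    OTHER = "other"
    NONE = "none"


@dataclass(frozen=True)
class Annotation:
    """Per-variant annotation consumed by the triage filters.

    Absent population MAFs are treated as 0 by the filters: a variant
    unseen in gnomAD/ExAC is not a common polymorphism.
    """

    gene: str = ""
    consequence: Consequence = Consequence.OTHER
    maf_gnomad: Optional[float] = None
    maf_exac: Optional[float] = None
    in_dbsnp: bool = False
    in_cosmic: bool = False
    is_hla: bool = False
    in_blacklist: bool = False
    clinvar: Clinvar = Clinvar.NONE

    def __post_init__(self) -> None:
        for name in ("maf_gnomad", "maf_exac"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")

    @property
    def max_pop_maf(self) -> float:
        return max(self.maf_gnomad or 0.0, self.maf_exac or 0.0)


DEFAULT_ANNOTATION = Annotation()


@dataclass
class Patient:
    patient_id: str
    cancer_type: str
    age: int
    observations: list[PairedObservation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be >= 0")


@dataclass(frozen=True)
class Thresholds:
    """Filter thresholds of the triage decision procedure.

    Defaults follow the published pipeline: somatic calls need >=100x
    depth, >=2 alt reads, VAF >= 0.3% and population MAF <= 0.2%;
    germline calls need >=30x PBL depth and PBL VAF >= 20%; CH candidates
    need Fisher p >= 0.05 with sample odds ratio strictly inside
    (0.5, 1.5); recurrent candidates with carrier ratio > 0.25% are
    dropped cohort-wide.
    """

    somatic_min_depth: int = 100
    min_alt_reads: int = 2
    somatic_min_vaf: float = 0.003
    max_pop_maf: float = 0.002
    germline_min_depth: int = 30
    germline_min_vaf: float = 0.20
    ch_min_p: float = 0.05
    ch_or_low: float = 0.5
    ch_or_high: float = 1.5
    carrier_ratio_max: float = 0.0025

    def __post_init__(self) -> None:
        if not 0 < self.ch_or_low < 1 < self.ch_or_high:
            raise ValueError("require 0 < ch_or_low < 1 < ch_or_high")
        for name in ("somatic_min_vaf", "max_pop_maf", "germline_min_vaf", "ch_min_p",
                     "carrier_ratio_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


class Label(str, enum.Enum):
    SOMATIC = "SOMATIC"
    GERMLINE_PATHOGENIC = "GERMLINE_PATHOGENIC"
    CANDIDATE_CH = "CANDIDATE_CH"
    CH = "CH"
    DISCORDANT_DISCARD = "DISCORDANT_DISCARD"
    FILTERED = "FILTERED"


@dataclass(frozen=True)
class ClassifiedVariant:
    """Triage outcome for one (patient, variant) pair.

    ``p_value`` and ``odds_ratio`` are present exactly when the
    cfDNA-vs-PBL Fisher test was performed (the low-VAF PBL branch).
    ``reasons`` records the ordered rule identifiers that fired and is
    never empty for FILTERED or DISCORDANT_DISCARD records.
    """

    patient_id: str
    variant: VariantKey
    label: Label
    p_value: Optional[float] = None
    odds_ratio: Optional[float] = None
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label in (Label.FILTERED, Label.DISCORDANT_DISCARD) and not self.reasons:
            raise ValueError(f"{self.label.value} records require a non-empty reasons list")
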