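"""Synthetic paired-compartment cohorts with known ground truth.

The generator emulates the statistical structure the triage assumes:
every planted variant has a true allele fraction per compartment, the
sequencer draws a Poisson depth and a binomial alt-read count on top of
a base error rate, and a variant is "called" in a compartment iff at
least one alt read was observed.  Germline variants sit near 50% VAF in
both blood compartments; CH variants share one low VAF between PBL and
cfDNA (the null hypothesis of the concordance test); tumor-derived
somatic variants have true PBL VAF 0 and only error reads there;
recurrent artifacts are CH-like variants planted into a fixed fraction
of CH carriers so the carrier-ratio filter has something to catch.
CH prevalence rises logistically with age, calibrated to climb from
roughly a quarter of patients at 40 to about 70% above 90.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationMap, write_annotations
from .model import (
    AlleleCounts,
    Annotation,
    ClassifiedVariant,
    Clinvar,
    Consequence,
    Label,
    PairedObservation,
    Patient,
    VariantKey,
)

CANCER_TYPES = (
    "BRCA", "CESC", "CHOL", "COAD", "ESCA", "HNSC", "KICH", "LIHC", "LUAD",
    "LUSC", "NASO", "NSCLC", "OV", "PAAD", "PRAD", "READ", "SCL", "STAD",
)

# Hot-gene weights for CH concentrate the signal the way aging blood does:
# epigenetic modifiers first, then DNA-damage and splicing genes.
CH_GENE_WEIGHTS = {
    "DNMT3A": 0.29, "TET2": 0.11, "ASXL1": 0.04, "TP53": 0.05, "ATM": 0.04,
    "CHEK2": 0.03, "SF3B1": 0.03, "NOTCH1": 0.03, "CREBBP": 0.03,
    "NOTCH2": 0.03, "CIC": 0.03, "ARID1B": 0.03, "NF1": 0.03, "EP300": 0.03,
    "SPEN": 0.03, "NOTCH3": 0.03, "KMT2D": 0.04, "FAT1": 0.04, "CBL": 0.03,
    "RAD21": 0.03,
}
GERMLINE_GENES = ("BRCA1", "BRCA2", "MLH1", "MSH2", "MSH6", "PMS2", "ATM",
                  "CHEK2", "PALB2", "TP53")
SOMATIC_GENES = ("TP53", "KRAS", "EGFR", "PIK3CA", "APC", "NRAS", "ERBB2",
                 "BRAF", "PTEN", "FGFR3", "IDH1", "KIT")

_CONSEQUENCES = {
    "CH": ([Consequence.MISSENSE, Consequence.NONSENSE, Consequence.FRAMESHIFT_INDEL,
            Consequence.SPLICE], [0.50, 0.20, 0.25, 0.05]),
    "germline": ([Consequence.MISSENSE, Consequence.NONSENSE,
                  Consequence.FRAMESHIFT_INDEL], [0.50, 0.25, 0.25]),
    "somatic": ([Consequence.MISSENSE, Consequence.NONSENSE,
                 Consequence.FRAMESHIFT_INDEL], [0.70, 0.15, 0.15]),
    "artifact": ([Consequence.MISSENSE], [1.0]),
}


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the study conditions."""

    n_patients: int = 1000
    seed: int = 0
    # ages uniform on [age_min, age_max]
    age_min: int = 30
    age_max: int = 90
    # P(>=1 CH | age) = logistic(prev_intercept + prev_slope * age)
    prev_intercept: float = -2.25
    prev_slope: float = 0.0344
    # per-carrier CH count: P(1..4)
    ch_count_probs: tuple[float, ...] = (0.60, 0.25, 0.10, 0.05)
    # CH VAF log-uniform on [ch_vaf_min, ch_vaf_max)
    ch_vaf_min: float = 0.005
    ch_vaf_max: float = 0.20
    n_germline: int = 2
    germline_beta: tuple[float, float] = (50.0, 50.0)
    germline_pathogenic_prob: float = 0.3
    n_somatic: int = 3
    somatic_vaf_min: float = 0.003
    somatic_vaf_max: float = 0.30
    tumor_vaf_multiplier: float = 10.0
    tumor_vaf_cap: float = 0.5
    # mean sequencing depths (Poisson)
    depth_pbl: float = 200.0
    depth_cfdna: float = 1000.0
    depth_tumor: float = 1000.0
    error_rate: float = 0.001
    # recurrent artifacts: each planted into this fraction of CH carriers
    n_artifact_variants: int = 3
    artifact_carrier_fraction: float = 0.02
    artifact_vaf: float = 0.05
    tumor_sample_fraction: float = 0.3
    # robustness knobs, off by default
    overdispersion_rho: float = 0.0
    ch_compartment_shift: float = 0.0

    def validate(self) -> None:
        checks = {
            "n_patients": self.n_patients >= 0,
            "age_min": 0 <= self.age_min <= self.age_max,
            "ch_count_probs": abs(sum(self.ch_count_probs) - 1.0) < 1e-9
                              and all(p >= 0 for p in self.ch_count_probs),
            "ch_vaf_min": 0 < self.ch_vaf_min < self.ch_vaf_max <= 1,
            "somatic_vaf_min": 0 < self.somatic_vaf_min < self.somatic_vaf_max <= 1,
            "error_rate": 0 <= self.error_rate < 1,
            "artifact_carrier_fraction": 0 <= self.artifact_carrier_fraction <= 1,
            "artifact_vaf": 0 < self.artifact_vaf < 1,
            "tumor_sample_fraction": 0 <= self.tumor_sample_fraction <= 1,
            "germline_pathogenic_prob": 0 <= self.germline_pathogenic_prob <= 1,
            "overdispersion_rho": 0 <= self.overdispersion_rho < 1,
            "depth_pbl": self.depth_pbl > 0,
            "depth_cfdna": self.depth_cfdna > 0,
            "depth_tumor": self.depth_tumor > 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid SimulationConfig field: {name}")


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    patients: list[Patient]
    calls: dict[str, dict[str, list[tuple[VariantKey, AlleleCounts]]]]
    annotations: AnnotationMap
    truth: pd.DataFrame


class _VariantFactory:
    """Deterministic unique VariantKeys, one genomic window per gene."""

    _BASES = "ACGT"

    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._gene_slot: dict[str, int] = {}
        self._used: set[tuple[str, int]] = set()

    def new(self, gene: str, consequence: Consequence) -> VariantKey:
        slot = self._gene_slot.setdefault(gene, len(self._gene_slot))
        chrom = f"chr{(slot % 22) + 1}"
        base = 1_000_000 * (slot + 1)
        while True:
            pos = int(self._rng.integers(base, base + 900_000))
            if (chrom, pos) not in self._used:
                self._used.add((chrom, pos))
                break
        ref = self._BASES[self._rng.integers(4)]
        if consequence is Consequence.FRAMESHIFT_INDEL:
            if self._rng.random() < 0.5:
                alt = ref + self._BASES[self._rng.integers(4)]
            else:
                ref = ref + self._BASES[self._rng.integers(4)]
                alt = ref[0]
        else:
            alt = self._BASES[(self._BASES.index(ref) + 1 + self._rng.integers(3)) % 4]
        return VariantKey(chrom, pos, ref, alt)


def _sample_counts(rng: np.random.Generator, mean_depth: float, vaf: float,
                   cfg: SimulationConfig) -> AlleleCounts:
    depth = int(rng.poisson(mean_depth))
    p = vaf + cfg.error_rate * (1.0 - vaf)
    if depth == 0 or p <= 0:
        return AlleleCounts(depth, 0)
    if cfg.overdispersion_rho > 0:
        rho = cfg.overdispersion_rho
        p = float(rng.beta(p * (1 - rho) / rho, (1 - p) * (1 - rho) / rho))
    alt = int(rng.binomial(depth, min(p, 1.0)))
    return AlleleCounts(depth, alt)


def _weighted_choice(rng: np.random.Generator, items: Sequence, probs: Sequence[float]):
    return items[int(rng.choice(len(items), p=np.asarray(probs) / np.sum(probs)))]


@dataclass
class _Planted:
    patient_id: str
    variant: VariantKey
    gene: str
    true_class: str
    vaf_cfdna: float
    vaf_pbl: float
    vaf_tumor: float


def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate paired PBL/cfDNA/tumor call tables with ground truth.

    For each planted variant and compartment: depth ~ Poisson(mean),
    alt_reads ~ Binomial(depth, v + e*(1-v)); a variant enters a
    compartment's call table only when it drew >= 1 alt read there
    (the not-called convention).  Tumor tables exist for a random
    subset of patients.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    factory = _VariantFactory(rng)
    ch_genes = list(CH_GENE_WEIGHTS)
    ch_weights = list(CH_GENE_WEIGHTS.values())

    planted: list[_Planted] = []
    patients_meta: list[Patient] = []
    has_tumor: dict[str, bool] = {}
    carriers: list[str] = []

    def plant(pid: str, gene: str, cls: str, v_cf: float, v_pbl: float,
              v_tum: float, consequence: Consequence, clinvar: Clinvar,
              variant: Optional[VariantKey] = None) -> _Planted:
        if variant is None:
            variant = factory.new(gene, consequence)
        rec = _Planted(pid, variant, gene, cls, v_cf, v_pbl, v_tum)
        planted.append(rec)
        ann_map[variant] = Annotation(gene=gene, consequence=consequence,
                                      clinvar=clinvar)
        return rec

    ann_map: dict[VariantKey, Annotation] = {}
    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        age = int(rng.integers(cfg.age_min, cfg.age_max + 1))
        cancer = str(rng.choice(CANCER_TYPES))
        patients_meta.append(Patient(pid, cancer, age))
        has_tumor[pid] = bool(rng.random() < cfg.tumor_sample_fraction)

        p_ch = 1.0 / (1.0 + np.exp(-(cfg.prev_intercept + cfg.prev_slope * age)))
        if rng.random() < p_ch:
            carriers.append(pid)
            n_ch = 1 + int(rng.choice(len(cfg.ch_count_probs), p=cfg.ch_count_probs))
            for _ in range(n_ch):
                v = float(np.exp(rng.uniform(np.log(cfg.ch_vaf_min), np.log(cfg.ch_vaf_max))))
                gene = _weighted_choice(rng, ch_genes, ch_weights)
                cons = _weighted_choice(rng, *_CONSEQUENCES["CH"])
                v_cf = min(v * (1.0 + cfg.ch_compartment_shift), 0.999)
                plant(pid, gene, "CH", v_cf, v, 0.0, cons, Clinvar.NONE)
        for _ in range(cfg.n_germline):
            v = float(rng.beta(*cfg.germline_beta))
            gene = str(rng.choice(GERMLINE_GENES))
            cons = _weighted_choice(rng, *_CONSEQUENCES["germline"])
            clin = (Clinvar.PATHOGENIC if rng.random() < cfg.germline_pathogenic_prob
                    else Clinvar.NONE)
            plant(pid, gene, "germline", v, v, v, cons, clin)
        for _ in range(cfg.n_somatic):
            v = float(np.exp(rng.uniform(np.log(cfg.somatic_vaf_min),
                                         np.log(cfg.somatic_vaf_max))))
            gene = str(rng.choice(SOMATIC_GENES))
            cons = _weighted_choice(rng, *_CONSEQUENCES["somatic"])
            v_tum = min(v * cfg.tumor_vaf_multiplier, cfg.tumor_vaf_cap)
            plant(pid, gene, "somatic", v, 0.0, v_tum, cons, Clinvar.NONE)

    # Recurrent artifacts: CH-like signal shared by a fixed fraction of
    # the CH carriers, so their carrier ratio is far above 0.25%.
    if carriers and cfg.n_artifact_variants > 0 and cfg.artifact_carrier_fraction > 0:
        n_planted = max(1, round(cfg.artifact_carrier_fraction * len(carriers)))
        for _ in range(cfg.n_artifact_variants):
            gene = _weighted_choice(rng, ch_genes, ch_weights)
            variant = factory.new(gene, Consequence.MISSENSE)
            ann_map[variant] = Annotation(gene=gene, consequence=Consequence.MISSENSE)
            chosen = rng.choice(len(carriers), size=min(n_planted, len(carriers)),
                                replace=False)
            for idx in sorted(chosen):
                pid = carriers[int(idx)]
                planted.append(_Planted(pid, variant, gene, "artifact",
                                        cfg.artifact_vaf, cfg.artifact_vaf, 0.0))

    # Draw read counts and build per-compartment call tables.
    calls: dict[str, dict[str, list[tuple[VariantKey, AlleleCounts]]]] = {
        p.patient_id: {"cfdna": [], "pbl": [], "tumor": []} for p in patients_meta
    }
    truth_rows = []
    for rec in planted:
        pid = rec.patient_id
        for comp, vaf, mean in (
            ("cfdna", rec.vaf_cfdna, cfg.depth_cfdna),
            ("pbl", rec.vaf_pbl, cfg.depth_pbl),
            ("tumor", rec.vaf_tumor, cfg.depth_tumor),
        ):
            if comp == "tumor" and not has_tumor[pid]:
                continue
            counts = _sample_counts(rng, mean, vaf, cfg)
            if counts.alt_reads >= 1:
                calls[pid][comp].append((rec.variant, counts))
        truth_rows.append((pid, rec.variant.chrom, rec.variant.pos, rec.variant.ref,
                           rec.variant.alt, rec.gene, rec.true_class,
                           rec.vaf_cfdna, rec.vaf_pbl, rec.vaf_tumor))

    truth = pd.DataFrame(truth_rows, columns=[
        "patient_id", "chrom", "pos", "ref", "alt", "gene", "true_class",
        "vaf_cfdna", "vaf_pbl", "vaf_tumor",
    ])
    patients = [
        Patient(p.patient_id, p.cancer_type, p.age,
                assemble_observations(calls[p.patient_id]))
        for p in patients_meta
    ]
    return SimulatedCohort(cfg, patients, calls, AnnotationMap(ann_map), truth)


def assemble_observations(
    tables: Mapping[str, Sequence[tuple[VariantKey, AlleleCounts]]],
) -> list[PairedObservation]:
    """Join per-compartment call tables into cfDNA-anchored observations.

    Variants not called in cfDNA cannot enter the triage (its first
    branch conditions on the cfDNA call) and are skipped here.
    """
    pbl = dict(tables.get("pbl", ()))
    tumor = dict(tables.get("tumor", ()))
    return [
        PairedObservation(v, counts, pbl.get(v), tumor.get(v))
        for v, counts in sorted(tables.get("cfdna", ()))
    ]


def tumor_somatic_calls(
    calls: Mapping[str, Mapping[str, Sequence[tuple[VariantKey, AlleleCounts]]]],
) -> dict[str, list[VariantKey]]:
    """Per-patient tumor somatic call sets for the crosscheck stage.

    Mirrors matched-normal somatic calling: a tumor-table variant also
    called in the same patient's PBL (germline or CH signal) is not a
    somatic call.
    """
    out: dict[str, list[VariantKey]] = {}
    for pid, tables in calls.items():
        pbl = {v for v, _ in tables.get("pbl", ())}
        out[pid] = sorted(v for v, _ in tables.get("tumor", ()) if v not in pbl)
    return out


# ---------------------------------------------------------------------------
# Persistence


def write_cohort(cohort: SimulatedCohort, out_dir) -> None:
    """Write per-patient TSV call tables, annotations, truth and config."""
    out = Path(out_dir)
    (out / "calls").mkdir(parents=True, exist_ok=True)
    header = "chrom\tpos\tref\talt\tdepth\talt_reads\n"
    for p in cohort.patients:
        for comp, table in cohort.calls[p.patient_id].items():
            if comp == "tumor" and not table:
                continue
            with open(out / "calls" / f"{p.patient_id}.{comp}.tsv", "w") as fh:
                fh.write(header)
                for v, c in sorted(table):
                    fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{c.depth}\t{c.alt_reads}\n")
    with open(out / "patients.tsv", "w") as fh:
        fh.write("patient_id\tcancer_type\tage\n")
        for p in cohort.patients:
            fh.write(f"{p.patient_id}\t{p.cancer_type}\t{p.age}\n")
    write_annotations(out / "annotations.tsv", cohort.annotations)
    cohort.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Scoring


def evaluate_calls(
    truth: pd.DataFrame,
    classified: Sequence[ClassifiedVariant],
    final_ch: Sequence[ClassifiedVariant],
    removed_by_carrier: Sequence[VariantKey] = (),
    vaf_threshold: float = 0.02,
) -> dict:
    """Score the pipeline's recovery against the simulator's ground truth.

    Returns a confusion table (true class x assigned label), CH
    sensitivity overall and above ``vaf_threshold``, somatic->CH
    leakage, germline->CH count, and the artifact removal rate of the
    carrier-ratio filter.
    """
    truth_patients = set(truth["patient_id"])
    call_patients = {r.patient_id for r in classified}
    if not call_patients <= truth_patients:
        raise ValueError("classified records reference patients absent from truth")

    def key_of(row) -> tuple[str, VariantKey]:
        return row.patient_id, VariantKey(row.chrom, int(row.pos), row.ref, row.alt)

    assigned: dict[tuple[str, VariantKey], str] = {
        (r.patient_id, r.variant): r.label.value for r in classified
    }
    ch_set = {(r.patient_id, r.variant) for r in final_ch}

    confusion: dict[str, dict[str, int]] = {}
    n_truth = {"CH": 0, "germline": 0, "somatic": 0, "artifact": 0}
    n_ch_called = dict.fromkeys(n_truth, 0)
    n_ch_vaf = 0
    n_ch_vaf_called = 0
    omitted = 0
    for row in truth.itertuples():
        k = key_of(row)
        cls = row.true_class
        n_truth[cls] += 1
        label = "NOT_CALLED"
        if k in ch_set:
            label = Label.CH.value
        elif k in assigned:
            label = assigned[k]
        else:
            omitted += 1
        confusion.setdefault(cls, {}).setdefault(label, 0)
        confusion[cls][label] += 1
        is_final_ch = k in ch_set
        if is_final_ch:
            n_ch_called[cls] += 1
        if cls == "CH" and row.vaf_pbl >= vaf_threshold:
            n_ch_vaf += 1
            n_ch_vaf_called += is_final_ch

    removed = set(removed_by_carrier)
    artifact_variants = {
        VariantKey(r.chrom, int(r.pos), r.ref, r.alt)
        for r in truth[truth["true_class"] == "artifact"].itertuples()
    }
    artifact_removed = len(artifact_variants & removed)

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return {
        "confusion": confusion,
        "n_truth": n_truth,
        "omitted_not_called_cfdna": omitted,
        "ch_sensitivity": ratio(n_ch_called["CH"], n_truth["CH"]),
        "ch_sensitivity_above_vaf": ratio(n_ch_vaf_called, n_ch_vaf),
        "vaf_threshold": vaf_threshold,
        "somatic_to_ch_leakage": ratio(n_ch_called["somatic"], n_truth["somatic"]),
        "germline_to_ch": n_ch_called["germline"],
        "artifact_removal_rate": ratio(artifact_removed, len(artifact_variants)),
    }
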