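"""Per-patient triage of called variants into somatic, germline and CH.

The decision procedure mirrors the paired cfDNA/PBL design.  A variant
called only in cfDNA is a candidate tumor-derived somatic mutation and
must clear depth/VAF/population-frequency filters.  A variant also
present in PBL at high allele fraction (>= 20% with >= 30x depth) is
germline, retained only when ClinVar calls it (likely) pathogenic.  A
variant present in PBL at low allele fraction is tested for clonal
hematopoiesis: under CH the clone contributes the same allele fraction
to both blood compartments, so a two-sided Fisher's exact test on the
alt/ref read counts should not reject (p >= 0.05) and the sample odds
ratio should sit near 1 (strictly inside (0.5, 1.5)).  Significant
cfDNA enrichment instead re-routes the variant to the somatic filters;
the remaining discordant patterns are discarded and logged.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from .model import (
    Annotation,
    ClassifiedVariant,
    Clinvar,
    Consequence,
    Label,
    PairedObservation,
    Patient,
    Thresholds,
    VariantKey,
)
from .stats import Table2x2, fisher_exact

PATHOGENIC = (Clinvar.PATHOGENIC, Clinvar.LIKELY_PATHOGENIC)


def prefilter(
    variants: Iterable[tuple[VariantKey, Annotation]],
) -> tuple[list[tuple[VariantKey, Annotation]], list[tuple[VariantKey, str]]]:
    """Drop blacklisted and synonymous variants before classification.

    Returns (retained, removed) with input order preserved; each removed
    entry carries the rule that fired ("blacklist" or "synonymous").
    """
    kept: list[tuple[VariantKey, Annotation]] = []
    removed: list[tuple[VariantKey, str]] = []
    for key, ann in variants:
        if ann.in_blacklist:
            removed.append((key, "blacklist"))
        elif ann.consequence is Consequence.SYNONYMOUS:
            removed.append((key, "synonymous"))
        else:
            kept.append((key, ann))
    return kept, removed


def _somatic_filters(obs: PairedObservation, ann: Annotation, th: Thresholds) -> list[str]:
    """Reasons for which a candidate somatic call fails; empty = pass."""
    cf = obs.cfdna
    reasons: list[str] = []
    if cf.depth < th.somatic_min_depth:
        reasons.append("somatic_low_depth")
    if cf.alt_reads < th.min_alt_reads:
        reasons.append("somatic_min_alt")
    if cf.depth > 0 and cf.vaf < th.somatic_min_vaf:
        reasons.append("somatic_low_vaf")
    if ann.max_pop_maf > th.max_pop_maf:
        reasons.append("common_population")
    if ann.in_dbsnp and not ann.in_cosmic:
        reasons.append("dbsnp_not_cosmic")
    if ann.is_hla:
        reasons.append("hla")
    return reasons


def classify_variant(
    obs: PairedObservation,
    ann: Annotation = Annotation(),
    th: Thresholds = Thresholds(),
) -> ClassifiedVariant:
    """Assign one triage label to a prefiltered paired observation."""
    pid = ""  # filled by classify_patient; standalone use keeps it empty
    return _classify(pid, obs, ann, th)


def _classify(
    patient_id: str, obs: PairedObservation, ann: Annotation, th: Thresholds
) -> ClassifiedVariant:
    cf, pbl = obs.cfdna, obs.pbl

    if cf.depth == 0 or (pbl is not None and pbl.depth == 0):
        return ClassifiedVariant(patient_id, obs.variant, Label.FILTERED,
                                 reasons=("zero_depth",))

    # Branch 1: called only in cfDNA -> candidate somatic.
    if pbl is None:
        failures = _somatic_filters(obs, ann, th)
        if failures:
            return ClassifiedVariant(patient_id, obs.variant, Label.FILTERED,
                                     reasons=tuple(failures))
        return ClassifiedVariant(patient_id, obs.variant, Label.SOMATIC,
                                 reasons=("cfdna_only",))

    # Branch 4 (checked before 2/3): PBL coverage too shallow to judge.
    if pbl.depth < th.germline_min_depth:
        return ClassifiedVariant(patient_id, obs.variant, Label.FILTERED,
                                 reasons=("pbl_low_depth",))

    # Branch 2: high PBL allele fraction -> germline.
    if pbl.vaf >= th.germline_min_vaf:
        if ann.clinvar in PATHOGENIC:
            return ClassifiedVariant(patient_id, obs.variant, Label.GERMLINE_PATHOGENIC,
                                     reasons=("germline_pathogenic",))
        return ClassifiedVariant(patient_id, obs.variant, Label.FILTERED,
                                 reasons=("germline_not_pathogenic",))

    # Branch 3: low PBL allele fraction -> Fisher test cfDNA vs PBL.
    res = fisher_exact(Table2x2(cf.alt_reads, cf.ref_reads, pbl.alt_reads, pbl.ref_reads))
    p, odds = res.p_two_sided, res.or_sample
    if p >= th.ch_min_p and th.ch_or_low < odds < th.ch_or_high:
        if cf.alt_reads >= th.min_alt_reads and pbl.alt_reads >= th.min_alt_reads:
            return ClassifiedVariant(patient_id, obs.variant, Label.CANDIDATE_CH,
                                     p_value=p, odds_ratio=odds,
                                     reasons=("ch_concordant",))
        return ClassifiedVariant(patient_id, obs.variant, Label.FILTERED,
                                 p_value=p, odds_ratio=odds, reasons=("ch_min_alt",))
    if p < th.ch_min_p and odds > 1:
        failures = _somatic_filters(obs, ann, th)
        if failures:
            return ClassifiedVariant(patient_id, obs.variant, Label.FILTERED,
                                     p_value=p, odds_ratio=odds, reasons=tuple(failures))
        return ClassifiedVariant(patient_id, obs.variant, Label.SOMATIC,
                                 p_value=p, odds_ratio=odds,
                                 reasons=("cfdna_enriched",))
    reason = "pbl_enriched" if p < th.ch_min_p else "or_outside_window"
    return ClassifiedVariant(patient_id, obs.variant, Label.DISCORDANT_DISCARD,
                             p_value=p, odds_ratio=odds, reasons=(reason,))


def classify_patient(
    patient: Patient,
    annotations: Mapping[VariantKey, Annotation],
    th: Thresholds = Thresholds(),
) -> list[ClassifiedVariant]:
    """Prefilter and classify every observation of one patient.

    Prefiltered-out variants are emitted as FILTERED records so that
    every input (patient, variant) pair receives exactly one label.
    """
    pairs = [(obs.variant, annotations[obs.variant]) for obs in patient.observations]
    kept, removed = prefilter(pairs)
    kept_keys = {k for k, _ in kept}
    out: list[ClassifiedVariant] = []
    removed_reasons = dict(removed)
    for obs in patient.observations:
        if obs.variant in kept_keys:
            out.append(_classify(patient.patient_id, obs,
                                 annotations[obs.variant], th))
        else:
            out.append(ClassifiedVariant(patient.patient_id, obs.variant, Label.FILTERED,
                                         reasons=(removed_reasons[obs.variant],)))
    return out
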