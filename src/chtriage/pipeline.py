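"""End-to-end orchestration: triage -> funnel -> cohort analytics.

``run_pipeline`` consumes a directory of per-patient call tables plus
the annotation, blacklist and knowledge-base inputs, classifies every
variant, applies the candidate-CH funnel, and persists the analytics
tables together with a machine-readable run summary whose stage counts
satisfy the funnel conservation identity.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import time
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import cohort as ca
from .io import (
    AnnotationMap,
    Blacklist,
    read_annotations,
    read_blacklist,
    read_calls,
    read_knowledge_base,
    write_classified,
)
from .model import Annotation, ClassifiedVariant, Label, Patient, Thresholds, VariantKey
from .simulate import assemble_observations, tumor_somatic_calls
from .triage import classify_patient

logger = logging.getLogger("chtriage")

_CALL_FILE = re.compile(r"^(?P<pid>.+)\.(?P<comp>cfdna|pbl|tumor)\.(?P<ext>tsv|vcf)$")


def load_thresholds(path) -> Thresholds:
    """Thresholds from a flat YAML/JSON mapping; unknown keys rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown threshold fields: {sorted(unknown)}")
    return Thresholds(**data)


def load_patients_dir(patients_dir) -> tuple[list[Patient], dict]:
    """Read per-patient call tables named <pid>.<compartment>.tsv|vcf.

    Patient metadata (age, cancer type) comes from an optional
    ``patients.tsv`` beside the ``calls/`` directory; patients missing
    from it get age 0 and type "unknown".
    """
    root = Path(patients_dir)
    calls_dir = root / "calls" if (root / "calls").is_dir() else root
    tables: dict[str, dict[str, list]] = {}
    for path in sorted(calls_dir.iterdir()):
        m = _CALL_FILE.match(path.name)
        if not m:
            continue
        pid, comp = m.group("pid"), m.group("comp")
        tables.setdefault(pid, {})[comp] = read_calls(path)
    meta: dict[str, tuple[str, int]] = {}
    meta_path = root / "patients.tsv"
    if meta_path.exists():
        with open(meta_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                meta[row["patient_id"]] = (row.get("cancer_type", "unknown"),
                                           int(row.get("age", 0)))
    patients = []
    for pid in sorted(set(tables) | set(meta)):
        cancer, age = meta.get(pid, ("unknown", 0))
        patients.append(Patient(pid, cancer, age,
                                assemble_observations(tables.get(pid, {}))))
    return patients, {pid: t for pid, t in tables.items()}


def run_pipeline(
    patients_dir,
    annotations_path,
    out_dir,
    blacklist_path=None,
    kb_path=None,
    config_path=None,
    panel: Optional[Sequence[str]] = None,
) -> dict:
    """Execute the full pipeline and return the run summary dict."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = load_thresholds(config_path) if config_path else Thresholds()

    def stage(name):
        logger.info(json.dumps({"stage": name}))

    stage("load")
    patients, tables = load_patients_dir(patients_dir)
    annotations = read_annotations(annotations_path)
    blacklist = read_blacklist(blacklist_path) if blacklist_path else Blacklist()
    annotations = _apply_blacklist(annotations, blacklist, patients)
    kb = read_knowledge_base(kb_path) if kb_path else {}

    stage("classify")
    classified: list[ClassifiedVariant] = []
    for p in patients:
        classified.extend(classify_patient(p, annotations, th))

    stage("funnel")
    tumor_calls = tumor_somatic_calls(tables)
    final_ch, funnel, removed_variants = ca.apply_funnel(classified, tumor_calls, th)

    stage("analytics")
    trend, r = ca.age_trend(patients, final_ch)
    summary = ca.gene_summary(final_ch, patients, annotations, panel)
    occurrences = ca.preferred_occurrences(
        [r_ for r_ in classified if r_.label is not Label.CANDIDATE_CH] + final_ch)
    genes_of = {v: annotations[v].gene for v in occurrences}
    per_mut, per_gene_pref = ca.classify_preferred(occurrences, genes_of)

    write_classified(out / "classified.tsv", classified)
    write_classified(out / "ch_final.tsv", final_ch)
    trend.to_csv(out / "age_trend.tsv", sep="\t", index=False)
    with open(out / "carrier_ratios.tsv", "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcarrier_ratio\tremoved\n")
        candidates = [c for c in classified if c.label is Label.CANDIDATE_CH]
        ratios = ca.carrier_ratio(candidates) if candidates else {}
        removed_set = set(removed_variants)
        for v in sorted(ratios):
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t"
                     f"{ratios[v]:.6g}\t{v in removed_set}\n")
    with open(out / "gene_summary.tsv", "w") as fh:
        fh.write("gene\tcarriers\tnon_carriers\tpct_of_ch_positive\n")
        for g, (w, wo) in summary.per_gene.items():
            pct = 100.0 * w / summary.ch_positive_samples if summary.ch_positive_samples else float("nan")
            fh.write(f"{g}\t{w}\t{wo}\t{pct:.4g}\n")
    with open(out / "preferred_genes.tsv", "w") as fh:
        fh.write("gene\tpreferred\n")
        for g, lab in sorted(per_gene_pref.items()):
            fh.write(f"{g}\t{lab}\n")

    interference = None
    if kb:
        hits, per_gene_hits, interference = ca.actionable_overlap(final_ch, kb, annotations)
        per_gene_hits.to_csv(out / "actionable_genes.tsv", sep="\t", index=False)
        with open(out / "actionable_hits.tsv", "w") as fh:
            fh.write("chrom\tpos\tref\talt\tgene\tn_patients\tassertion\n")
            for h in hits:
                fh.write(f"{h.variant.chrom}\t{h.variant.pos}\t{h.variant.ref}\t"
                         f"{h.variant.alt}\t{h.gene}\t{len(h.patient_ids)}\t{h.assertion}\n")

    reason_counts: dict[str, int] = {}
    for rec in classified:
        if rec.label in (Label.FILTERED, Label.DISCORDANT_DISCARD):
            for reason in rec.reasons:
                reason_counts[reason] = reason_counts.get(reason, 0) + 1

    run_summary = {
        "thresholds": dataclasses.asdict(th),
        "n_patients": len(patients),
        "n_observations": sum(len(p.observations) for p in patients),
        "labels": {lab.value: sum(1 for r in classified if r.label is lab)
                   for lab in Label},
        "funnel": dataclasses.asdict(funnel),
        "filter_reasons": dict(sorted(reason_counts.items())),
        "age_trend_pearson_r": r,
        "ch_positive_patients": summary.ch_positive_samples,
        "interference": interference,
        "outputs": sorted(p.name for p in out.iterdir()),
        "wall_time_s": round(time.time() - t0, 3),
    }
    with open(out / "run_summary.json", "w") as fh:
        json.dump(run_summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stage("done")
    return run_summary


def recovery_benchmark(
    n_patients: int = 2000,
    seeds: Sequence[int] = tuple(range(10)),
    config: Optional["SimulationConfig"] = None,
) -> dict:
    """Seed-averaged recovery metrics on default synthetic cohorts.

    For each seed: simulate, classify, run the candidate-CH funnel and
    score against ground truth.  Returns per-seed metrics plus their
    means (the keys under ``mean``).
    """
    from .simulate import SimulationConfig, evaluate_calls, simulate_cohort

    per_seed = []
    keys = ("ch_sensitivity", "ch_sensitivity_above_vaf",
            "somatic_to_ch_leakage", "germline_to_ch", "artifact_removal_rate")
    for seed in seeds:
        base = config or SimulationConfig()
        cfg = dataclasses.replace(base, n_patients=n_patients, seed=int(seed))
        coh = simulate_cohort(cfg)
        classified: list[ClassifiedVariant] = []
        for p in coh.patients:
            classified.extend(classify_patient(p, coh.annotations))
        final, funnel, removed = ca.apply_funnel(
            classified, tumor_somatic_calls(coh.calls))
        m = evaluate_calls(coh.truth, classified, final, removed)
        m["funnel"] = dataclasses.asdict(funnel)
        m["seed"] = int(seed)
        per_seed.append(m)
    mean = {k: sum(m[k] for m in per_seed) / len(per_seed) for k in keys}
    return {"per_seed": per_seed, "mean": mean,
            "n_patients": n_patients, "n_seeds": len(seeds)}


def _apply_blacklist(
    annotations: AnnotationMap, blacklist: Blacklist, patients: Sequence[Patient]
) -> AnnotationMap:
    """Mark in_blacklist on annotations of observed variants in regions."""
    if len(blacklist) == 0:
        return annotations
    merged: dict[VariantKey, Annotation] = dict(annotations.items())
    for p in patients:
        for obs in p.observations:
            v = obs.variant
            ann = annotations[v]
            if v in blacklist and not ann.in_blacklist:
                merged[v] = dataclasses.replace(ann, in_blacklist=True)
    return AnnotationMap(merged)
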