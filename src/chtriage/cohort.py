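"""Cohort-level analytics over classified variants.

Covers the candidate-CH funnel (recurrent-carrier filter and matched-
tumor crosscheck), the age/prevalence trend, per-gene carrier
summaries, preferred-class labelling of polymorphic mutations,
two-cohort per-gene comparison, actionable-mutation interference, and
generic gene-set over-representation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import Annotation, ClassifiedVariant, Label, Patient, Thresholds, VariantKey
from .stats import FisherResult, Table2x2, bh_fdr, fisher_exact, pearson_r

AGE_GROUP_LABELS = ("<=40", "40-50", "50-60", "60-70", "70-80", "80-90", ">90")
_AGE_EDGES = (40, 50, 60, 70, 80, 90)


# ---------------------------------------------------------------------------
# Candidate-CH funnel


def carrier_ratio(candidates: Iterable[ClassifiedVariant]) -> dict[VariantKey, float]:
    """Per-variant carrier ratio among CH-positive patients.

    The denominator is the number of patients carrying at least one
    candidate CH mutation, computed once on the candidate set; a
    recurrent technical artifact shows up as an implausibly high ratio.
    """
    carriers: dict[VariantKey, set[str]] = defaultdict(set)
    patients: set[str] = set()
    for rec in candidates:
        if rec.label is not Label.CANDIDATE_CH:
            raise ValueError("carrier_ratio expects CANDIDATE_CH records only")
        carriers[rec.variant].add(rec.patient_id)
        patients.add(rec.patient_id)
    n = len(patients)
    return {v: len(p) / n for v, p in carriers.items()}


def filter_carrier_ratio(
    candidates: Sequence[ClassifiedVariant], th: Thresholds = Thresholds()
) -> tuple[list[ClassifiedVariant], list[VariantKey], float]:
    """Drop every instance of variants with carrier ratio > threshold.

    Returns (retained records, removed variants, variant-level retention
    fraction).  The threshold is strict: a ratio exactly at
    ``carrier_ratio_max`` is retained.
    """
    if not candidates:
        return [], [], float("nan")
    ratios = carrier_ratio(candidates)
    removed = sorted(v for v, r in ratios.items() if r > th.carrier_ratio_max)
    removed_set = set(removed)
    retained = [rec for rec in candidates if rec.variant not in removed_set]
    retention = (len(ratios) - len(removed)) / len(ratios)
    return retained, removed, retention


def tumor_crosscheck(
    candidates: Sequence[ClassifiedVariant],
    tumor_somatic_calls: Mapping[str, Iterable[VariantKey]],
) -> tuple[list[ClassifiedVariant], list[ClassifiedVariant]]:
    """Remove candidates also called somatic in the same patient's tumor.

    Patients without tumor data pass through.  Returns (final CH,
    removed records).
    """
    tumor_sets = {pid: set(keys) for pid, keys in tumor_somatic_calls.items()}
    final: list[ClassifiedVariant] = []
    removed: list[ClassifiedVariant] = []
    for rec in candidates:
        if rec.variant in tumor_sets.get(rec.patient_id, ()):  # matched sample only
            removed.append(rec)
        else:
            final.append(rec)
    return final, removed


@dataclass
class FunnelCounts:
    """Stage counts of the candidate-to-final CH filtering funnel."""

    candidates_in: int
    removed_min_alt: int
    removed_carrier_ratio: int
    removed_tumor: int
    ch_final: int

    def conserved(self) -> bool:
        return self.candidates_in == (self.ch_final + self.removed_min_alt
                                      + self.removed_carrier_ratio + self.removed_tumor)


def apply_funnel(
    classified: Sequence[ClassifiedVariant],
    tumor_somatic_calls: Mapping[str, Iterable[VariantKey]] | None = None,
    th: Thresholds = Thresholds(),
) -> tuple[list[ClassifiedVariant], FunnelCounts, list[VariantKey]]:
    """Run min-alt -> carrier-ratio -> tumor stages over classified records.

    The min-alt-read rule is applied during classification (records that
    failed it carry the "ch_min_alt" reason); here it only enters the
    funnel accounting.  Returns (final CH records relabelled CH, funnel
    counts, variants removed by the carrier-ratio stage).
    """
    removed_min_alt = sum(1 for r in classified
                          if r.label is Label.FILTERED and "ch_min_alt" in r.reasons)
    candidates = [r for r in classified if r.label is Label.CANDIDATE_CH]
    retained, removed_variants, _ = filter_carrier_ratio(candidates, th)
    final, removed_tumor = tumor_crosscheck(retained, tumor_somatic_calls or {})
    counts = FunnelCounts(
        candidates_in=len(candidates) + removed_min_alt,
        removed_min_alt=removed_min_alt,
        removed_carrier_ratio=len(candidates) - len(retained),
        removed_tumor=len(removed_tumor),
        ch_final=len(final),
    )
    final_ch = [ClassifiedVariant(r.patient_id, r.variant, Label.CH, r.p_value,
                                  r.odds_ratio, r.reasons) for r in final]
    return final_ch, counts, removed_variants


# ---------------------------------------------------------------------------
# Age trend


def age_group(age: float) -> str:
    """Bin a diagnostic age into the seven right-closed cohort groups."""
    if age < 0:
        raise ValueError("age must be >= 0")
    for i, edge in enumerate(_AGE_EDGES):
        if age <= edge:
            return AGE_GROUP_LABELS[i]
    return AGE_GROUP_LABELS[-1]


def age_trend_from_counts(
    carriers: Sequence[int], totals: Sequence[int]
) -> tuple[pd.DataFrame, Optional[float]]:
    """Prevalence table and Pearson r from per-group carrier/total counts.

    Groups with zero patients are excluded from the correlation; r is
    None when fewer than 3 groups remain or the percents are constant.
    The x variable is the (1-based) group index — equally spaced bins
    make the index and the bin midpoint give the same r.
    """
    if len(carriers) != len(totals) or len(carriers) > len(AGE_GROUP_LABELS):
        raise ValueError("carriers/totals must align with the age groups")
    rows = []
    for label, c, t in zip(AGE_GROUP_LABELS, carriers, totals):
        pct = 100.0 * c / t if t > 0 else float("nan")
        rows.append((label, c, t, pct))
    table = pd.DataFrame(rows, columns=["group", "carriers", "total", "percent"])
    nonempty = table[table["total"] > 0]
    r: Optional[float] = None
    if len(nonempty) >= 3:
        try:
            r = pearson_r(nonempty.index.to_numpy() + 1, nonempty["percent"].to_numpy())
        except ValueError:
            r = None
    return table, r


def age_trend(
    patients: Sequence[Patient], ch_calls: Iterable[ClassifiedVariant]
) -> tuple[pd.DataFrame, Optional[float]]:
    """Per-age-group CH prevalence and its Pearson correlation with age."""
    positive = {rec.patient_id for rec in ch_calls}
    carriers = [0] * len(AGE_GROUP_LABELS)
    totals = [0] * len(AGE_GROUP_LABELS)
    index = {label: i for i, label in enumerate(AGE_GROUP_LABELS)}
    for p in patients:
        i = index[age_group(p.age)]
        totals[i] += 1
        if p.patient_id in positive:
            carriers[i] += 1
    return age_trend_from_counts(carriers, totals)


# ---------------------------------------------------------------------------
# Gene summaries and cohort comparison


@dataclass
class CohortSummary:
    """Per-gene and per-variant carrier counts over a patient cohort."""

    total_samples: int
    ch_positive_samples: int
    per_variant: dict[VariantKey, int] = field(default_factory=dict)
    per_gene: dict[str, tuple[int, int]] = field(default_factory=dict)  # gene -> (with, without)


def gene_summary(
    ch_calls: Iterable[ClassifiedVariant],
    patients: Sequence[Patient],
    annotations: Mapping[VariantKey, Annotation],
    panel: Optional[Iterable[str]] = None,
) -> CohortSummary:
    """Carrier counts per gene and per variant over the whole cohort.

    ``panel`` optionally restricts counting to a gene list before any
    tallying (used for cross-panel prevalence comparisons).
    """
    panel_set = set(panel) if panel is not None else None
    total = len(patients)
    per_variant_carriers: dict[VariantKey, set[str]] = defaultdict(set)
    gene_carriers: dict[str, set[str]] = defaultdict(set)
    positive: set[str] = set()
    for rec in ch_calls:
        gene = annotations[rec.variant].gene
        if panel_set is not None and gene not in panel_set:
            continue
        per_variant_carriers[rec.variant].add(rec.patient_id)
        gene_carriers[gene].add(rec.patient_id)
        positive.add(rec.patient_id)
    return CohortSummary(
        total_samples=total,
        ch_positive_samples=len(positive),
        per_variant={v: len(s) for v, s in sorted(per_variant_carriers.items())},
        per_gene={g: (len(s), total - len(s)) for g, s in sorted(gene_carriers.items())},
    )


def prevalence_compare(
    summary_a: CohortSummary, summary_b: CohortSummary
) -> tuple[float, FisherResult]:
    """Prevalence ratio and Fisher test between two cohort summaries.

    The ratio is (carriers_A/total_A)/(carriers_B/total_B) — the
    quantity the study prints as its cohort-level "odds ratio" — while
    the FisherResult carries the cross-product OR and exact p for the
    same 2x2 table; the two estimands differ and are reported side by
    side.
    """
    for s in (summary_a, summary_b):
        if s.total_samples == 0:
            raise ValueError("cohort with zero samples")
    pa = summary_a.ch_positive_samples / summary_a.total_samples
    pb = summary_b.ch_positive_samples / summary_b.total_samples
    if pb == 0:
        raise ValueError("reference cohort has zero prevalence")
    table = Table2x2(
        summary_a.ch_positive_samples,
        summary_a.total_samples - summary_a.ch_positive_samples,
        summary_b.ch_positive_samples,
        summary_b.total_samples - summary_b.ch_positive_samples,
    )
    return pa / pb, fisher_exact(table)


def compare_cohorts(
    summary_a: CohortSummary,
    summary_b: CohortSummary,
    genes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-gene 2x2 enrichment between two cohorts.

    Default gene universe: genes carrying CH in BOTH cohorts.  The 2x2
    is laid out with rows = with/without CH and columns = cohort A/B,
    so OR = (a*d)/(b*c) with a = carriers in A, b = carriers in B.
    q-values are Benjamini-Hochberg over exactly the tested genes.
    """
    if genes is None:
        genes = sorted(
            g for g, (w, _) in summary_a.per_gene.items()
            if w > 0 and summary_b.per_gene.get(g, (0, 0))[0] > 0
        )
    else:
        genes = sorted(set(genes))
    rows = []
    for g in genes:
        with_a, without_a = summary_a.per_gene.get(g, (0, summary_a.total_samples))
        with_b, without_b = summary_b.per_gene.get(g, (0, summary_b.total_samples))
        t = Table2x2(with_a, with_b, without_a, without_b)
        res = fisher_exact(t)
        rows.append((g, with_a, with_b, without_a, without_b,
                     res.or_sample, res.p_two_sided))
    df = pd.DataFrame(rows, columns=["gene", "a", "b", "c", "d", "odds_ratio", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


# ---------------------------------------------------------------------------
# Preferred-class labelling


CH_PREFERRED = "CH_preferred"
GERMLINE_PREFERRED = "germline_preferred"
SOMATIC_PREFERRED = "somatic_preferred"
UNLABELED = "unlabeled"

_CLASS_TO_LABEL = {"CH": CH_PREFERRED, "germline": GERMLINE_PREFERRED,
                   "somatic": SOMATIC_PREFERRED}


def classify_preferred(
    occurrences: Mapping[VariantKey, Mapping[str, int]],
    genes: Mapping[VariantKey, str],
) -> tuple[dict[VariantKey, str], dict[str, str]]:
    """Label polymorphic CH mutations and their genes by majority class.

    ``occurrences`` maps each variant to patient-level counts of how
    often it was classified CH, germline or somatic across the cohort.
    Only polymorphic CH mutations enter (CH in >= 1 patient AND germline
    or somatic in >= 1 other).  A mutation takes the label of the class
    holding a strict majority (> 50%) of its occurrences.  A gene is
    CH-preferred iff its labelled mutations are CH-preferred only;
    germline-preferred iff it has >= 1 CH-preferred mutation and
    strictly more germline- than somatic-preferred ones; symmetrically
    for somatic-preferred; ties stay unlabeled.
    """
    per_mutation: dict[VariantKey, str] = {}
    for variant, counts in occurrences.items():
        n_ch = counts.get("CH", 0)
        n_ger = counts.get("germline", 0)
        n_som = counts.get("somatic", 0)
        if n_ch < 1 or (n_ger + n_som) < 1:
            continue  # not a polymorphic CH mutation
        total = n_ch + n_ger + n_som
        label = UNLABELED
        for cls, n in (("CH", n_ch), ("germline", n_ger), ("somatic", n_som)):
            if n / total > 0.5:
                label = _CLASS_TO_LABEL[cls]
        per_mutation[variant] = label

    by_gene: dict[str, Counter] = defaultdict(Counter)
    for variant, label in per_mutation.items():
        by_gene[genes[variant]][label] += 1
    per_gene: dict[str, str] = {}
    for gene, counts in sorted(by_gene.items()):
        n_ch = counts[CH_PREFERRED]
        n_ger = counts[GERMLINE_PREFERRED]
        n_som = counts[SOMATIC_PREFERRED]
        if n_ch >= 1 and n_ger == 0 and n_som == 0:
            per_gene[gene] = CH_PREFERRED
        elif n_ch >= 1 and n_ger > n_som:
            per_gene[gene] = GERMLINE_PREFERRED
        elif n_ch >= 1 and n_som > n_ger:
            per_gene[gene] = SOMATIC_PREFERRED
        else:
            per_gene[gene] = UNLABELED
    return per_mutation, per_gene


def preferred_occurrences(
    classified: Iterable[ClassifiedVariant],
) -> dict[VariantKey, dict[str, int]]:
    """Patient-level CH/germline/somatic occurrence counts per variant."""
    label_to_class = {Label.CH: "CH", Label.CANDIDATE_CH: "CH",
                      Label.GERMLINE_PATHOGENIC: "germline", Label.SOMATIC: "somatic"}
    seen: dict[VariantKey, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for rec in classified:
        cls = label_to_class.get(rec.label)
        if cls is not None:
            seen[rec.variant][cls].add(rec.patient_id)
    return {v: {cls: len(p) for cls, p in classes.items()}
            for v, classes in seen.items()}


# ---------------------------------------------------------------------------
# Actionable-mutation interference


@dataclass(frozen=True)
class ActionableHit:
    variant: VariantKey
    gene: str
    patient_ids: tuple[str, ...]
    assertion: str


def actionable_overlap(
    final_ch_calls: Sequence[ClassifiedVariant],
    kb: Mapping[VariantKey, str],
    annotations: Mapping[VariantKey, Annotation],
) -> tuple[list[ActionableHit], pd.DataFrame, dict[str, float]]:
    """Overlap final CH calls with an actionable-mutation knowledge base.

    A hit requires the genomic position and the alternate allele to
    match exactly.  Returns the hit list, a per-gene table with Fisher
    enrichment of hit patients against non-hit CH carriers of the gene
    (BH-corrected over the hit genes), and summary fractions.
    """
    kb_index = {(k.chrom, k.pos, k.alt): (k, text) for k, text in kb.items()}
    hits_by_variant: dict[VariantKey, set[str]] = defaultdict(set)
    assertion_for: dict[VariantKey, str] = {}
    all_ch_variants: set[VariantKey] = set()
    carriers_by_gene: dict[str, set[str]] = defaultdict(set)
    all_patients: set[str] = set()
    for rec in final_ch_calls:
        all_ch_variants.add(rec.variant)
        all_patients.add(rec.patient_id)
        carriers_by_gene[annotations[rec.variant].gene].add(rec.patient_id)
        match = kb_index.get((rec.variant.chrom, rec.variant.pos, rec.variant.alt))
        if match is not None:
            hits_by_variant[rec.variant].add(rec.patient_id)
            assertion_for[rec.variant] = match[1]

    hits = [
        ActionableHit(v, annotations[v].gene, tuple(sorted(pids)), assertion_for[v])
        for v, pids in sorted(hits_by_variant.items())
    ]
    hit_patients: set[str] = set()
    hit_patients_by_gene: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        hit_patients.update(h.patient_ids)
        hit_patients_by_gene[h.gene].update(h.patient_ids)

    n_hit = len(hit_patients)
    n_ch_patients = len(all_patients)
    rows = []
    for gene in sorted(hit_patients_by_gene):
        a = len(hit_patients_by_gene[gene])
        b = n_hit - a
        gene_carriers = carriers_by_gene[gene]
        c = len(gene_carriers - hit_patients)
        d = (n_ch_patients - n_hit) - c
        res = fisher_exact(Table2x2(a, b, c, d))
        rows.append((gene, a, 100.0 * a / n_hit if n_hit else float("nan"),
                     res.or_sample, res.p_two_sided))
    per_gene = pd.DataFrame(rows, columns=["gene", "hit_patients",
                                           "pct_of_hit_patients", "odds_ratio", "p"])
    per_gene["q"] = bh_fdr(per_gene["p"].to_numpy()) if len(per_gene) else []

    summary = {
        "n_hit_variants": float(len(hits)),
        "n_ch_variants": float(len(all_ch_variants)),
        "pct_hit_variants": 100.0 * len(hits) / len(all_ch_variants) if all_ch_variants else float("nan"),
        "n_hit_patients": float(n_hit),
        "n_ch_patients": float(n_ch_patients),
        "pct_hit_patients": 100.0 * n_hit / n_ch_patients if n_ch_patients else float("nan"),
    }
    return hits, per_gene, summary


# ---------------------------------------------------------------------------
# Generic gene-set over-representation


def enrich_gene_sets(
    genes: Iterable[str],
    background: Iterable[str],
    sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Fisher over-representation of ``genes`` within ``background``.

    For each set S the 2x2 is (query∩S, query\\S, bg∩S\\query,
    bg\\S\\query); the Haldane-corrected sample OR handles degenerate
    saturated tables.  q-values are BH over all sets in the collection.
    """
    query = set(genes)
    bg = set(background)
    if not query <= bg:
        raise ValueError("query genes must be a subset of the background")
    rows = []
    for name in sorted(sets):
        s = sets[name] & bg
        a = len(query & s)
        b = len(query - s)
        c = len((bg - query) & s)
        d = len(bg - query - s)
        res = fisher_exact(Table2x2(a, b, c, d))
        rows.append((name, a, b, c, d, res.or_sample, res.p_two_sided))
    df = pd.DataFrame(rows, columns=["set", "a", "b", "c", "d", "odds_ratio", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df
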