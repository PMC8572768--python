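"""Triage a handful of paired cfDNA/PBL observations.

Builds one observation per decision branch and prints the label each
receives: a cfDNA-only call passing the somatic filters, a low-VAF
variant concordant between compartments (clonal hematopoiesis), a
cfDNA-enriched variant re-routed to somatic, and a ~50% PBL-VAF
germline variant dropped for lacking a pathogenic ClinVar record.
"""

from chtriage import (
    AlleleCounts,
    Annotation,
    Clinvar,
    PairedObservation,
    VariantKey,
    classify_variant,
)

cases = [
    ("cfDNA-only, VAF 1%",
     PairedObservation(VariantKey("chr17", 7577120, "C", "A"),
                       AlleleCounts(1000, 10)),
     Annotation(gene="TP53", in_cosmic=True)),
    ("low VAF, concordant across compartments",
     PairedObservation(VariantKey("chr2", 25234374, "C", "T"),
                       AlleleCounts(1000, 11), AlleleCounts(500, 5)),
     Annotation(gene="DNMT3A")),
    ("cfDNA-enriched, Fisher p < 0.05",
     PairedObservation(VariantKey("chr12", 25398284, "C", "T"),
                       AlleleCounts(1000, 60), AlleleCounts(300, 2)),
     Annotation(gene="KRAS", in_cosmic=True)),
    ("PBL VAF 50%, no ClinVar pathogenic record",
     PairedObservation(VariantKey("chr13", 32907420, "G", "T"),
                       AlleleCounts(1000, 480), AlleleCounts(200, 100)),
     Annotation(gene="BRCA2", clinvar=Clinvar.NONE)),
]

for description, obs, ann in cases:
    rec = classify_variant(obs, ann)
    p = f"{rec.p_value:.3g}" if rec.p_value is not None else "-"
    orr = f"{rec.odds_ratio:.3g}" if rec.odds_ratio is not None else "-"
    print(f"{description:48s} -> {rec.label.value:20s} p={p:8s} OR={orr:8s} "
          f"reasons={','.join(rec.reasons)}")

print()
print("A variant is a CH candidate only when the cfDNA and PBL allele")
print("fractions are statistically concordant (p >= 0.05, OR in (0.5, 1.5))")
print("with >= 2 supporting reads in both compartments.")
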