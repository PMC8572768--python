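"""Actionable-mutation interference audit on final CH calls.

CH mutations that coincide with therapy-guiding somatic mutations can
mislead a plasma-only liquid biopsy.  This example overlaps a toy set
of final CH calls with a small knowledge base and prints which calls
would interfere with clinical interpretation.
"""

from chtriage import Annotation, ClassifiedVariant, Label, VariantKey
from chtriage.cohort import actionable_overlap
from chtriage.io import AnnotationMap

annotations = AnnotationMap({
    VariantKey("chr17", 7577120, "C", "A"): Annotation(gene="TP53"),
    VariantKey("chr12", 25398284, "C", "T"): Annotation(gene="KRAS"),
    VariantKey("chr2", 25234374, "C", "T"): Annotation(gene="DNMT3A"),
})

ch = lambda pid, v: ClassifiedVariant(pid, v, Label.CH, reasons=("ch_concordant",))
final_ch = [
    ch("P001", VariantKey("chr17", 7577120, "C", "A")),
    ch("P002", VariantKey("chr17", 7577120, "C", "A")),
    ch("P002", VariantKey("chr12", 25398284, "C", "T")),
    ch("P003", VariantKey("chr2", 25234374, "C", "T")),
]
kb = {
    VariantKey("chr17", 7577120, "C", "A"): "TP53 prognosis marker",
    VariantKey("chr12", 25398284, "C", "T"): "KRAS G12D - anti-EGFR resistance",
}

hits, per_gene, summary = actionable_overlap(final_ch, kb, annotations)
for h in hits:
    print(f"{h.gene:8s} {h.variant.chrom}:{h.variant.pos} {h.variant.ref}>"
          f"{h.variant.alt}  patients={','.join(h.patient_ids)}  [{h.assertion}]")
print(f"\n{summary['n_hit_variants']:.0f} of {summary['n_ch_variants']:.0f} CH variants "
      f"({summary['pct_hit_variants']:.1f}%) are actionable, affecting "
      f"{summary['n_hit_patients']:.0f} of {summary['n_ch_patients']:.0f} patients "
      f"({summary['pct_hit_patients']:.1f}%).")
print("These blood-derived calls would look like tumor mutations in a")
print("plasma-only assay; matched PBL sequencing exposes them as CH.")
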