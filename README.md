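# chtriage

Clonal hematopoiesis (CH) confounds liquid biopsy: blood-cell clones
carrying somatic mutations shed DNA into plasma, so a variant seen in
cell-free DNA (cfDNA) may come from the tumor, the germline, or the
hematopoietic compartment. `chtriage` implements the paired-sample
triage that separates the three using matched cfDNA and white-blood-cell
(PBL) panel sequencing, plus the cohort-level analytics built on top of
it, for groups running pan-cancer or screening cohorts with paired
plasma/buffy-coat panels.

## The decision procedure

For each variant called in a patient's cfDNA, with allele counts
(alt, ref) in each compartment:

1. **Not called in PBL** → candidate somatic; retained if cfDNA depth ≥
   100×, alt reads ≥ 2, VAF ≥ 0.3%, population MAF (gnomAD/ExAC) ≤
   0.2%, not dbSNP-without-COSMIC, not HLA.
2. **PBL depth ≥ 30× and PBL VAF ≥ 20%** → germline; retained only when
   ClinVar says pathogenic / likely pathogenic.
3. **PBL depth ≥ 30× and PBL VAF < 20%** → Fisher's exact test on the
   2×2 table of alt/ref counts in cfDNA vs PBL. If p ≥ 0.05 and the
   sample odds ratio OR = (a·d)/(b·c) satisfies 0.5 < OR < 1.5, the
   compartments are concordant → **candidate CH** (kept if ≥ 2 alt
   reads in both compartments). If p < 0.05 with OR > 1 (cfDNA-enriched)
   the variant re-enters the somatic filters; remaining discordant
   patterns are discarded with logged reasons.

Cohort-wide, candidate CH then passes a funnel: variants whose *carrier
ratio* (fraction of CH-positive patients carrying them) exceeds 0.25%
are removed as recurrent artifacts, and candidates also called somatic
in the patient's matched tumor are removed. Downstream analytics cover
the age–prevalence trend (Pearson r over age-group prevalences),
per-gene carrier summaries, CH/germline/somatic-preferred gene
labelling, two-cohort per-gene Fisher comparison with BH FDR,
actionable-mutation interference, and generic gene-set
over-representation on user-supplied GMT files.

A synthetic-cohort generator (`chtriage.simulate`) emulates the paired
binomial read-count model with known ground truth — germline near 50%
VAF in both blood compartments, CH sharing one low VAF between them,
somatic confined to cfDNA/tumor, planted recurrent artifacts, and CH
prevalence rising logistically with age — so the whole pipeline can be
scored end to end.

## Worked example

```
$ python examples/age_prevalence_trend.py
group  carriers  total  percent
 <=40       179    684    26.17
40-50       512   1685    30.39
50-60      1237   3207    38.57
60-70      1925   4015    47.95
70-80      1025   1795    57.10
80-90       217    332    65.36
  >90         5      7    71.43

Pearson r (prevalence vs age-group index) = 0.997
```

The percentages are per-age-group CH prevalences; the correlation of
0.997 with the group index is the hallmark age-dependence of clonal
hematopoiesis. An end-to-end run on a synthetic cohort:

```
$ python examples/simulate_and_recover.py
simulated 1500 patients, 8621 planted variants ...
funnel: 923 candidates -> -138 min-alt -> -36 carrier-ratio -> -0 tumor -> 749 final CH
CH sensitivity (true VAF >= 2%): 0.82
somatic->CH leakage:             0.005
germline->CH calls:              0
artifact removal rate:           1.00
```

Every planted recurrent artifact is caught by the carrier-ratio filter
and no germline variant reaches the CH set; sensitivity is limited by
the odds-ratio window at 200× PBL depth (see `docs/methods.md`).

Other entry points: `examples/classify_paired_variants.py` (one
observation per triage branch) and `examples/actionable_interference.py`
(knowledge-base overlap). A thin CLI mirrors the library:
`chtriage run`, `chtriage simulate`, `chtriage evaluate`,
`chtriage compare`, `chtriage interference`, `chtriage enrich`, and
`chtriage stats fisher A B C D`.

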