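# Methods

## Model and assumptions

The triage treats each called variant in a patient as a pair (or
triple) of binomial read-count observations: alt reads out of total
depth in cfDNA, PBL, and optionally tumor tissue. Three generative
hypotheses are distinguished by the PBL compartment. Germline variants
are heterozygous in every nucleated cell, so both blood compartments
sit near 50% VAF. CH variants arise in hematopoietic stem-cell clones;
because plasma cfDNA in these panels is overwhelmingly hematopoietic,
a CH clone contributes the *same* expected allele fraction to cfDNA
and PBL — this equality is the null hypothesis of the per-variant
Fisher test. Tumor-derived somatic variants have expected PBL VAF of
zero (only sequencing error appears there) and are usually not called
in PBL at all.

The decision procedure conditions on compartment presence first (a
panel caller emits only calls, so "absent from the PBL table" and
"called with 0 alt reads" are distinct states), then on PBL VAF, then
on the exact test. Thresholds are strict or inclusive exactly as the
pipeline defines them: "at least"/"not smaller than" bounds are ≥,
the 20% germline VAF split is `< 0.20` vs `≥ 0.20`, the odds-ratio
window is strictly inside (0.5, 1.5), and the carrier-ratio cutoff is
strictly greater than 0.25%.

Two cases the three-way rule does not define — significant PBL
enrichment (p < 0.05 with OR ≤ 1), and a non-significant test with OR
outside the window — are assigned `DISCORDANT_DISCARD` with a logged
reason and excluded from all downstream tallies. Calling them CH would
contradict the test; calling them somatic is stated only for the
cfDNA-enriched significant case.

## Exact statistics

`fisher_exact` computes the two-sided p-value by the point-probability
method: the sum over the hypergeometric support of all point
probabilities not exceeding the observed one, with ties admitted at a
relative tolerance of 1e-7 (floating-point tie robustness). Log-gamma
arithmetic over the support keeps the computation exact to ~1e-13 for
the margins this pipeline sees. Two odds-ratio estimates are always
reported: the cross-product sample OR, with a Haldane–Anscombe 0.5
added to every cell iff any cell is zero (the triage window consumes
this one), and the conditional-MLE OR of the noncentral hypergeometric
model, solved by bisection on the conditional mean to a relative
tolerance of 1e-9, with the conventional 0 and ∞ at the support
boundaries. An independent enumeration oracle in exact rational
arithmetic (`fisher_oracle`) backs the test suite; scipy's
implementations serve as a second cross-check there. BH FDR is
delegated to statsmodels, Pearson correlation to scipy.

The interference audit's per-gene enrichment 2×2 — not fully specified
by the triage rules — compares hit patients in a gene vs hit patients
in other genes against non-hit CH carriers of that gene vs the rest,
BH-corrected across hit genes. Actionable matching keys on chromosome,
position and alternate allele (the reference allele is implied by the
position).

## Cohort analytics choices

* Carrier-ratio denominator: patients with ≥ 1 candidate CH after the
  min-alt-read rule, computed once; the filter is applied a single
  time, not iterated to a fixed point.
* Age bins are right-closed, `[0,40], (40,50], …, (90,∞)`; the Pearson
  x-variable is the 1-based group index (equal spacing makes index and
  midpoint equivalent); groups with zero patients are excluded, and r
  is reported absent with < 3 usable groups or constant prevalence.
* The cohort-level prevalence comparison reports the *prevalence
  ratio* (pA/pB) and the cross-product OR side by side: the two
  estimands differ (0.921 vs 0.908 on the published counts) and are
  labelled distinctly.
* Preferred-class labelling counts occurrences at patient level (one
  determination per patient per variant); a class needs a strict
  majority (> 50%); gene-level ties (equal germline- and
  somatic-preferred counts with CH-preferred present) stay unlabeled.
* The two-cohort gene comparison defaults to genes carrying CH in both
  cohorts; a caller-supplied gene list widens the universe.
* Tumor somatic calls for the crosscheck are derived as tumor-table
  variants absent from the same patient's PBL table, mirroring
  matched-normal somatic calling; a variant with PBL support is by
  construction not "called somatic from tissue".

## The synthetic cohort

Defaults are the study conditions where those are stated, and declared
package choices otherwise:

| parameter | default | note |
|---|---|---|
| depths (PBL / cfDNA / tumor) | Poisson, mean 200 / 1000 / 1000× | panel sequencing floors |
| base error rate e | 0.001 | alt reads ~ Binomial(depth, v + e(1−v)) |
| ages | uniform 30–90 | |
| P(≥1 CH \| age) | logistic, intercept −2.25, slope 0.0344/yr | calibrated to ≈26% at 35 yr, ≈71% at 92 yr |
| CH per carrier | 1–4 with P = (0.60, 0.25, 0.10, 0.05) | one or two mutations dominate |
| CH VAF | log-uniform [0.005, 0.20) | shared by both blood compartments |
| germline | 2 per patient, VAF ~ Beta(50, 50) | ClinVar-pathogenic with P = 0.3 |
| somatic | 3 per patient, cfDNA VAF log-uniform [0.003, 0.30] | tumor VAF ×10, capped at 0.5; PBL VAF 0 |
| artifacts | 3 variants, each in 2% of CH carriers | CH-like VAF 0.05 in both compartments |
| tumor samples | 30% of patients | |

A variant enters a compartment's call table iff it drew ≥ 1 alt read
there, reproducing the caller convention that absence is informative.
Overdispersion (beta-binomial) and a cfDNA/PBL compartment shift exist
as knobs for robustness experiments and default to off: the default
generator realizes exactly the binomial model the exact test assumes.
Planted variants default to neutral annotations (no population MAF, no
dbSNP/HLA/blacklist flags, non-synonymous consequences), so the
recovery benchmark measures the statistical core; the deterministic
annotation-driven filters are exercised by dedicated fixtures instead.

What the generator does **not** emulate: shared hotspot variants across
patients (each non-artifact variant is private, so polymorphic-variant
labelling is tested on constructed fixtures), UMI/duplex error
structure, GC- or fragment-length-dependent coverage, tumor
contamination of the buffy coat, and CH signal in tumor tissue.
Passing recovery bands therefore demonstrate the pipeline's behavior
under its own model assumptions, not performance on real libraries.

## Known limitations and measured operating characteristics

At 200× PBL depth the sample OR of a true CH variant with VAF v has
log-scale counting noise ≈ √(1/(1000·v) + 1/(200·v)), so for v near 2%
(~4 expected PBL alt reads) a substantial fraction of true CH falls
outside the (0.5, 1.5) window even though the concordance null is
true, and near the 20% VAF boundary sampled PBL VAF can cross into the
germline branch. On default cohorts of 2000 patients averaged over ten
seeds the pipeline measures: final-CH sensitivity ≈ 0.80 for true
VAF ≥ 2% (≈ 0.67 over all CH), somatic→CH leakage < 1%, zero
germline→CH calls, and 100% removal of planted recurrent artifacts.
Sensitivity at low VAF is a power property of the window-plus-test
rule at these depths, not an implementation artifact; deeper PBL
sequencing or a widened window would trade it against artifact and
somatic leakage.

Indel normalization (left-alignment) is assumed done upstream; variant
identity is exact string equality on (chrom, pos, ref, alt). Problem
sizes in the test and acceptance suites (cohorts of 1500–2000 patients,
ten seeds) were chosen so that a private candidate variant sits below
the 0.25% carrier-ratio cutoff, matching the regime the filter was
designed for.
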