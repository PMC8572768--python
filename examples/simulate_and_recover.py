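"""End-to-end run on a synthetic cohort with known ground truth.

Simulates a 1500-patient paired-compartment cohort, classifies every
called variant, applies the candidate-CH funnel (min alt reads ->
carrier-ratio filter -> tumor crosscheck), and scores recovery against
the generator's truth labels.
"""

from chtriage import SimulationConfig, evaluate_calls, simulate_cohort
from chtriage.cohort import age_trend, apply_funnel
from chtriage.simulate import tumor_somatic_calls
from chtriage.triage import classify_patient

cohort = simulate_cohort(SimulationConfig(n_patients=1500, seed=42))
print(f"simulated {len(cohort.patients)} patients, "
      f"{len(cohort.truth)} planted variants "
      f"({dict(cohort.truth['true_class'].value_counts())})")

classified = []
for patient in cohort.patients:
    classified.extend(classify_patient(patient, cohort.annotations))

final_ch, funnel, removed = apply_funnel(classified,
                                         tumor_somatic_calls(cohort.calls))
print(f"funnel: {funnel.candidates_in} candidates -> "
      f"-{funnel.removed_min_alt} min-alt -> "
      f"-{funnel.removed_carrier_ratio} carrier-ratio -> "
      f"-{funnel.removed_tumor} tumor -> {funnel.ch_final} final CH")

metrics = evaluate_calls(cohort.truth, classified, final_ch, removed)
print(f"CH sensitivity (true VAF >= 2%): {metrics['ch_sensitivity_above_vaf']:.2f}")
print(f"somatic->CH leakage:             {metrics['somatic_to_ch_leakage']:.3f}")
print(f"germline->CH calls:              {metrics['germline_to_ch']}")
print(f"artifact removal rate:           {metrics['artifact_removal_rate']:.2f}")

table, r = age_trend(cohort.patients, final_ch)
print(f"recovered age-prevalence Pearson r: {r:.2f}")
print("\nLeakage and germline contamination stay near zero; sensitivity is")
print("bounded by the odds-ratio window at the 200x PBL depth.")
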