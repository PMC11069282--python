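"""Per-patient glycemic indexes, including the estimated pre-hospital CV.

For one patient: the HbA1c-derived pre-admission mean glucose, the
in-hospital mean/SD/CV, and the novel index — in-hospital glucose SD over
the pre-admission mean, as a percentage.  A high value says the inpatient
glucose swings are large relative to the patient's chronic glycemic level.
"""

from glycostrat import CohortSpec, generate_cohort, summarize_glycemia, charlson_index

rec = generate_cohort(CohortSpec(n_patients=5, seed=1))[0]
s = summarize_glycemia(rec)

print(f"patient {rec.patient_id}: HbA1c {rec.hba1c:.1f} %")
print(f"pre-admission mean glucose (28.7*A1c - 46.7): {s.pre_mean_glucose:.1f} mg/dl")
print(f"in-hospital mean / median: {s.in_mean:.1f} / {s.in_median:.1f} mg/dl")
print(f"glycemic variability (sample SD):             {s.in_sd:.1f} mg/dl")
print(f"in-hospital CV:                               {s.in_cv:.1f} %")
print(f"estimated pre-hospital CV (SD/pre-mean):      {s.est_pre_cv:.1f} %")
print(f"in/pre mean ratio:                            {s.ratio_in_pre:.2f}")
print(f"Hirsch rule satisfied (SD <= mean/3):         {s.hirsch_ok}")
print(f"Charlson comorbidity index:                   "
      f"{charlson_index(rec.comorbidities, rec.age)}")
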