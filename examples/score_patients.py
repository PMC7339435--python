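"""Score individual patients on the four stroke-mimic prediction scales.

Builds two contrasting presentations and prints each scale's value.
FABS, simplified FABS and the Khan score rise with mimic-likeness;
the TeleStroke Mimic Score (TMS) falls.
"""

from mimicscale import PatientRecord, fabs, khan, sfabs, tms

typical_stroke = PatientRecord(
    patient_id="example-stroke", age=74, sex="male", sbp=176, dbp=95, nihss=18,
    facial_droop=True, isolated_sensory_deficit=False, atrial_fibrillation=True,
    hypertension=True, hyperlipidemia=True, diabetes=False, migraine=False,
    seizure_history=False, psychiatric_history=False, label="stroke",
)

likely_mimic = PatientRecord(
    patient_id="example-mimic", age=36, sex="female", sbp=128, dbp=78, nihss=3,
    facial_droop=False, isolated_sensory_deficit=True, atrial_fibrillation=False,
    hypertension=False, hyperlipidemia=False, diabetes=False, migraine=True,
    seizure_history=False, psychiatric_history=True, label="mimic",
)

print(f"{'scale':<8}{'typical stroke':>16}{'likely mimic':>15}")
for name, fn in [("FABS", fabs), ("sFABS", sfabs), ("TMS", tms), ("Khan", khan)]:
    print(f"{name:<8}{fn(typical_stroke):>16}{fn(likely_mimic):>15}")

print()
print("Higher FABS/sFABS/Khan and lower TMS point toward a stroke mimic:")
print("the young migrainous patient scores FABS 5, sFABS 4, Khan 8 with")
print("TMS 7.2, while the elderly hypertensive AF patient scores 0 on all")
print("three mimic-positive scales with TMS 37.8.")
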