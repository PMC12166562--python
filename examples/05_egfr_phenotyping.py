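"""CKD-EPI eGFR and incident-CKD classification from creatinine visits.

Incident CKD is a first eGFR crossing below 60 mL/min/1.73 m² during
follow-up among subjects at or above 60 at baseline; subjects already
below 60 at baseline are excluded from the risk set.
"""

from nutrimr.phenotypes import (
    SubjectVisits,
    classify_incident_ckd,
    creatinine_for_egfr,
    egfr_ckd_epi,
)

print(f"eGFR(scr=0.7, age=50, female) = {egfr_ckd_epi(0.7, 50, 'female'):.1f}")
print(f"eGFR(scr=0.9, age=60, male)   = {egfr_ckd_epi(0.9, 60, 'male'):.1f}")
print(f"eGFR(scr=1.4, age=65, male)   = {egfr_ckd_epi(1.4, 65, 'male'):.1f}")

# build a declining trajectory: 90 → 75 → 58 over six years
subject = SubjectVisits(
    subject_id="s001",
    sex="male",
    visits=tuple(
        (t, creatinine_for_egfr(e, 55 + t, "male"), 55 + t)
        for t, e in [(0.0, 90.0), (2.0, 75.0), (6.0, 58.0)]
    ),
)
print(f"\ntrajectory 90 → 75 → 58: {classify_incident_ckd(subject).value}")

# The subject starts above the threshold and crosses below 60 at the third
# visit, so they count as an incident case; a single qualifying visit
# suffices under the phenotype definition used here.
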