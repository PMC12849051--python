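"""Score every risk model for one hand-built patient record.

A 44-year-old premenopausal woman with CA 125 of 100 IU/mL, HE4 of 60 pmol/L
and a multilocular, partly solid lesion with ascites and one malignant
ultrasound feature.
"""

from ovarisk import (
    UltrasoundExam,
    compute_rmi,
    compute_roma,
    compute_simple_rules,
    compute_u_score,
    dichotomize_score,
    load_coefficients,
    map_orads,
)

exam = UltrasoundExam(
    lesion_present=True,
    max_lesion_diameter=80.0,
    max_solid_diameter=40.0,
    multilocular=True,
    solid_areas=True,
    bilateral=False,
    ascites=True,
    metastases=False,
    more_than_10_locules=False,
    papillation_count=1,
    acoustic_shadows=False,
    benign_features=frozenset(),
    malignant_features=frozenset({"M1"}),
)

u = compute_u_score(exam)
rmi = compute_rmi(ca125=100.0, u=u, menopausal_status="premenopausal")
roma = compute_roma(100.0, 60.0, "premenopausal", load_coefficients("roma"))
sr = compute_simple_rules(exam)
orads = map_orads(exam)

print(f"U-score: {u} (multilocular + solid areas + ascites -> 3 features -> U=3)")
print(f"RMI 1: {rmi.numeric_value:.0f} -> {dichotomize_score(rmi, 250.0).state} at the 250 threshold")
print(f"ROMA: {roma.numeric_value:.1f}% risk of malignancy (premenopausal stratum)")
print(f"Simple rules: {sr.category} (M-feature present, no B-feature)")
print(f"ORADS category: {orads.category} -> {dichotomize_score(orads).state} (positive iff 4-5)")
# RMI = U x M x CA125 = 3 x 1 x 100 = 300: above the 250 referral threshold,
# so this patient would be triaged to a gynaecological cancer centre.
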