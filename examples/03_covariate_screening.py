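"""Collinearity screening: why a BMI-for-age z-score replaces height x weight.

Height, weight and age are strongly collinear in a growing cohort, so a
design containing height, weight and their product is unusable for
regression (huge GVIF).  Replacing the anthropometrics with a single
BMI-for-age z-score collapses the worst scaled GVIF below the strict
acceptability bound of 3.
"""

from microzinb import classify_zbmi, generate_covariates, screen_interactions, synthetic_lms_reference

cov = generate_covariates(800, seed=11)
report = screen_interactions(
    cov,
    {
        "height*weight": ["age", "ethnic", "geography", "height", "weight", "height:weight"],
        "bmiaz": ["age", "ethnic", "geography", "bmiaz"],
    },
)
print(report.round(3).to_string(index=False))
print("acceptable = max GVIF^(1/(2 df)) strictly below 3\n")

ref = synthetic_lms_reference()
bmi = 22.4
z = ref.zscore("bmi", "M", age_months=120, x=bmi)
print(f"BMI {bmi} kg/m2 for a 10-year-old boy -> z = {z:.2f} -> {classify_zbmi(z)}")
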