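"""Published summary statistics used in the worked examples.

These are group-level counts and moments from a multicenter survey of
1,101 caregivers of psychiatric inpatients (208 of whom screened positive
for insomnia symptoms).  They are *inputs* for the summary-statistic
routines — prevalence intervals, chi-square tests from contingency tables,
t tests from group moments — not outputs of this package.
"""

from __future__ import annotations

CAREGIVER_N = 1101

#: insomnia-severity head-counts: any symptoms, subthreshold, moderate, severe
CAREGIVER_SEVERITY_COUNTS = {
    "any": 208,
    "subthreshold": 157,
    "moderate": 44,
    "severe": 7,
}

#: 2 x c contingency tables, rows = (without insomnia, with insomnia)
CAREGIVER_TABLES = {
    "gender_male": [[345, 548], [97, 111]],
    "married": [[740, 153], [163, 45]],
    "employed": [[726, 167], [168, 40]],
    "education_high": [[547, 346], [130, 78]],
    "rural": [[387, 506], [81, 127]],
    "physical_disease": [[35, 858], [17, 191]],
    "access_difficulty": [[245, 648], [82, 126]],
    "financial_status": [[172, 623, 98], [62, 137, 9]],
    "social_media": [[72, 278, 543], [13, 78, 117]],
    "diagnosis": [[317, 123, 191, 262], [83, 39, 31, 55]],
    "adherence": [[634, 259], [141, 67]],
}

#: (mean, sd, n) per group for the continuous contrasts
CAREGIVER_MOMENTS = {
    "age": {"without": (42.99, 11.337, 893), "with": (43.34, 12.892, 208)},
    "qol": {"without": (6.90, 1.554, 893), "with": (5.10, 1.409, 208)},
}
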