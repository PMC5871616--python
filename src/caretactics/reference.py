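"""Published demographic estimates for the south-central Swedish brown bear
population (females, 1993-2015), used as default simulator parameters and as
inputs for the worked examples.

``SURVIVAL_MEANS`` / ``RECRUITMENT_MEANS`` are the bootstrapped model-based
predictions of tactic- and age-class-specific annual survival and recruitment
(yearling daughters per female-year). ``SURVIVAL_MODEL`` / ``RECRUITMENT_MODEL``
are the fitted-model coefficients on the link scale (logit survival with
reference level 1.5-year tactic x yearling; log-link recruitment with
reference 1.5-year tactic).
"""

from __future__ import annotations

from .records_io import T15, T25

# Mean annual survival probability by tactic and age class.
SURVIVAL_MEANS = {
    T15: {"1": 0.809, "2": 0.844, "3": 0.916, "4-8": 0.973, "9+": 0.841},
    T25: {"1": 0.903, "2": 0.922, "3": 0.961, "4-8": 0.988, "9+": 0.920},
}

# 95% CI bounds for the same cells (lower, upper).
SURVIVAL_CIS = {
    T15: {
        "1": (0.739, 0.874),
        "2": (0.767, 0.911),
        "3": (0.851, 0.974),
        "4-8": (0.947, 0.994),
        "9+": (0.789, 0.889),
    },
    T25: {
        "1": (0.833, 0.951),
        "2": (0.860, 0.966),
        "3": (0.914, 0.988),
        "4-8": (0.971, 0.997),
        "9+": (0.874, 0.957),
    },
}

# Mean yearling daughters per female-year; age classes 5-9 and 10+ share one
# value (age class had no significant effect on recruitment).
RECRUITMENT_MEANS = {T15: 0.384, T25: 0.251}
RECRUITMENT_CIS = {T15: (0.296, 0.482), T25: (0.167, 0.351)}

# Survival model, logit scale: intercept = yearling on the 1.5-year tactic.
SURVIVAL_MODEL = {
    "intercept": 1.430,
    "tactic_T25": 0.761,
    "age_2": 0.238,
    "age_3": 0.932,
    "age_4-8": 2.124,
    "age_9+": 0.224,
}
SURVIVAL_MODEL_CIS = {
    "intercept": (1.015, 1.887),
    "tactic_T25": (0.214, 1.365),
    "age_2": (-0.434, 0.934),
    "age_3": (0.099, 1.887),
    "age_4-8": (1.219, 3.230),
    "age_9+": (-0.335, 0.769),
}

# Recruitment model, log scale: intercept = 1.5-year tactic.
RECRUITMENT_MODEL = {"intercept": -0.923, "tactic_T25": -0.425}
RECRUITMENT_MODEL_CIS = {"intercept": (-1.154, -0.697), "tactic_T25": (-0.860, -0.003)}

# Protective-effect counts: hunting deaths / adult bear-years by status.
PROTECTION_COUNTS = {
    "solitary": {"bear_years": 407, "hunting_deaths": 55},
    "family_group": {"bear_years": 207, "hunting_deaths": 9},
}
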