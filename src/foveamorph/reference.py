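"""Reference cohort summary statistics used to calibrate the simulator.

Two groups of 6.5-year-old children are modelled: full-term controls
(left eyes, n = 92) and children born extremely preterm (< 27 gestational
weeks) without retinopathy of prematurity ("EPT-NoROP", both eyes,
n = 37 from 21 children).  The per-parameter means and SDs below are the
marginal calibration targets of :mod:`foveamorph.simulate`; the printed
control limits, outside-proportions and subgroup factor summaries are
kept for cross-checking recomputed values, never as substitutes for them.

All thicknesses are in micrometres.  Parameter keys:

``GCLp_FC``
    ganglion cell + inner plexiform layer (GCL+) thickness at the foveal
    centre (FC)
``GCLp_Q2Q``
    GCL+ thickness averaged over the nasal and temporal quarter points
    between FC and the foveal wall maximum
``ONL_FC``
    outer nuclear layer thickness at FC
``RT_FC``
    full retinal thickness (ILM to posterior RPE) at FC
``FD``
    foveal depth = mean nasal/temporal rim retinal thickness − RT at FC
"""

from __future__ import annotations

# Directly sampled parameters (RT_FC and RT_FWM are structural sums).
SAMPLED_PARAMS = ("GCLp_FC", "GCLp_Q2Q", "ONL_FC", "FD")

# The five normative parameters reported per eye.
REPORTED_PARAMS = ("GCLp_FC", "GCLp_Q2Q", "ONL_FC", "RT_FC", "FD")

CONTROL_MEANS = {"GCLp_FC": 3.47, "GCLp_Q2Q": 10.23, "ONL_FC": 107.78, "FD": 131.15}
CONTROL_SDS = {"GCLp_FC": 2.11, "GCLp_Q2Q": 4.76, "ONL_FC": 12.43, "FD": 16.73}

EPT_MEANS = {"GCLp_FC": 13.95, "GCLp_Q2Q": 27.19, "ONL_FC": 150.52, "FD": 89.46}
EPT_SDS = {"GCLp_FC": 11.66, "GCLp_Q2Q": 11.59, "ONL_FC": 26.75, "FD": 22.98}

# Printed retinal thickness at FC per group.  The control SD is consistent
# with its printed range; the EPT SD (4.49) is not (range 192.72-303.95
# implies an SD an order of magnitude larger) and is therefore stored only
# for display.  RT_FC is simulated as GCL+ + ONL + residual layers, whose
# mean is fixed so the group RT_FC mean is reproduced exactly:
# 208.36 - 3.47 - 107.78 = 97.11 and 247.09 - 13.95 - 150.52 = 82.62.
CONTROL_RT_MEAN = 208.36
CONTROL_RT_SD_PRINTED = 12.53
EPT_RT_MEAN = 247.09
EPT_RT_SD_PRINTED = 4.49  # internally inconsistent; do not calibrate to it

CONTROL_RESIDUAL_MEAN = 97.11
CONTROL_RESIDUAL_SD = 8.0
EPT_RESIDUAL_MEAN = 82.62
EPT_RESIDUAL_SD = 10.0

#: Published normative limits (control mean ± 2 SD, rounded to 0.1 µm as
#: printed).  Note the ONL_FC entry is internally inconsistent with the
#: printed control mean/SD (107.78 + 2*12.43 = 132.64); recomputation
#: flags it, see :func:`foveamorph.normative.compare_with_published`.
PUBLISHED_LIMITS = {
    "GCLp_FC": 7.7,
    "GCLp_Q2Q": 19.7,
    "ONL_FC": 136.9,
    "RT_FC": 233.4,
    "FD": 97.7,
}

#: Published percentage of EPT-NoROP eyes outside the control limit.
#: These depend on the real cohort's empirical distribution and are
#: reproduced only qualitatively (majority outside for thicknesses).
PUBLISHED_PCT_OUTSIDE = {
    "GCLp_FC": 68.0,
    "GCLp_Q2Q": 73.0,
    "ONL_FC": 76.0,
    "RT_FC": 68.0,
    "FD": 51.0,
}

#: Published per-group layer proportions (mean, SD) of central thickness.
PUBLISHED_PROPORTIONS = {
    "EPT-NoROP": {"inner_plus_onl": (0.66, 0.08), "onl": (0.60, 0.04), "gclp": (0.06, 0.04)},
    "control": {"inner_plus_onl": (0.53, 0.04), "onl": (0.51, 0.03), "gclp": (0.02, 0.01)},
}

#: Printed parameter ranges per group (display only).
PUBLISHED_RANGES = {
    "control": {
        "GCLp_FC": (0.0, 9.1),
        "GCLp_Q2Q": (2.09, 21.30),
        "ONL_FC": (84.85, 141.63),
        "RT_FC": (182.48, 238.75),
        "FD": (90.9, 173.6),
    },
    "EPT-NoROP": {
        "GCLp_FC": (0.0, 42.12),
        "GCLp_Q2Q": (11.06, 55.01),
        "ONL_FC": (104.49, 208.66),
        "RT_FC": (192.72, 303.95),
        "FD": (38.40, 126.59),
    },
}

#: Associated-factor summaries for EPT-NoROP right eyes split by the
#: RT_FC control limit (outside n=12 vs within n=7), with the published
#: two-sided p-value for reference.  Used by the summary-statistics mode
#: of :func:`foveamorph.stats.group_compare_from_summary`.
SUBGROUP_FACTORS = [
    {"variable": "gestational_age_weeks", "mean1": 25.83, "sd1": 0.39, "n1": 12,
     "mean2": 25.71, "sd2": 0.49, "n2": 7, "published_p": 0.591},
    {"variable": "gestational_age_days", "mean1": 185.83, "sd1": 3.13, "n1": 12,
     "mean2": 184.57, "sd2": 3.87, "n2": 7, "published_p": 0.376},
    {"variable": "birth_weight_g", "mean1": 899.66, "sd1": 170.27, "n1": 12,
     "mean2": 875.42, "sd2": 95.23, "n2": 7, "published_p": 0.554},
    {"variable": "visual_acuity_decimal", "mean1": 0.81, "sd1": 0.17, "n1": 12,
     "mean2": 0.83, "sd2": 0.13, "n2": 7, "published_p": 0.891},
    {"variable": "refraction_se_diopters", "mean1": 1.41, "sd1": 1.04, "n1": 12,
     "mean2": 0.84, "sd2": 0.84, "n2": 7, "published_p": 0.307},
]
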