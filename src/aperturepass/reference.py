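"""Published group-level results for the real/virtual aperture-passage study.

These tables hold the fixed-effect estimates, odds ratios, and derived
critical values reported for the study this package models: a cohort
passing through 35-75 cm apertures in a real environment and a second
cohort in a faithfully reproduced virtual environment.  They serve two
purposes: (a) the generator presets are calibrated against the derived
critical values, and (b) the analytic identities of
:mod:`aperturepass.thresholds` (curve-shift algebra, odds-ratio identity)
can be cross-checked directly against print.

Keys follow the package's term naming: ``ax_ratio`` is the slope in the
centered aperture-to-body-width ratio; factors are coded -1/+1 with
randomized / real / increasing / body-not-visible at -1.
"""

from __future__ import annotations

#: Fixed-effect estimates of the combined (real vs. virtual) posture model.
COMBINED_ESTIMATES = {
    "shoulder": {
        "ax_ratio": -16.111, "environment": +1.777, "condition": -0.051,
        "order": +0.230, "fatigue": +0.209,
        "environment:order": -0.087, "condition:order": -0.022,
    },
    "thorax": {
        "ax_ratio": -16.415, "environment": +1.890, "condition": -0.107,
        "order": +0.260, "fatigue": +0.258,
        "environment:order": -0.060, "condition:order": -0.049,
    },
    "pelvis": {
        "ax_ratio": -12.213, "environment": +2.020, "condition": -0.006,
        "order": +0.257, "fatigue": -0.122,
        "environment:order": -0.048, "condition:order": -0.053,
    },
}

#: Published odds ratios for the combined model (same cells).
COMBINED_ODDS_RATIOS = {
    "shoulder": {
        "ax_ratio": 1.008e-7, "environment": 5.913, "condition": 0.950,
        "order": 1.258, "fatigue": 1.232,
        "environment:order": 0.916, "condition:order": 0.978,
    },
    "thorax": {
        "ax_ratio": 7.430e-8, "environment": 6.620, "condition": 0.898,
        "order": 1.298, "fatigue": 1.295,
        "environment:order": 0.942, "condition:order": 0.952,
    },
    "pelvis": {
        "ax_ratio": 4.965e-6, "environment": 7.537, "condition": 0.994,
        "order": 1.293, "fatigue": 0.885,
        "environment:order": 0.954, "condition:order": 0.949,
    },
}

#: Fixed-effect estimates of the visual-feedback (virtual-only) model.
FEEDBACK_ESTIMATES = {
    "shoulder": {
        "ax_ratio": -10.014, "body_visible": +0.400, "condition": +0.012,
        "order": +0.143, "fatigue": +0.768,
        "body_visible:order": -0.041, "condition:order": -0.067,
    },
    "thorax": {
        "ax_ratio": -10.321, "body_visible": +0.405, "condition": -0.002,
        "order": +0.154, "fatigue": +0.773,
        "body_visible:order": -0.065, "condition:order": -0.081,
    },
    "pelvis": {
        "ax_ratio": -8.779, "body_visible": +0.502, "condition": -0.088,
        "order": +0.141, "fatigue": +0.743,
        "body_visible:order": -0.061, "condition:order": -0.078,
    },
}

#: Published odds ratios for the visual-feedback model.
FEEDBACK_ODDS_RATIOS = {
    "shoulder": {
        "ax_ratio": 4.475e-5, "body_visible": 1.490, "condition": 1.012,
        "order": 1.154, "fatigue": 2.156,
        "body_visible:order": 0.960, "condition:order": 0.935,
    },
    "thorax": {
        "ax_ratio": 3.293e-5, "body_visible": 1.499, "condition": 0.998,
        "order": 1.167, "fatigue": 2.166,
        "body_visible:order": 0.937, "condition:order": 0.922,
    },
    "pelvis": {
        "ax_ratio": 1.540e-4, "body_visible": 1.653, "condition": 0.916,
        "order": 1.152, "fatigue": 2.102,
        "body_visible:order": 0.941, "condition:order": 0.925,
    },
}

#: Critical shoulder A/S values (5% of maximum rotation), percent of
#: shoulder width, as reported alongside the combined and feedback models.
CRITICAL_VALUES_PCT = {
    "combined": {
        "reference_real": 120.7,
        "reference_virtual": 142.8,
        "order_increasing": 130.3,
        "order_decreasing": 133.2,
        "point_of_change_real": 102.4,
        "point_of_change_virtual": 124.5,
    },
    "feedback": {
        "body_invisible": 154.0,
        "body_visible": 162.0,
        "order_increasing": 156.6,
        "order_decreasing": 159.4,
        "fatigue_first_sequence": 150.3,
        "fatigue_last_sequence": 165.7,
        "per_sequence_pct": 0.67,
    },
}

#: Sequences per experiment (fatigue code span).
N_SEQUENCES = {"exp1": 15, "exp2": 24}
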