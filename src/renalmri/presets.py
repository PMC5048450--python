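"""Reference parameter values for the synthetic kidney phantom.

These are typical rat renal values measured at 1.5 T: IVIM perfusion fraction,
tissue diffusion and pseudodiffusion coefficients per region, baseline T2*,
and the characteristic responses to three vasomodulating drugs (hydralazine, a
systemic vasodilator; furosemide, a loop diuretic; angiotensin II, a
vasoconstrictor).  The phantom uses them as ground truth so that parameter
recovery can be checked against known region values, and challenge transforms
are encoded as pre-to-post multiplicative factors derived from the pre/post
region values below.

All diffusion coefficients are in internal units (mm^2/s); f is a fraction;
T2* is in ms.
"""

from __future__ import annotations

from .signal_models import IvimParams, T2StarParams

__all__ = [
    "DRUGS",
    "baseline_ivim",
    "baseline_t2star",
    "challenge_pre_ivim",
    "challenge_ivim_multipliers",
    "t2star_timecourse_ms",
    "t2star_timecourse_multipliers",
    "TIMEPOINT_LABELS",
]

#: Recognised challenge arms (``"none"`` is the identity / repeatability arm).
DRUGS = ("none", "hydralazine", "furosemide", "angiotensin_ii")

#: Post-administration BOLD timepoint labels (elapsed time of each repeat).
TIMEPOINT_LABELS = ("2m15s", "6m51s", "11m24s")

_DEFAULT_S0 = 1000.0

# Baseline (repeatability scan 1) IVIM values per region: f, D (mm^2/s), D* (mm^2/s).
_BASELINE_IVIM = {
    "whole_kidney": (0.269, 1.245e-3, 4.0e-2),
    "cortex": (0.271, 1.050e-3, 3.7e-2),
    "medulla": (0.234, 1.330e-3, 4.2e-2),
}

#: Baseline whole-kidney T2* (ms) per study arm (first timepoint, pre drug).
_BASELINE_T2STAR = {
    "none": 32.8,
    "hydralazine": 37.7,
    "furosemide": 38.5,
    "angiotensin_ii": 34.5,
}

# Whole-kidney T2* (ms) at baseline then the three post-administration repeats.
_T2STAR_TIMECOURSE = {
    "none": (32.8, 33.3, 33.7, 33.5),
    "hydralazine": (37.7, 36.7, 34.5, 30.2),
    "furosemide": (38.5, 44.7, 48.5, 47.8),
    "angiotensin_ii": (34.5, 29.8, 29.4, 30.7),
}

# Pre/post challenge IVIM values per drug and region: {(drug, region): ((f, d, d*) pre, (f, d, d*) post)}.
_CHALLENGE_IVIM = {
    ("hydralazine", "whole_kidney"): ((0.109, 1.339e-3, 4.0e-2), (0.151, 1.002e-3, 5.0e-2)),
    ("hydralazine", "cortex"): ((0.174, 1.303e-3, 3.3e-2), (0.244, 0.968e-3, 5.0e-2)),
    ("hydralazine", "medulla"): ((0.072, 1.393e-3, 4.3e-2), (0.083, 1.096e-3, 4.9e-2)),
    ("furosemide", "whole_kidney"): ((0.120, 1.188e-3, 3.6e-2), (0.101, 1.388e-3, 3.8e-2)),
    ("furosemide", "cortex"): ((0.171, 1.175e-3, 3.2e-2), (0.120, 1.374e-3, 3.7e-2)),
    ("furosemide", "medulla"): ((0.096, 1.235e-3, 3.8e-2), (0.082, 1.416e-3, 3.6e-2)),
    ("angiotensin_ii", "whole_kidney"): ((0.193, 1.188e-3, 4.3e-2), (0.187, 1.150e-3, 5.1e-2)),
    ("angiotensin_ii", "cortex"): ((0.239, 1.164e-3, 4.2e-2), (0.216, 1.107e-3, 4.5e-2)),
    ("angiotensin_ii", "medulla"): ((0.153, 1.291e-3, 4.3e-2), (0.133, 1.238e-3, 5.2e-2)),
}


def baseline_ivim(region: str = "whole_kidney", s0: float = _DEFAULT_S0) -> IvimParams:
    """Baseline IVIM ground truth for a region (repeatability conditions)."""
    f, d, d_star = _BASELINE_IVIM[region]
    return IvimParams(s0=s0, f=f, d=d, d_star=d_star)


def baseline_t2star(drug: str = "none", s0: float = _DEFAULT_S0) -> T2StarParams:
    """Baseline whole-kidney T2* ground truth for a study arm."""
    return T2StarParams(s0=s0, t2_star=_BASELINE_T2STAR[drug])


def challenge_pre_ivim(drug: str, region: str = "whole_kidney", s0: float = _DEFAULT_S0) -> IvimParams:
    """Pre-administration IVIM ground truth for a challenge arm and region."""
    if drug == "none":
        return baseline_ivim(region, s0=s0)
    (f, d, d_star), _ = _CHALLENGE_IVIM[(drug, region)]
    return IvimParams(s0=s0, f=f, d=d, d_star=d_star)


def challenge_ivim_multipliers(drug: str, region: str = "whole_kidney") -> dict[str, float]:
    """Pre-to-post multiplicative factors for f, d and d_star.

    E.g. hydralazine reduces whole-kidney D by a factor 1.002/1.339 ~ 0.748
    while increasing f and D*.
    """
    if drug == "none":
        return {"f": 1.0, "d": 1.0, "d_star": 1.0}
    pre, post = _CHALLENGE_IVIM[(drug, region)]
    return {name: post[i] / pre[i] for i, name in enumerate(("f", "d", "d_star"))}


def t2star_timecourse_ms(drug: str) -> tuple[float, ...]:
    """Whole-kidney T2* (ms) at baseline and the three post timepoints."""
    return _T2STAR_TIMECOURSE[drug]


def t2star_timecourse_multipliers(drug: str) -> tuple[float, ...]:
    """T2* multipliers (relative to baseline) for the three post timepoints."""
    baseline, *post = _T2STAR_TIMECOURSE[drug]
    return tuple(v / baseline for v in post)
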