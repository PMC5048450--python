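"""Closed-form forward models for renal diffusion-weighted and BOLD signal decay.

The diffusion signal in well-perfused tissue such as kidney is modelled with the
two-compartment intravoxel incoherent motion (IVIM) form

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ]

where ``D`` is the tissue water diffusion coefficient, ``D*`` the pseudodiffusion
coefficient of the incoherent-flow (vascular/tubular) compartment and ``f`` its
signal fraction at b = 0.  The perfusion-insensitive apparent diffusion
coefficient (ADC) uses the monoexponential form ``S(b) = S0 * exp(-b * ADC)``,
and the multi-gradient-echo BOLD signal decays as ``S(TE) = S0 * exp(-TE/T2*)``.

Internal units are mm^2/s for diffusion coefficients and ms for relaxation
times; the conventional reporting scales (x1e-5 mm^2/s for D and ADC,
x1e-2 mm^2/s for D*, x1e-4 mm^2/s for the flow product fD*, percent for f)
are applied only at the reporting boundary via :data:`REPORT_SCALE`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DWI_B_VALUES",
    "BOLD_ECHO_TIMES",
    "REPORT_SCALE",
    "REPORT_UNITS",
    "IvimParams",
    "MonoexpParams",
    "T2StarParams",
    "DecayCurve",
    "ivim_signal",
    "monoexp_signal",
    "t2star_signal",
    "flow_product",
    "to_report_units",
]

#: Default 9-point diffusion-weighting scheme (s/mm^2), as used clinically.
DWI_B_VALUES: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 200.0, 400.0, 800.0)

#: Default 5-echo gradient-echo scheme (ms) for T2* mapping.
BOLD_ECHO_TIMES: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0, 40.0)

#: Multiplicative factor taking internal units to conventional reporting units.
REPORT_SCALE: dict[str, float] = {
    "f": 1e2,        # fraction -> %
    "d": 1e5,        # mm^2/s -> x1e-5 mm^2/s
    "adc": 1e5,      # mm^2/s -> x1e-5 mm^2/s
    "d_star": 1e2,   # mm^2/s -> x1e-2 mm^2/s
    "f_d_star": 1e4, # mm^2/s -> x1e-4 mm^2/s
    "t2_star": 1.0,  # ms
    "s0": 1.0,       # a.u.
}

REPORT_UNITS: dict[str, str] = {
    "f": "%",
    "d": "1e-5 mm^2/s",
    "adc": "1e-5 mm^2/s",
    "d_star": "1e-2 mm^2/s",
    "f_d_star": "1e-4 mm^2/s",
    "t2_star": "ms",
    "s0": "a.u.",
}


def to_report_units(parameter: str, value):
    """Convert an internal-unit value of ``parameter`` to reporting units."""
    try:
        scale = REPORT_SCALE[parameter]
    except KeyError:
        raise ValueError(f"unknown parameter {parameter!r}") from None
    return value * scale


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class IvimParams:
    """Biexponential IVIM parameters in internal units.

    Attributes
    ----------
    s0 : signal amplitude at b = 0 (a.u., > 0)
    f : perfusion (fast-compartment) fraction, stored in [0, 1]
    d : tissue diffusion coefficient (mm^2/s, > 0)
    d_star : pseudodiffusion coefficient (mm^2/s, > 0)
    """

    s0: float
    f: float
    d: float
    d_star: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.s0) and self.s0 > 0, f"s0 must be > 0, got {self.s0}")
        _require(np.isfinite(self.f) and 0.0 <= self.f <= 1.0, f"f must lie in [0, 1], got {self.f}")
        _require(np.isfinite(self.d) and self.d > 0, f"d must be > 0, got {self.d}")
        _require(np.isfinite(self.d_star) and self.d_star > 0, f"d_star must be > 0, got {self.d_star}")

    @property
    def f_d_star(self) -> float:
        """Flow product f*D* (mm^2/s)."""
        return self.f * self.d_star


@dataclass(frozen=True)
class MonoexpParams:
    """Monoexponential DWI parameters: amplitude and apparent diffusion coefficient."""

    s0: float
    adc: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.s0) and self.s0 > 0, f"s0 must be > 0, got {self.s0}")
        _require(np.isfinite(self.adc) and self.adc > 0, f"adc must be > 0, got {self.adc}")


@dataclass(frozen=True)
class T2StarParams:
    """Gradient-echo decay parameters: amplitude and effective transverse relaxation time (ms)."""

    s0: float
    t2_star: float

    def __post_init__(self) -> None:
        _require(np.isfinite(self.s0) and self.s0 > 0, f"s0 must be > 0, got {self.s0}")
        _require(np.isfinite(self.t2_star) and self.t2_star > 0, f"t2_star must be > 0, got {self.t2_star}")


@dataclass(frozen=True)
class DecayCurve:
    """One voxel's (or an ROI-mean) signal against b-value or echo time.

    ``abscissa`` is b-values in s/mm^2 (``kind="dwi"``) or echo times in ms
    (``kind="bold"``), strictly increasing.  Signals must be finite; small
    negative excursions are tolerated because additive Gaussian noise on a
    nearly fully attenuated magnitude signal can dip below zero.
    """

    abscissa: np.ndarray
    signal: np.ndarray
    kind: str = "dwi"

    def __post_init__(self) -> None:
        abscissa = np.asarray(self.abscissa, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "abscissa", abscissa)
        object.__setattr__(self, "signal", signal)
        _require(self.kind in ("dwi", "bold"), f"kind must be 'dwi' or 'bold', got {self.kind!r}")
        _require(abscissa.ndim == 1 and signal.ndim == 1, "abscissa and signal must be 1-D")
        _require(len(abscissa) == len(signal), "abscissa and signal lengths differ")
        _require(len(abscissa) >= 2, "a decay curve needs at least two points")
        _require(bool(np.all(np.isfinite(abscissa))), "abscissa must be finite")
        _require(bool(np.all(abscissa >= 0)), "abscissa must be non-negative")
        _require(bool(np.all(np.diff(abscissa) > 0)), "abscissa must be strictly increasing")
        _require(bool(np.all(np.isfinite(signal))), "signal must be finite")

    def __len__(self) -> int:
        return len(self.abscissa)

    @classmethod
    def dwi(cls, signal, b_values=DWI_B_VALUES) -> "DecayCurve":
        return cls(np.asarray(b_values, float), np.asarray(signal, float), kind="dwi")

    @classmethod
    def bold(cls, signal, echo_times=BOLD_ECHO_TIMES) -> "DecayCurve":
        return cls(np.asarray(echo_times, float), np.asarray(signal, float), kind="bold")


def _check_abscissa(x, name: str):
    x = np.asarray(x, dtype=float)
    _require(bool(np.all(np.isfinite(x))), f"{name} must be finite")
    _require(bool(np.all(x >= 0)), f"{name} must be non-negative")
    return x


def ivim_signal(params: IvimParams, b):
    """IVIM biexponential signal S(b) = S0*[f*exp(-b*D*) + (1-f)*exp(-b*D)].

    ``b`` may be a scalar or array of b-values (s/mm^2, >= 0).
    """
    b = _check_abscissa(b, "b")
    fast = params.f * np.exp(-b * params.d_star)
    slow = (1.0 - params.f) * np.exp(-b * params.d)
    return params.s0 * (fast + slow)


def monoexp_signal(params: MonoexpParams, b):
    """Monoexponential DWI signal S(b) = S0*exp(-b*ADC)."""
    b = _check_abscissa(b, "b")
    return params.s0 * np.exp(-b * params.adc)


def t2star_signal(params: T2StarParams, te):
    """Gradient-echo signal S(TE) = S0*exp(-TE/T2*), TE in ms."""
    te = _check_abscissa(te, "te")
    return params.s0 * np.exp(-te / params.t2_star)


def flow_product(f: float, d_star: float) -> float:
    """Flow product fD* (mm^2/s); zero iff f is zero."""
    _require(np.isfinite(f) and 0.0 <= f <= 1.0, f"f must lie in [0, 1], got {f}")
    _require(np.isfinite(d_star) and d_star > 0, f"d_star must be > 0, got {d_star}")
    return f * d_star
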