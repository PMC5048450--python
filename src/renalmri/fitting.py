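"""Curve-level and voxelwise parameter estimation for renal DWI and BOLD data.

Four estimators are provided:

* :func:`fit_adc` — perfusion-insensitive ADC: Levenberg-Marquardt
  monoexponential fit restricted to b >= 200 s/mm^2, where the fast
  pseudodiffusion compartment has decayed to negligible amplitude.
* :func:`segmented_init` — the classical two-stage IVIM initialisation: a
  high-b monoexponential fit gives D, and back-projecting the fitted line to
  b = 0 gives the perfusion fraction from the intercept deficit
  f = 1 - A / S(0).
* :func:`fit_ivim_bayesian` — Bayesian estimation of (S0, f, D, D*) from all
  b-values under a Gaussian likelihood with uniform priors.  The default
  engine integrates the posterior on a deterministic grid: S0 enters the model
  linearly, so it is marginalised in closed form (truncated Gaussian) and the
  remaining (f, D, D*) box is evaluated on a coarse-to-fine sequence of grids
  that zooms onto the credible region.  Point estimates are marginal posterior
  medians.  An MCMC engine (emcee) is available for cross-checking.
* :func:`fit_t2star` — Levenberg-Marquardt monoexponential T2* fit of the
  multi-echo signal, with no noise-floor term.

:func:`fit_map` drives any of these over a masked slice and returns a
:class:`ParameterMap` carrying per-voxel convergence flags; downstream region
medians are computed over converged voxels only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize, special

from .signal_models import DecayCurve, IvimParams, MonoexpParams, T2StarParams

__all__ = [
    "PriorSpec",
    "FitResult",
    "ParameterMap",
    "fit_adc",
    "segmented_init",
    "fit_ivim_bayesian",
    "fit_t2star",
    "fit_map",
]

#: Default initial D*/D ratio for the segmented initialisation; pseudodiffusion
#: in kidney is typically 1.5 orders of magnitude faster than tissue diffusion.
DEFAULT_D_STAR_RATIO = 30.0


@dataclass(frozen=True)
class PriorSpec:
    """Prior box for the Bayesian IVIM fit.

    f and S0 carry uniform priors; the diffusion coefficients are bounded to
    the physiologically plausible renal range (tissue diffusion cannot exceed
    free-water diffusivity, ~3e-3 mm^2/s at body temperature) with a several-
    fold margin around reported renal values.  Parameters named in
    ``log_scale`` (by default the pseudodiffusion coefficient, a scale
    parameter uncertain over orders of magnitude) carry a log-uniform prior
    over their bounds; a linear-uniform prior on so wide a D* interval puts
    almost all prior volume in the fast tail where the data cannot
    discriminate, which drags the marginal median far above any plausible
    value.  ``s0_max=None`` defaults to twice the measured b = 0 signal.
    The box is recorded in every fit's diagnostics for auditability.
    """

    f_bounds: tuple[float, float] = (0.0, 1.0)
    d_bounds: tuple[float, float] = (2e-4, 5e-3)
    d_star_bounds: tuple[float, float] = (5e-3, 0.3)
    s0_max: Optional[float] = None
    log_scale: tuple[str, ...] = ("d_star",)

    def __post_init__(self) -> None:
        for name in ("f_bounds", "d_bounds", "d_star_bounds"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"{name} must satisfy lower < upper, got ({lo}, {hi})")
        if self.d_bounds[0] <= 0 or self.d_star_bounds[0] <= 0:
            raise ValueError("d and d_star prior bounds must be positive")
        if not (0.0 <= self.f_bounds[0] < self.f_bounds[1] <= 1.0):
            raise ValueError("f_bounds must lie within [0, 1]")
        if self.s0_max is not None and self.s0_max <= 0:
            raise ValueError("s0_max must be positive")
        if any(p not in ("d", "d_star") for p in self.log_scale):
            raise ValueError("log_scale may only name 'd' and/or 'd_star'")

    def resolve_s0_max(self, curve: DecayCurve) -> float:
        if self.s0_max is not None:
            return self.s0_max
        s0_obs = float(curve.signal[0])
        if s0_obs <= 0:
            s0_obs = float(np.max(curve.signal))
        if s0_obs <= 0:
            raise ValueError("cannot set an S0 prior bound from a non-positive signal")
        return 2.0 * s0_obs


@dataclass
class FitResult:
    """Outcome of a single-curve fit.

    ``residual_norm`` is the sum of squared residuals divided by the residual
    degrees of freedom (n points minus n parameters, floored at 1).
    ``diagnostics`` carries engine-specific extras: the likelihood noise scale,
    central 95% credible-interval widths for Bayesian fits, prior bounds, and
    any failure flags.  ``converged=False`` marks the parameters unusable for
    downstream medians.
    """

    params: object | None
    converged: bool
    residual_norm: float = np.nan
    diagnostics: dict = field(default_factory=dict)


def _residual_norm(observed: np.ndarray, predicted: np.ndarray, n_params: int) -> float:
    dof = max(len(observed) - n_params, 1)
    return float(np.sum((observed - predicted) ** 2) / dof)


def _failed(reason: str, **extra) -> FitResult:
    diag = {"flags": [reason]}
    diag.update(extra)
    return FitResult(params=None, converged=False, diagnostics=diag)


# ---------------------------------------------------------------------------
# Least-squares monoexponential fits
# ---------------------------------------------------------------------------

def _monoexp_lm(x: np.ndarray, y: np.ndarray, rate_init: float, amp_init: float):
    """LM fit of y = amp * exp(-rate * x); returns (amp, rate, success)."""
    def model(x, amp, rate):
        return amp * np.exp(-rate * x)

    try:
        with warnings.catch_warnings():
            # two-point fits are exactly determined; their covariance is moot
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, x, y, p0=[amp_init, rate_init], method="lm", maxfev=2000
            )
    except RuntimeError:
        return np.nan, np.nan, False
    amp, rate = popt
    ok = np.isfinite(amp) and np.isfinite(rate) and amp > 0 and rate > 0
    return float(amp), float(rate), bool(ok)


def _loglinear_init(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-point log-linear solution between the first and last positive points."""
    pos = y > 0
    if pos.sum() < 2:
        return float(np.max(y)) if np.max(y) > 0 else 1.0, 1e-3
    xi, yi = x[pos], y[pos]
    rate = float(np.log(yi[0] / yi[-1]) / (xi[-1] - xi[0]))
    rate = rate if np.isfinite(rate) and rate > 0 else 1e-3
    amp = float(yi[0] * np.exp(rate * xi[0]))
    return amp, rate


def fit_adc(curve: DecayCurve, b_min: float = 200.0) -> FitResult:
    """Perfusion-insensitive ADC: monoexponential LM fit on b >= ``b_min``.

    Restricting to high b-values removes the perfusion-sensitive part of the
    decay so the fitted rate approximates tissue diffusion.  Initialised from
    the log-linear two-point solution.  Returns a non-converged result (never
    raises) when the retained signals are unusable.
    """
    if curve.kind != "dwi":
        raise ValueError("fit_adc expects a DWI curve")
    keep = curve.abscissa >= b_min
    if keep.sum() < 2:
        raise ValueError(f"need at least 2 points with b >= {b_min}, have {int(keep.sum())}")
    b, y = curve.abscissa[keep], curve.signal[keep]
    if not np.any(y > 0):
        return _failed("all retained signals non-positive")
    amp0, rate0 = _loglinear_init(b, y)
    amp, rate, ok = _monoexp_lm(b, y, rate0, amp0)
    if not ok:
        return _failed("LM fit did not converge")
    params = MonoexpParams(s0=amp, adc=rate)
    rn = _residual_norm(y, amp * np.exp(-rate * b), 2)
    return FitResult(params=params, converged=True, residual_norm=rn, diagnostics={"b_min": b_min})


def fit_t2star(curve: DecayCurve) -> FitResult:
    """Monoexponential T2* fit of a multi-echo curve (no noise-floor term).

    The decay rate is fitted as 1/T2*; degenerate inputs (non-positive
    signals everywhere, or no measurable decay) yield a non-converged result.
    """
    if curve.kind != "bold":
        raise ValueError("fit_t2star expects a BOLD curve")
    te, y = curve.abscissa, curve.signal
    if not np.any(y > 0):
        return _failed("all signals non-positive")
    amp0, rate0 = _loglinear_init(te, y)
    amp, rate, ok = _monoexp_lm(te, y, rate0, amp0)
    if not ok or rate < 1e-6:  # rate ~ 0: constant signal, T2* unbounded
        return _failed("LM fit did not converge or no measurable decay")
    params = T2StarParams(s0=amp, t2_star=1.0 / rate)
    rn = _residual_norm(y, amp * np.exp(-rate * te), 2)
    return FitResult(params=params, converged=True, residual_norm=rn)


# ---------------------------------------------------------------------------
# Segmented IVIM initialisation
# ---------------------------------------------------------------------------

def segmented_init(
    curve: DecayCurve,
    b_min: float = 200.0,
    d_star_ratio: float = DEFAULT_D_STAR_RATIO,
) -> FitResult:
    """Two-stage IVIM initialisation.

    A monoexponential fit at b >= ``b_min`` estimates D; projecting the fitted
    line back to b = 0 gives an intercept A, and the perfusion fraction is
    initialised as f = 1 - A/S(0), clamped to [0, 1].  D* has no information
    at high b and is initialised at ``d_star_ratio`` times D.  The
    diagnostics carry ``sigma_highb``, the residual noise scale of the high-b
    fit, used as the default likelihood scale of the Bayesian fit.
    """
    if curve.kind != "dwi":
        raise ValueError("segmented_init expects a DWI curve")
    low = curve.abscissa < b_min
    if not low.any():
        raise ValueError(f"curve has no points below b = {b_min}")
    s0_obs = float(curve.signal[0])
    if curve.abscissa[0] != 0:
        warnings.warn("curve has no b = 0 point; using the lowest-b signal as S(0)", stacklevel=2)
    if s0_obs <= 0:
        return _failed("S(0) non-positive")

    high_fit = fit_adc(curve, b_min=b_min)
    if not high_fit.converged:
        return _failed("high-b monoexponential fit failed", upstream=high_fit.diagnostics)
    d_init = high_fit.params.adc
    intercept = high_fit.params.s0  # extrapolated signal at b = 0

    f_init = 1.0 - intercept / s0_obs
    clamped = not (0.0 <= f_init <= 1.0)
    f_init = float(np.clip(f_init, 0.0, 1.0))

    n_high = int((curve.abscissa >= b_min).sum())
    sigma_highb = float(np.sqrt(high_fit.residual_norm))  # already SSR/dof

    params = IvimParams(s0=s0_obs, f=f_init, d=d_init, d_star=d_star_ratio * d_init)
    diag = {"sigma_highb": sigma_highb, "n_high_b": n_high, "intercept": intercept}
    if clamped:
        diag["flags"] = ["f_init clamped to [0, 1]"]
    return FitResult(params=params, converged=True, residual_norm=high_fit.residual_norm, diagnostics=diag)


# ---------------------------------------------------------------------------
# Bayesian IVIM fit: deterministic grid posterior
# ---------------------------------------------------------------------------

def _axis_node_widths(x: np.ndarray) -> np.ndarray:
    """Trapezoid quadrature widths for arbitrary monotone nodes."""
    w = np.empty_like(x)
    w[1:-1] = 0.5 * (x[2:] - x[:-2])
    w[0] = 0.5 * (x[1] - x[0])
    w[-1] = 0.5 * (x[-1] - x[-2])
    return w


def _cell_stats(b, y, f_ax, d_ax, ds_ax):
    """Per-cell Gram quantities A = sum g^2 and B = sum g*y for g = model/S0."""
    ed = np.exp(-np.outer(d_ax, b))     # (nd, nb)
    eds = np.exp(-np.outer(ds_ax, b))   # (nds, nb)
    f = f_ax[:, None, None, None]
    g = f * eds[None, None, :, :] + (1.0 - f) * ed[None, :, None, :]  # (nf, nd, nds, nb)
    A = np.einsum("ijkb,ijkb->ijk", g, g)
    B = np.einsum("ijkb,b->ijk", g, y)
    return A, B


def _log_marginal_s0(A, B, C, sigma, s0_max):
    """Log of the likelihood integrated over S0 ~ Uniform(0, s0_max].

    The likelihood is Gaussian in S0 with mean B/A and variance sigma^2/A, so
    the integral is a scaled difference of normal CDFs.
    """
    mu = B / A
    sd = sigma / np.sqrt(A)
    z_hi = (s0_max - mu) / sd
    z_lo = -mu / sd
    mass = special.ndtr(z_hi) - special.ndtr(z_lo)
    mass = np.clip(mass, 1e-300, None)
    log_peak = -(C - B * B / A) / (2.0 * sigma**2)
    return log_peak + 0.5 * np.log(2.0 * np.pi * sigma**2 / A) + np.log(mass)


def _marginal(weights: np.ndarray, axis_keep: int) -> np.ndarray:
    axes = tuple(i for i in range(weights.ndim) if i != axis_keep)
    return weights.sum(axis=axes)


def _cdf_quantile(x: np.ndarray, mass: np.ndarray, q) -> np.ndarray:
    total = mass.sum()
    if total <= 0 or not np.isfinite(total):
        return np.interp(np.atleast_1d(q), [0, 1], [x[0], x[-1]])
    cdf = (np.cumsum(mass) - 0.5 * mass) / total
    return np.interp(np.atleast_1d(q), cdf, x)


def _refine_window(x: np.ndarray, mass: np.ndarray, bounds: tuple[float, float]) -> tuple[float, float]:
    lo, hi = _cdf_quantile(x, mass, [5e-4, 1 - 5e-4])
    pad = float(np.max(np.diff(x)))
    lo, hi = max(bounds[0], lo - pad), min(bounds[1], hi + pad)
    if hi <= lo:
        mid = 0.5 * (lo + hi)
        lo, hi = max(bounds[0], mid - pad), min(bounds[1], mid + pad)
    return float(lo), float(hi)


def _estimate_sigma(curve: DecayCurve, init: FitResult) -> float:
    """Likelihood noise scale from the segmented high-b fit residuals, floored.

    The floor (1e-4 of the signal scale) keeps effectively noiseless curves
    numerically well-posed on the posterior grid without visibly widening the
    posterior of genuinely noisy data.
    """
    floor = 1e-4 * max(float(np.max(np.abs(curve.signal))), 1.0)
    sigma = init.diagnostics.get("sigma_highb", 0.0) if init.converged else 0.0
    if not np.isfinite(sigma) or sigma <= 0:
        sigma = 0.0
    return max(sigma, floor)


def _grid_posterior(curve, priors, sigma, n_grid, n_passes):
    b, y = curve.abscissa, curve.signal
    C = float(np.dot(y, y))
    s0_max = priors.resolve_s0_max(curve)

    f_lo, f_hi = priors.f_bounds
    d_lo, d_hi = priors.d_bounds
    ds_lo, ds_hi = priors.d_star_bounds
    # pass 1: prior-wide, log-spaced on the diffusion axes
    f_ax = np.linspace(f_lo, f_hi, n_grid)
    d_ax = np.geomspace(d_lo, d_hi, n_grid)
    ds_ax = np.geomspace(ds_lo, ds_hi, n_grid)

    boundary_mass = {}
    medians = {}
    ci = {}
    axes = last_w = last_A = last_B = None
    for it in range(n_passes):
        A, B = _cell_stats(b, y, f_ax, d_ax, ds_ax)
        logw = _log_marginal_s0(A, B, C, sigma, s0_max)
        w_d = _axis_node_widths(d_ax)
        w_ds = _axis_node_widths(ds_ax)
        if "d" in priors.log_scale:
            w_d = w_d / d_ax  # density 1/x: uniform in log d
        if "d_star" in priors.log_scale:
            w_ds = w_ds / ds_ax
        logw += np.log(_axis_node_widths(f_ax))[:, None, None]
        logw += np.log(w_d)[None, :, None]
        logw += np.log(w_ds)[None, None, :]
        w = np.exp(logw - logw.max())

        marg = {k: _marginal(w, i) for i, k in enumerate(("f", "d", "d_star"))}
        axes = {"f": f_ax, "d": d_ax, "d_star": ds_ax}
        if it == 0:
            total = w.sum()
            for k in ("f", "d"):
                m = marg[k]
                boundary_mass[k] = float((m[0] + m[-1]) / total) if total > 0 else 1.0
        if it < n_passes - 1:
            f_ax = np.linspace(*_refine_window(axes["f"], marg["f"], (f_lo, f_hi)), n_grid)
            d_ax = np.linspace(*_refine_window(axes["d"], marg["d"], (d_lo, d_hi)), n_grid)
            ds_ax = np.linspace(*_refine_window(axes["d_star"], marg["d_star"], (ds_lo, ds_hi)), n_grid)
        else:
            for k in ("f", "d", "d_star"):
                med, q_lo, q_hi = _cdf_quantile(axes[k], marg[k], [0.5, 0.025, 0.975])
                medians[k] = float(med)
                ci[k] = float(q_hi - q_lo)
            last_w, last_A, last_B = w, A, B

    # S0 marginal is a mixture of near-Gaussians N(B/A, sigma^2/A); its median
    # is approximated by the weighted median of the per-cell conditional means
    # (exact as sigma -> 0, and well within grid resolution otherwise), the
    # 95% interval by moment matching.
    keep = last_w > last_w.max() * 1e-12
    wk = last_w[keep]
    mu = np.clip((last_B / last_A)[keep], 0.0, s0_max)
    var = (sigma**2 / last_A)[keep]
    order = np.argsort(mu)
    medians["s0"] = float(_cdf_quantile(mu[order], wk[order], 0.5)[0])
    m1 = float(np.average(mu, weights=wk))
    mix_var = float(np.average(var + mu**2, weights=wk)) - m1**2
    ci["s0"] = float(2 * 1.959964 * np.sqrt(max(mix_var, 0.0)))
    return medians, ci, boundary_mass, s0_max


def _mcmc_posterior(curve, priors, sigma, init, seed, n_walkers=24, n_steps=1200, n_burn=400):
    import emcee

    b, y = curve.abscissa, curve.signal
    s0_max = priors.resolve_s0_max(curve)
    lo = np.array([0.0, priors.f_bounds[0], priors.d_bounds[0], priors.d_star_bounds[0]])
    hi = np.array([s0_max, priors.f_bounds[1], priors.d_bounds[1], priors.d_star_bounds[1]])

    def log_prob(theta):
        if np.any(theta <= lo) or np.any(theta > hi):
            return -np.inf
        s0, f, d, ds = theta
        model = s0 * (f * np.exp(-b * ds) + (1 - f) * np.exp(-b * d))
        lp = -0.5 * np.sum((y - model) ** 2) / sigma**2
        if "d" in priors.log_scale:
            lp -= np.log(d)
        if "d_star" in priors.log_scale:
            lp -= np.log(ds)
        return lp

    rng = np.random.default_rng(seed)
    centre = np.array([
        np.clip(init.s0, lo[0] + 1e-9, hi[0]),
        np.clip(init.f, 1e-3, 1 - 1e-3),
        np.clip(init.d, lo[2] * 1.01, hi[2] * 0.99),
        np.clip(init.d_star, lo[3] * 1.01, hi[3] * 0.99),
    ])
    p0 = centre * (1 + 0.05 * rng.standard_normal((n_walkers, 4)))
    p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
    sampler = emcee.EnsembleSampler(n_walkers, 4, log_prob)
    sampler._random = np.random.RandomState(seed)
    sampler.run_mcmc(p0, n_steps, progress=False)
    chain = sampler.get_chain(discard=n_burn, flat=True)
    names = ("s0", "f", "d", "d_star")
    medians = {k: float(np.median(chain[:, i])) for i, k in enumerate(names)}
    ci = {
        k: float(np.quantile(chain[:, i], 0.975) - np.quantile(chain[:, i], 0.025))
        for i, k in enumerate(names)
    }
    boundary = {}
    for k, i, (blo, bhi) in (("f", 1, priors.f_bounds), ("d", 2, priors.d_bounds)):
        edge = 0.02 * (bhi - blo)
        boundary[k] = float(np.mean((chain[:, i] < blo + edge) | (chain[:, i] > bhi - edge)))
    return medians, ci, boundary, s0_max


def fit_ivim_bayesian(
    curve: DecayCurve,
    priors: PriorSpec | None = None,
    init: IvimParams | None = None,
    seed: int = 0,
    sigma: float | None = None,
    engine: str = "grid",
    n_grid: int = 40,
    n_passes: int = 3,
) -> FitResult:
    """Bayesian IVIM fit of all b-values: Gaussian likelihood, uniform priors.

    Point estimates are marginal posterior medians; diagnostics report the
    central 95% credible-interval width per parameter, the noise scale, the
    prior box and prior-boundary posterior mass.  ``sigma=None`` estimates the
    noise scale from the segmented initialisation's high-b residuals.  The
    default ``grid`` engine is fully deterministic (``seed`` only affects the
    optional ``mcmc`` engine).

    A fit is flagged non-converged when the posterior piles onto the prior
    boundary for f or D (mass >= 50%), or when the posterior medians are
    compartment-swapped (median D* below median D).
    """
    if curve.kind != "dwi":
        raise ValueError("fit_ivim_bayesian expects a DWI curve")
    priors = priors or PriorSpec()
    y = curve.signal
    if not np.all(np.isfinite(y)) or np.allclose(y, y[0]):
        return _failed("degenerate curve (constant or non-finite signals)")

    seg = None
    if init is None or sigma is None:
        seg = segmented_init(curve)
    if init is None:
        if not seg.converged:
            return _failed("segmented initialisation failed", upstream=seg.diagnostics)
        init = seg.params
    if sigma is None:
        sigma = _estimate_sigma(curve, seg)

    if engine == "grid":
        medians, ci, boundary, s0_max = _grid_posterior(curve, priors, sigma, n_grid, n_passes)
    elif engine == "mcmc":
        medians, ci, boundary, s0_max = _mcmc_posterior(curve, priors, sigma, init, seed)
    else:
        raise ValueError(f"unknown engine {engine!r}")

    flags = []
    converged = True
    if boundary.get("f", 0.0) >= 0.5 or boundary.get("d", 0.0) >= 0.5:
        flags.append("posterior mass concentrated at prior boundary")
        converged = False
    if medians["d_star"] < medians["d"]:
        flags.append("compartment_swapped")
        converged = False

    params = IvimParams(
        s0=max(medians["s0"], 1e-12), f=medians["f"], d=medians["d"], d_star=medians["d_star"]
    )
    model = params.s0 * (
        params.f * np.exp(-curve.abscissa * params.d_star)
        + (1 - params.f) * np.exp(-curve.abscissa * params.d)
    )
    rn = _residual_norm(y, model, 4)
    diag = {
        "engine": engine,
        "sigma": float(sigma),
        "ci95_width": ci,
        "boundary_mass": boundary,
        "prior_bounds": {
            "f": priors.f_bounds,
            "d": priors.d_bounds,
            "d_star": priors.d_star_bounds,
            "s0": (0.0, s0_max),
        },
        "flags": flags,
    }
    return FitResult(params=params, converged=converged, residual_norm=rn, diagnostics=diag)


# ---------------------------------------------------------------------------
# Voxelwise driver
# ---------------------------------------------------------------------------

_MODEL_PARAMS = {
    "adc": ("adc", "s0"),
    "ivim": ("f", "d", "d_star", "f_d_star", "s0"),
    "t2star": ("t2_star", "s0"),
}


@dataclass
class ParameterMap:
    """Voxelwise fitted parameters over a masked slice.

    ``params`` maps parameter name to a 2-D array (NaN outside the mask or
    where the fit failed); ``fitted`` marks voxels where a fit was attempted
    and ``converged`` those whose result is usable.
    """

    model: str
    params: dict[str, np.ndarray]
    converged: np.ndarray
    fitted: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.converged.shape

    @property
    def n_fitted(self) -> int:
        return int(self.fitted.sum())

    @property
    def n_nonconverged(self) -> int:
        return int((self.fitted & ~self.converged).sum())


def _extract(model: str, params) -> dict[str, float]:
    if model == "adc":
        return {"adc": params.adc, "s0": params.s0}
    if model == "t2star":
        return {"t2_star": params.t2_star, "s0": params.s0}
    return {
        "f": params.f, "d": params.d, "d_star": params.d_star,
        "f_d_star": params.f_d_star, "s0": params.s0,
    }


def fit_map(
    stack: np.ndarray,
    mask: np.ndarray,
    model: str,
    abscissa=None,
    **settings,
) -> ParameterMap:
    """Fit every voxel inside ``mask`` of an image stack.

    ``model`` selects the estimator: "adc", "ivim" (Bayesian) or "t2star".
    ``abscissa`` gives the b-values or echo times of the stack's first axis
    (defaults to the standard scheme for the model).  Extra keyword settings
    are passed to the underlying fitter.
    """
    if model not in _MODEL_PARAMS:
        raise ValueError(f"model must be one of {tuple(_MODEL_PARAMS)}, got {model!r}")
    stack = np.asarray(stack, float)
    mask = np.asarray(mask).astype(bool)
    if stack.ndim != 3 or stack.shape[1:] != mask.shape:
        raise ValueError(f"grid mismatch: stack {stack.shape} vs mask {mask.shape}")
    if abscissa is None:
        from .signal_models import BOLD_ECHO_TIMES, DWI_B_VALUES
        abscissa = BOLD_ECHO_TIMES if model == "t2star" else DWI_B_VALUES
    abscissa = np.asarray(abscissa, float)
    kind = "bold" if model == "t2star" else "dwi"

    maps = {k: np.full(mask.shape, np.nan) for k in _MODEL_PARAMS[model]}
    converged = np.zeros(mask.shape, dtype=bool)
    fitted = np.zeros(mask.shape, dtype=bool)
    if not mask.any():
        warnings.warn("fit_map called with an empty mask", stacklevel=2)
        return ParameterMap(model=model, params=maps, converged=converged, fitted=fitted)

    fitters = {
        "adc": lambda c: fit_adc(c, **settings),
        "ivim": lambda c: fit_ivim_bayesian(c, **settings),
        "t2star": lambda c: fit_t2star(c),
    }
    fit_one = fitters[model]
    for r, c in zip(*np.where(mask)):
        fitted[r, c] = True
        try:
            result = fit_one(DecayCurve(abscissa, stack[:, r, c], kind=kind))
        except ValueError:
            result = _failed("invalid curve")
        if result.params is not None:
            for name, value in _extract(model, result.params).items():
                maps[name][r, c] = value
        converged[r, c] = result.converged
    pmap = ParameterMap(model=model, params=maps, converged=converged, fitted=fitted)
    if pmap.n_nonconverged:
        warnings.warn(
            f"{model} map: {pmap.n_nonconverged}/{pmap.n_fitted} voxels did not converge",
            stacklevel=2,
        )
    return pmap
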