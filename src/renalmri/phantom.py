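"""Synthetic kidney phantom: DWI and BOLD stacks with known ground truth.

A single coronal slice holds an elliptical "kidney" whose one-voxel rim is the
cortex and whose interior is the medulla (the same rule the region module
applies to real masks).  Each region carries constant ground-truth IVIM and
T2* parameters; stacks are simulated by evaluating the forward models over the
acquisition scheme and adding white Gaussian noise.  The default geometry (13 x 9
voxel ellipse, ~91 kidney voxels) and noise level (SNR 20 relative to S0)
emulate a rat kidney imaged at 1.5 T with clinical coils.

Drug challenges are modelled purely as multiplicative transforms of the
ground-truth parameter fields (per region, and per BOLD timepoint for T2*),
with default factors taken from :mod:`renalmri.presets`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import presets
from .regions import CORTEX, MEDULLA, RegionSet, derive_regions
from .signal_models import (
    BOLD_ECHO_TIMES,
    DWI_B_VALUES,
    IvimParams,
    T2StarParams,
    ivim_signal,
    t2star_signal,
)

__all__ = [
    "RegionTruth",
    "PhantomSpec",
    "PhantomTruth",
    "ChallengeTransform",
    "make_phantom",
    "simulate_dwi",
    "simulate_bold",
    "apply_challenge",
    "save_stack_nifti",
    "load_stack_nifti",
]


@dataclass(frozen=True)
class RegionTruth:
    """Ground-truth IVIM and T2* parameters for one phantom region."""

    ivim: IvimParams
    t2star: T2StarParams


def _default_region_params() -> dict[str, RegionTruth]:
    return {
        "cortex": RegionTruth(presets.baseline_ivim("cortex"), presets.baseline_t2star()),
        "medulla": RegionTruth(presets.baseline_ivim("medulla"), presets.baseline_t2star()),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, ground truth and noise model of the synthetic kidney slice.

    ``ellipse_axes`` are the full axes (row, column) of the kidney ellipse in
    voxels; the default 13 x 9 yields ~91 kidney voxels.  ``region_params`` maps
    ``"cortex"``/``"medulla"`` (or a single ``"whole_kidney"`` entry for a
    uniform kidney) to ground truth.  ``snr_target`` is S0 divided by the
    Gaussian noise standard deviation; ``noise_sigma`` may be given explicitly
    instead.  ``kidney_voxel_tolerance`` bounds the accepted deviation of the
    realised kidney size from ``expected_kidney_voxels``.
    """

    grid: tuple[int, int] = (32, 32)
    ellipse_axes: tuple[float, float] = (13.0, 9.0)
    region_params: dict[str, RegionTruth] = field(default_factory=_default_region_params)
    snr_target: float = 20.0
    noise_sigma: float | None = None
    expected_kidney_voxels: int = 91
    kidney_voxel_tolerance: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_target <= 0:
            raise ValueError("snr_target must be positive")
        if self.noise_sigma is not None and self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if len(self.grid) != 2 or min(self.grid) < 4:
            raise ValueError("grid must be 2-D and at least 4 voxels on a side")
        allowed = {"cortex", "medulla", "whole_kidney"}
        keys = set(self.region_params)
        if keys != {"whole_kidney"} and keys != {"cortex", "medulla"}:
            raise ValueError(
                f"region_params keys must be {{'whole_kidney'}} or {{'cortex', 'medulla'}}, got {keys}"
            )

    @property
    def s0_reference(self) -> float:
        return max(rt.ivim.s0 for rt in self.region_params.values())

    @property
    def sigma(self) -> float:
        """Noise standard deviation actually applied (explicit, or S0/SNR)."""
        if self.noise_sigma is not None:
            return self.noise_sigma
        return self.s0_reference / self.snr_target


@dataclass(frozen=True)
class PhantomTruth:
    """Label map plus per-voxel ground-truth parameter fields."""

    regions: RegionSet
    maps: dict[str, np.ndarray]  # f, d, d_star, s0, t2_star over the slice
    spec: PhantomSpec

    def ivim_at(self, idx: tuple[int, int]) -> IvimParams:
        m = self.maps
        return IvimParams(
            s0=float(m["s0"][idx]), f=float(m["f"][idx]),
            d=float(m["d"][idx]), d_star=float(m["d_star"][idx]),
        )

    def t2star_at(self, idx: tuple[int, int]) -> T2StarParams:
        return T2StarParams(s0=float(self.maps["s0"][idx]), t2_star=float(self.maps["t2_star"][idx]))


def _ellipse_mask(grid: tuple[int, int], axes: tuple[float, float]) -> np.ndarray:
    rows, cols = grid
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    ay, ax = axes[0] / 2.0, axes[1] / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Build the labelled ground-truth slice for a phantom specification.

    Deterministic: the geometry and parameter fields involve no randomness
    (noise enters only in ``simulate_dwi``/``simulate_bold``).
    """
    mask = _ellipse_mask(spec.grid, spec.ellipse_axes)
    n_kidney = int(mask.sum())
    lo = spec.expected_kidney_voxels - spec.kidney_voxel_tolerance
    hi = spec.expected_kidney_voxels + spec.kidney_voxel_tolerance
    if not (lo <= n_kidney <= hi):
        raise ValueError(
            f"ellipse {spec.ellipse_axes} on grid {spec.grid} gives {n_kidney} kidney voxels, "
            f"outside the accepted range [{lo}, {hi}]; adjust ellipse_axes or the tolerance"
        )
    regions = derive_regions(mask, provenance="phantom_truth")

    maps = {k: np.zeros(spec.grid, dtype=float) for k in ("f", "d", "d_star", "s0", "t2_star")}
    if "whole_kidney" in spec.region_params:
        assignment = {CORTEX: spec.region_params["whole_kidney"], MEDULLA: spec.region_params["whole_kidney"]}
    else:
        assignment = {CORTEX: spec.region_params["cortex"], MEDULLA: spec.region_params["medulla"]}
    for label, truth in assignment.items():
        sel = regions.labels == label
        maps["f"][sel] = truth.ivim.f
        maps["d"][sel] = truth.ivim.d
        maps["d_star"][sel] = truth.ivim.d_star
        maps["s0"][sel] = truth.ivim.s0
        maps["t2_star"][sel] = truth.t2star.t2_star
    return PhantomTruth(regions=regions, maps=maps, spec=spec)


def _simulate(truth: PhantomTruth, abscissa: np.ndarray, forward, noise_sigma: float, seed: int) -> np.ndarray:
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    abscissa = np.asarray(abscissa, dtype=float)
    if abscissa.size == 0 or np.any(np.diff(abscissa) <= 0) or np.any(abscissa < 0):
        raise ValueError("acquisition scheme must be non-empty, non-negative and strictly increasing")
    kidney = truth.regions.whole_kidney_mask
    stack = np.zeros((abscissa.size, *truth.regions.labels.shape), dtype=float)
    idx = np.where(kidney)
    stack[:, idx[0], idx[1]] = forward(truth, idx, abscissa)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        stack += rng.normal(0.0, noise_sigma, size=stack.shape)
    return stack


def _dwi_forward(truth: PhantomTruth, idx, b: np.ndarray) -> np.ndarray:
    m = truth.maps
    f, d, ds, s0 = (m[k][idx] for k in ("f", "d", "d_star", "s0"))
    return s0 * (f * np.exp(-np.outer(b, ds)) + (1 - f) * np.exp(-np.outer(b, d)))


def _bold_forward(truth: PhantomTruth, idx, te: np.ndarray) -> np.ndarray:
    m = truth.maps
    return m["s0"][idx] * np.exp(-np.outer(te, 1.0 / m["t2_star"][idx]))


def simulate_dwi(
    truth: PhantomTruth,
    b_scheme=DWI_B_VALUES,
    noise_sigma: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a multi-b-value DWI stack (n_b, rows, cols).

    Kidney voxels follow the IVIM forward model; background voxels carry noise
    only.  ``noise_sigma=None`` uses the PhantomSpec's SNR-derived sigma; pass 0 for a
    noiseless stack.  Reproducible for a given seed.
    """
    sigma = truth.spec.sigma if noise_sigma is None else noise_sigma
    return _simulate(truth, np.asarray(b_scheme, float), _dwi_forward, sigma, seed)


def simulate_bold(
    truth: PhantomTruth,
    te_scheme=BOLD_ECHO_TIMES,
    noise_sigma: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a multi-echo gradient-echo stack (n_te, rows, cols)."""
    sigma = truth.spec.sigma if noise_sigma is None else noise_sigma
    return _simulate(truth, np.asarray(te_scheme, float), _bold_forward, sigma, seed)


@dataclass(frozen=True)
class ChallengeTransform:
    """Multiplicative pre-to-post modulation of the ground-truth fields.

    ``ivim`` maps region name ("cortex"/"medulla"/"whole_kidney") to
    per-parameter factors for f, d and d_star; ``t2star_timepoints`` maps
    region name to one T2* factor per post-administration BOLD timepoint.
    ``drug="none"`` must be the identity.
    """

    drug: str = "none"
    ivim: dict[str, dict[str, float]] = field(default_factory=dict)
    t2star_timepoints: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.drug not in presets.DRUGS:
            raise ValueError(f"unknown drug {self.drug!r}; expected one of {presets.DRUGS}")
        for region, factors in self.ivim.items():
            for name, m in factors.items():
                if name not in ("f", "d", "d_star"):
                    raise ValueError(f"unknown IVIM multiplier {name!r}")
                if m <= 0:
                    raise ValueError(f"multiplier {name} for {region} must be > 0, got {m}")
        for region, ms in self.t2star_timepoints.items():
            if any(m <= 0 for m in ms):
                raise ValueError(f"t2star multipliers for {region} must be > 0")
        if self.drug == "none":
            flat = [m for fs in self.ivim.values() for m in fs.values()]
            flat += [m for ms in self.t2star_timepoints.values() for m in ms]
            if any(m != 1.0 for m in flat):
                raise ValueError("drug='none' requires all multipliers equal to 1")

    @classmethod
    def for_drug(cls, drug: str) -> "ChallengeTransform":
        """Default transform for a study arm, from the preset pre/post values."""
        if drug == "none":
            return cls(drug="none")
        ivim = {
            region: presets.challenge_ivim_multipliers(drug, region)
            for region in ("whole_kidney", "cortex", "medulla")
        }
        t2 = {"whole_kidney": presets.t2star_timecourse_multipliers(drug)}
        return cls(drug=drug, ivim=ivim, t2star_timepoints=t2)

    def inverted(self) -> "ChallengeTransform":
        """Transform with reciprocal multipliers (undoes this one)."""
        return ChallengeTransform(
            drug=self.drug,
            ivim={r: {k: 1.0 / v for k, v in fs.items()} for r, fs in self.ivim.items()},
            t2star_timepoints={r: tuple(1.0 / v for v in ms) for r, ms in self.t2star_timepoints.items()},
        )


_LABEL_FOR_REGION = {"cortex": (CORTEX,), "medulla": (MEDULLA,), "whole_kidney": (CORTEX, MEDULLA)}


def apply_challenge(
    truth: PhantomTruth,
    transform: ChallengeTransform,
    timepoint: int | None = None,
) -> PhantomTruth:
    """Return a new ground truth with challenge multipliers applied.

    IVIM multipliers always apply; T2* multipliers apply only when
    ``timepoint`` selects one of the post-administration BOLD repeats
    (0-based).  Where a voxel is covered by both a whole-kidney and a
    cortex/medulla entry, the more specific region's multiplier wins (each
    voxel is scaled exactly once).  The input truth is not modified.
    """
    maps = {k: v.copy() for k, v in truth.maps.items()}
    labels = truth.regions.labels
    # least specific first, so cortex/medulla overwrite whole_kidney
    region_order = [r for r in ("whole_kidney", "cortex", "medulla") if r in transform.ivim]

    fields = {name: np.ones(labels.shape) for name in ("f", "d", "d_star")}
    for region in region_order:
        sel = np.isin(labels, _LABEL_FOR_REGION[region])
        for name, m in transform.ivim[region].items():
            fields[name][sel] = m
    for name, mult in fields.items():
        maps[name] *= mult

    if timepoint is not None:
        t2_field = np.ones(labels.shape)
        for region in ("whole_kidney", "cortex", "medulla"):
            if region not in transform.t2star_timepoints:
                continue
            ms = transform.t2star_timepoints[region]
            if not (0 <= timepoint < len(ms)):
                raise ValueError(f"timepoint {timepoint} outside the transform's {len(ms)} timepoints")
            t2_field[np.isin(labels, _LABEL_FOR_REGION[region])] = ms[timepoint]
        maps["t2_star"] *= t2_field
    np.clip(maps["f"], 0.0, 1.0, out=maps["f"])
    return PhantomTruth(regions=truth.regions, maps=maps, spec=truth.spec)


def save_stack_nifti(stack: np.ndarray, abscissa, kind: str, path) -> None:
    """Write a simulated stack as 4-D NIfTI plus a JSON sidecar with the scheme."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(stack, dtype=np.float32).transpose(1, 2, 0)[..., None, :], np.eye(4))
    nib.save(img, path)
    sidecar = {"kind": kind, "abscissa": list(map(float, abscissa))}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_stack_nifti(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Load a stack written by :func:`save_stack_nifti`; returns (stack, abscissa, kind)."""
    path = Path(path)
    data = np.asarray(nib.load(path).dataobj, dtype=float)
    stack = data[..., 0, :].transpose(2, 0, 1)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return stack, np.asarray(sidecar["abscissa"], float), sidecar["kind"]
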