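"""End-to-end experiments: simulate -> fit -> summarise -> statistics.

An :class:`ExperimentConfig` fully determines an experiment: phantom geometry
and ground truth, acquisition schemes, fitting settings, the design
(repeatability or one of the drug-challenge arms), the number of kidneys, and
a master seed from which all per-stage seeds are derived deterministically.
Re-running an identical config reproduces identical outputs.

Designs
-------
repeatability
    Each kidney is scanned twice with independent noise and no parameter
    change; paired medians give within-subject CoVs and Wilcoxon checks.
hydralazine / furosemide / angiotensin_ii
    Each kidney is simulated pre and post challenge (DWI) and at baseline plus
    three post-administration timepoints (BOLD), with ground-truth parameter
    fields modulated by the drug's default multipliers; paired Wilcoxon tests
    compare DWI medians pre vs post, and a repeated-measures ANOVA with
    post-hoc flags analyses the T2* timecourse alongside the
    percent-of-baseline series.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .fitting import PriorSpec, fit_map
from .phantom import (
    ChallengeTransform,
    PhantomSpec,
    PhantomTruth,
    RegionTruth,
    apply_challenge,
    make_phantom,
    save_stack_nifti,
    simulate_bold,
    simulate_dwi,
)
from . import presets
from .regions import ExclusionLog, summarise
from .signal_models import BOLD_ECHO_TIMES, DWI_B_VALUES
from .study_stats import (
    PairedMeasurements,
    TimecourseMeasurements,
    bold_timecourse_test,
    cov_repeatability,
    correlate_adc_d,
    paired_test,
    percent_change,
)

__all__ = ["ExperimentConfig", "ResultsBundle", "run_experiment", "report"]

log = logging.getLogger("renalmri")

Design = Literal["repeatability", "hydralazine", "furosemide", "angiotensin_ii"]


class PhantomConfig(BaseModel):
    """Phantom geometry, ground truth layout and noise level."""

    grid: tuple[int, int] = (32, 32)
    ellipse_axes: tuple[float, float] = (13.0, 9.0)
    snr_target: float = Field(20.0, gt=0)
    noise_sigma: Optional[float] = Field(None, ge=0)
    s0: float = Field(1000.0, gt=0)
    uniform_kidney: bool = False  # one ground truth for the whole kidney
    expected_kidney_voxels: int = 91
    kidney_voxel_tolerance: int = 12


class FittingConfig(BaseModel):
    """Settings forwarded to the voxelwise fitters."""

    b_min: float = Field(200.0, ge=0)
    engine: Literal["grid", "mcmc"] = "grid"
    n_grid: int = Field(40, ge=8)
    n_passes: int = Field(3, ge=1)
    d_bounds: tuple[float, float] = (2e-4, 5e-3)
    d_star_bounds: tuple[float, float] = (5e-3, 0.3)

    def priors(self) -> PriorSpec:
        return PriorSpec(d_bounds=self.d_bounds, d_star_bounds=self.d_star_bounds)


class ExperimentConfig(BaseModel):
    """Fully serialisable description of one experiment run."""

    design: Design = "repeatability"
    n_kidneys: int = Field(6, ge=1)
    seed: int = Field(0, ge=0)
    b_values: tuple[float, ...] = DWI_B_VALUES
    echo_times: tuple[float, ...] = BOLD_ECHO_TIMES
    phantom: PhantomConfig = PhantomConfig()
    fitting: FittingConfig = FittingConfig()
    fit_bold: bool = True
    output_dir: Optional[str] = None
    save_nifti: bool = False

    @field_validator("b_values", "echo_times")
    @classmethod
    def _increasing(cls, v):
        if any(b <= a for a, b in zip(v, v[1:])) or v[0] < 0:
            raise ValueError("acquisition scheme must be non-negative and strictly increasing")
        return v

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))


@dataclass
class ResultsBundle:
    """All outputs of one experiment run."""

    config: ExperimentConfig
    summaries: pd.DataFrame        # tidy per-kidney, per-condition region medians
    stats: dict                    # design-dependent statistics
    percent_change: Optional[pd.DataFrame] = None
    exclusions: ExclusionLog = field(default_factory=ExclusionLog)
    seeds: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.summaries.to_csv(out / "summaries.csv", index=False)
        (out / "stats.json").write_text(json.dumps(self.stats, indent=2, default=_jsonify))
        if self.percent_change is not None:
            self.percent_change.to_csv(out / "percent_change.csv", index=False)
        run_log = {
            "software": {"renalmri": __version__},
            "config": self.config.model_dump(mode="json"),
            "stage_seeds": self.seeds,
            "exclusions": self.exclusions.records,
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    return str(obj)


def _stage_seed(master: int, *tags) -> int:
    """Deterministic per-stage seed derived from the master seed (< 2^31)."""
    # zlib.crc32 is stable across processes (unlike str.__hash__)
    import zlib

    h = np.random.SeedSequence([master, *(zlib.crc32(str(t).encode()) for t in tags)])
    return int(h.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _phantom_spec(cfg: ExperimentConfig, truth_params: dict[str, RegionTruth]) -> PhantomSpec:
    p = cfg.phantom
    return PhantomSpec(
        grid=p.grid, ellipse_axes=p.ellipse_axes, region_params=truth_params,
        snr_target=p.snr_target, noise_sigma=p.noise_sigma,
        expected_kidney_voxels=p.expected_kidney_voxels,
        kidney_voxel_tolerance=p.kidney_voxel_tolerance, seed=cfg.seed,
    )


def _baseline_truth_params(cfg: ExperimentConfig) -> dict[str, RegionTruth]:
    drug = "none" if cfg.design == "repeatability" else cfg.design
    s0 = cfg.phantom.s0
    t2 = presets.baseline_t2star(drug, s0=s0)
    if cfg.phantom.uniform_kidney:
        return {"whole_kidney": RegionTruth(presets.challenge_pre_ivim(drug, "whole_kidney", s0=s0), t2)}
    return {
        "cortex": RegionTruth(presets.challenge_pre_ivim(drug, "cortex", s0=s0), t2),
        "medulla": RegionTruth(presets.challenge_pre_ivim(drug, "medulla", s0=s0), t2),
    }


def _fit_and_summarise(cfg, truth, stack, model, kidney_id, condition, out_dir=None):
    fit_cfg = cfg.fitting
    if model == "ivim":
        pmap = fit_map(
            stack, truth.regions.whole_kidney_mask, "ivim", abscissa=cfg.b_values,
            priors=fit_cfg.priors(), engine=fit_cfg.engine,
            n_grid=fit_cfg.n_grid, n_passes=fit_cfg.n_passes,
        )
    elif model == "adc":
        pmap = fit_map(stack, truth.regions.whole_kidney_mask, "adc",
                       abscissa=cfg.b_values, b_min=fit_cfg.b_min)
    else:
        pmap = fit_map(stack, truth.regions.whole_kidney_mask, "t2star", abscissa=cfg.echo_times)
    summary = summarise(pmap, truth.regions, kidney_id=kidney_id)
    summary.insert(1, "condition", condition)
    summary.insert(2, "model", model)
    if out_dir is not None:
        _save_maps(pmap, out_dir, f"{kidney_id}_{condition}_{model}")
    log.info("%s/%s %s: %d voxels fitted, %d non-converged",
             kidney_id, condition, model, pmap.n_fitted, pmap.n_nonconverged)
    return summary


def _save_maps(pmap, out_dir, stem) -> None:
    import nibabel as nib

    out = Path(out_dir) / "maps"
    out.mkdir(parents=True, exist_ok=True)
    for name, arr in pmap.params.items():
        nib.save(nib.Nifti1Image(arr.astype(np.float32), np.eye(4)), out / f"{stem}_{name}.nii")
    nib.save(nib.Nifti1Image(pmap.converged.astype(np.int16), np.eye(4)), out / f"{stem}_converged.nii")


def _median_lookup(summaries: pd.DataFrame, kidney_id, condition, region, parameter) -> float:
    sel = summaries[
        (summaries.kidney_id == kidney_id) & (summaries.condition == condition)
        & (summaries.region == region) & (summaries.parameter == parameter)
    ]
    return float(sel["median"].iloc[0]) if len(sel) else np.nan


_DWI_PARAMS = ("f", "d", "d_star", "f_d_star", "adc")
_REGIONS = ("whole_kidney", "cortex", "medulla")


def _paired_stats(summaries, kidney_ids, cond1, cond2) -> dict:
    """CoV + Wilcoxon per parameter x region between two conditions."""
    out: dict = {}
    for region in _REGIONS:
        for parameter in _DWI_PARAMS + ("t2_star",):
            pairs = []
            for kid in kidney_ids:
                v1 = _median_lookup(summaries, kid, cond1, region, parameter)
                v2 = _median_lookup(summaries, kid, cond2, region, parameter)
                if np.isfinite(v1) and np.isfinite(v2):
                    pairs.append(PairedMeasurements(kid, parameter, v1, v2))
            if not pairs:
                continue
            entry: dict = {"n": len(pairs), "cov_percent": cov_repeatability(pairs)}
            if len(pairs) >= 2:
                test = paired_test(pairs)
                entry.update(p_value=test.p_value, significant=test.significant, note=test.note)
            out.setdefault(region, {})[parameter] = entry
    return out


def _adc_d_correlation(summaries, condition) -> dict:
    sel = summaries[(summaries.condition == condition) & (summaries.region == "whole_kidney")]
    adc = sel[sel.parameter == "adc"].sort_values("kidney_id")["median"].to_numpy()
    d = sel[sel.parameter == "d"].sort_values("kidney_id")["median"].to_numpy()
    if len(adc) < 3 or len(adc) != len(d):
        return {"note": "too few kidneys for a correlation"}
    res = correlate_adc_d(adc, d)
    return {"r": res.r, "p_value": res.p_value, "n": res.n, "defined": res.defined}


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Execute a full experiment; returns (and optionally writes) the results bundle."""
    cfg = config
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    truth_params = _baseline_truth_params(cfg)
    spec = _phantom_spec(cfg, truth_params)
    truth = make_phantom(spec)
    transform = ChallengeTransform.for_drug("none" if cfg.design == "repeatability" else cfg.design)

    seeds: dict = {}
    summaries = []
    timecourses = []
    try:
        for k in range(cfg.n_kidneys):
            kid = f"kidney{k:02d}"
            if cfg.design == "repeatability":
                conditions = [("scan1", truth), ("scan2", truth)]
            else:
                conditions = [("pre", truth), ("post", apply_challenge(truth, transform))]
            for condition, cond_truth in conditions:
                seed = _stage_seed(cfg.seed, kid, condition, "dwi")
                seeds[f"{kid}/{condition}/dwi"] = seed
                stack = simulate_dwi(cond_truth, cfg.b_values, seed=seed)
                if cfg.save_nifti and out_dir:
                    save_stack_nifti(stack, cfg.b_values, "dwi", out_dir / f"{kid}_{condition}_dwi.nii")
                for model in ("ivim", "adc"):
                    summaries.append(_fit_and_summarise(
                        cfg, cond_truth, stack, model, kid, condition,
                        out_dir if cfg.save_nifti else None))

            if cfg.fit_bold:
                bold_medians = []
                bold_conditions = ["baseline"] + [f"post_{lbl}" for lbl in presets.TIMEPOINT_LABELS]
                for t, condition in enumerate(bold_conditions):
                    timepoint = None if t == 0 else t - 1
                    cond_truth = truth if timepoint is None else apply_challenge(truth, transform, timepoint)
                    seed = _stage_seed(cfg.seed, kid, condition, "bold")
                    seeds[f"{kid}/{condition}/bold"] = seed
                    stack = simulate_bold(cond_truth, cfg.echo_times, seed=seed)
                    summary = _fit_and_summarise(
                        cfg, cond_truth, stack, "t2star", kid, condition,
                        out_dir if cfg.save_nifti else None)
                    summaries.append(summary)
                    bold_medians.append(_median_lookup(summary, kid, condition, "whole_kidney", "t2_star"))
                if all(np.isfinite(v) for v in bold_medians):
                    timecourses.append(TimecourseMeasurements(
                        unit_id=kid, baseline=bold_medians[0], post=tuple(bold_medians[1:])))
    except Exception as exc:
        raise RuntimeError(f"experiment stage failed for design {cfg.design!r}: {exc}") from exc

    summaries = pd.concat(summaries, ignore_index=True)
    kidney_ids = sorted(summaries.kidney_id.unique())

    stats: dict = {"design": cfg.design, "n_kidneys": cfg.n_kidneys,
                   "notes": ["no multiple-testing correction across parameters/regions",
                             "kidneys treated as independent subjects"]}
    pct = None
    if cfg.design == "repeatability":
        stats["repeatability"] = _paired_stats(summaries, kidney_ids, "scan1", "scan2")
        stats["adc_d_correlation"] = _adc_d_correlation(summaries, "scan1")
    else:
        stats["challenge"] = _paired_stats(summaries, kidney_ids, "pre", "post")
        stats["adc_d_correlation"] = {
            "pre": _adc_d_correlation(summaries, "pre"),
            "post": _adc_d_correlation(summaries, "post"),
        }
    if cfg.fit_bold and len(timecourses) >= 2:
        tc = bold_timecourse_test(timecourses)
        stats["bold_timecourse"] = {
            "omnibus_f": tc.omnibus_f, "omnibus_p": tc.omnibus_p, "n_units": tc.n_units,
            "vs_baseline_p": tc.vs_baseline_p, "vs_previous_p": tc.vs_previous_p,
            "flags": tc.flags, "notes": tc.notes,
        }
        pct = percent_change(timecourses)

    bundle = ResultsBundle(config=cfg, summaries=summaries, stats=stats,
                           percent_change=pct, seeds=seeds)
    if out_dir:
        bundle.save(out_dir)
    return bundle


def report(bundle: ResultsBundle) -> str:
    """Render a bundle as a human-readable text report in reporting units."""
    lines: list[str] = []
    cfg = bundle.config
    if bundle.summaries.empty:
        return "no results\n"
    lines.append(f"renalmri {__version__} — design: {cfg.design}, {cfg.n_kidneys} kidneys, seed {cfg.seed}")
    lines.append("")

    conditions = list(dict.fromkeys(bundle.summaries.condition))
    key = "repeatability" if cfg.design == "repeatability" else "challenge"
    paired = bundle.stats.get(key, {})
    cond_pair = ("scan1", "scan2") if cfg.design == "repeatability" else ("pre", "post")
    third = "CoV (%)" if cfg.design == "repeatability" else "p"
    for region in _REGIONS:
        if region not in paired:
            continue
        lines.append(f"[{region}]")
        lines.append(f"  {'parameter':<10} {cond_pair[0]:>10} {cond_pair[1]:>10} {third:>10}  flag")
        for parameter, entry in paired[region].items():
            v1 = np.nanmean([
                _median_lookup(bundle.summaries, kid, cond_pair[0], region, parameter)
                for kid in sorted(bundle.summaries.kidney_id.unique())])
            v2 = np.nanmean([
                _median_lookup(bundle.summaries, kid, cond_pair[1], region, parameter)
                for kid in sorted(bundle.summaries.kidney_id.unique())])
            stat = entry["cov_percent"] if cfg.design == "repeatability" else entry.get("p_value", np.nan)
            flag = "a" if entry.get("significant") else ""
            lines.append(f"  {parameter:<10} {v1:>10.2f} {v2:>10.2f} {stat:>10.3f}  {flag}")
        lines.append("")

    if "bold_timecourse" in bundle.stats:
        tc = bundle.stats["bold_timecourse"]
        lines.append(f"BOLD T2* timecourse: omnibus F={tc['omnibus_f']:.2f}, p={tc['omnibus_p']:.4g}")
        for label, flag in tc["flags"].items():
            lines.append(f"  {label}: flags={flag or '-'}")
        lines.append("")
    n_excl = bundle.summaries["n_excluded"].sum()
    lines.append(f"non-converged voxels excluded from medians: {int(n_excl)}")
    if bundle.exclusions.records:
        lines.append(f"excluded kidneys: {bundle.exclusions.records}")
    return "\n".join(lines) + "\n"
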