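"""ROI construction and robust per-region summaries of parameter maps.

The kidney ROI on the analysed slice is split into a cortex, defined as the
single-voxel-wide outline of the kidney mask, and a medulla, the region
inside.  Region medians are reported rather than means, which suppresses the
influence of voxels where fitting did not converge; non-converged voxels are
excluded from the median outright and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .signal_models import REPORT_SCALE, REPORT_UNITS

__all__ = [
    "BACKGROUND",
    "CORTEX",
    "MEDULLA",
    "RegionSet",
    "ExclusionLog",
    "derive_regions",
    "summarise",
    "exclude_kidney",
]

BACKGROUND, CORTEX, MEDULLA = 0, 1, 2

_REGION_NAMES = {CORTEX: "cortex", MEDULLA: "medulla"}

# 4-connected (cross) structuring element; 8-connectivity optional.
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class RegionSet:
    """Label map partitioning a slice into background / cortex / medulla.

    ``labels`` holds 0 (background), 1 (cortex) and 2 (medulla); the whole
    kidney is the union of cortex and medulla.  ``provenance`` records how the
    regions were obtained (e.g. ``"phantom_truth"`` or ``"loaded_mask"``).
    """

    labels: np.ndarray
    provenance: str = "derived"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D slice")
        if not np.isin(labels, (BACKGROUND, CORTEX, MEDULLA)).all():
            raise ValueError("labels must contain only {0, 1, 2}")
        object.__setattr__(self, "labels", labels.astype(np.int16))

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.labels == CORTEX

    @property
    def medulla_mask(self) -> np.ndarray:
        return self.labels == MEDULLA

    @property
    def whole_kidney_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND

    def region_masks(self, bold: bool = False) -> dict[str, np.ndarray]:
        """Masks keyed by region name.

        With ``bold=True`` only the whole-kidney ROI is returned: the thick
        BOLD slice suffers partial-volume mixing that precludes a reliable
        cortex/medulla separation, so subregions are not summarised for T2*.
        """
        masks = {"whole_kidney": self.whole_kidney_mask}
        if not bold:
            masks["cortex"] = self.cortex_mask
            masks["medulla"] = self.medulla_mask
        return masks


def derive_regions(
    kidney_mask: np.ndarray,
    connectivity: int = 4,
    provenance: str = "derived",
) -> RegionSet:
    """Split a binary kidney mask into a one-voxel cortical rim and medullary interior.

    The cortex is the mask minus its one-step binary erosion; the medulla is
    the erosion.  Their union reconstructs the mask exactly.

    Raises
    ------
    ValueError
        If the mask is empty, disconnected, or too thin to contain an interior.
    """
    mask = np.asarray(kidney_mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("kidney_mask must be a 2-D slice")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("kidney_mask is empty")
    _, n_components = ndimage.label(mask, structure=_STRUCT_8)
    if n_components != 1:
        raise ValueError(f"kidney_mask must be a single connected region, found {n_components}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT_4 if connectivity == 4 else _STRUCT_8
    interior = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    if not interior.any():
        raise ValueError(
            f"mask of {n} voxels has no interior after one-voxel erosion; "
            "geometry too thin for a cortex/medulla split"
        )
    labels = np.zeros(mask.shape, dtype=np.int16)
    labels[mask & ~interior] = CORTEX
    labels[interior] = MEDULLA
    return RegionSet(labels=labels, provenance=provenance)


def summarise(
    parameter_map,
    regions: RegionSet,
    kidney_id: str = "kidney",
    bold: bool | None = None,
) -> pd.DataFrame:
    """Median of each fitted parameter over each region, converged voxels only.

    Parameters are converted to reporting units.  Returns a tidy frame with
    columns kidney_id, region, parameter, median, units, n_voxels, n_excluded;
    a region with no converged voxels yields a NaN median and a warning.
    """
    if bold is None:
        bold = parameter_map.model == "t2star"
    if parameter_map.shape != regions.labels.shape:
        raise ValueError(
            f"grid mismatch: map {parameter_map.shape} vs regions {regions.labels.shape}"
        )
    rows = []
    converged = parameter_map.converged
    for region_name, region_mask in regions.region_masks(bold=bold).items():
        ok = region_mask & converged
        n_vox = int(ok.sum())
        n_excl = int((region_mask & ~converged & parameter_map.fitted).sum())
        for name, values in parameter_map.params.items():
            if n_vox == 0:
                warnings.warn(
                    f"{kidney_id}/{region_name}: no converged voxels for {name}",
                    stacklevel=2,
                )
                median = np.nan
            else:
                median = float(np.median(values[ok])) * REPORT_SCALE.get(name, 1.0)
            rows.append(
                {
                    "kidney_id": kidney_id,
                    "region": region_name,
                    "parameter": name,
                    "median": median,
                    "units": REPORT_UNITS.get(name, "a.u."),
                    "n_voxels": n_vox,
                    "n_excluded": n_excl,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ExclusionLog:
    """Audit trail of kidneys excluded from cohort statistics."""

    records: list[dict] = field(default_factory=list)

    def excluded_ids(self) -> set[str]:
        return {r["kidney_id"] for r in self.records}

    def filter(self, summaries: pd.DataFrame) -> pd.DataFrame:
        """Drop excluded kidneys; refuse if nothing is left."""
        kept = summaries[~summaries["kidney_id"].isin(self.excluded_ids())]
        if summaries.shape[0] > 0 and kept.shape[0] == 0:
            raise ValueError(
                "all kidneys are excluded; cohort statistics need at least one kidney "
                f"(exclusions: {self.records})"
            )
        return kept


def exclude_kidney(log: ExclusionLog, kidney_id: str, reason: str) -> dict:
    """Mark a kidney excluded (e.g. unreliable ROI placement) with a logged reason."""
    record = {"kidney_id": kidney_id, "reason": reason}
    log.records.append(record)
    return record
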