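"""ROI definition and per-region perfusion summaries.

Regions of interest follow the renal reading convention: cortex, medulla,
the entire tumor, and the solid part of the tumor avoiding the necrotic
area.  Necrosis presents as a central low-perfusion zone on the f map, so
the solid mask is derived by excluding the low-perfusion quantile within
the tumor; phantom-truth masks are also supported so tests are not hostage
to the heuristic.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np

from .quantify import PerfusionMap

__all__ = [
    "RegionMask",
    "RegionStats",
    "derive_solid_mask",
    "region_mean",
    "build_patient_row",
    "COHORT_COLUMNS",
]

ROI_KINDS = ("cortex", "medulla", "tumor_entire", "tumor_solid")


@dataclass(frozen=True)
class RegionMask:
    mask: np.ndarray  # bool, voxel-aligned with the map
    roi_kind: str
    source: str = "phantom_truth"  # or "threshold_derived", "file"

    def __post_init__(self) -> None:
        if self.roi_kind not in ROI_KINDS:
            raise ValueError(f"unknown roi_kind {self.roi_kind!r}")


@dataclass(frozen=True)
class RegionStats:
    roi_kind: str
    pld: float
    mean_f: float
    sd_f: float
    n_voxels: int
    frac_valid: float


def derive_solid_mask(
    f_map: PerfusionMap,
    tumor_mask: np.ndarray,
    necrosis_quantile: float = 0.25,
) -> RegionMask:
    """Solid-tumor mask: tumor voxels above the low-perfusion quantile.

    The within-tumor perfusion quantile at ``necrosis_quantile`` (default
    0.25) separates the necrotic core from the solid rim; voxels strictly
    above it form the solid mask.  A homogeneous tumor (quantile ties the
    maximum) or ``necrosis_quantile = 0`` retains every valid tumor voxel.
    The result is always a subset of the tumor mask and shrinks (weakly)
    as the quantile grows.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor mask is empty")
    if not 0.0 <= necrosis_quantile < 1.0:
        raise ValueError("necrosis_quantile must be in [0, 1)")
    inside = tumor_mask & f_map.valid
    if not inside.any():
        raise ValueError("tumor mask contains no valid voxels")
    vals = f_map.f[inside]
    thr = float(np.quantile(vals, necrosis_quantile))
    if necrosis_quantile == 0.0 or vals.min() == vals.max():
        solid = inside  # homogeneous tumor or quantile 0: keep everything valid
    else:
        solid = inside & (f_map.f > thr)
        if not solid.any():  # threshold tied the maximum: keep the top ties
            solid = inside & (f_map.f >= vals.max())
    return RegionMask(mask=solid, roi_kind="tumor_solid", source="threshold_derived")


def region_mean(f_map: PerfusionMap, mask: RegionMask) -> RegionStats:
    """Mean and sample SD of perfusion over the valid voxels of a mask.

    ``frac_valid`` reports which fraction of the mask contributed, so
    degraded fits are visible rather than silently averaged.
    """
    m = np.asarray(mask.mask, dtype=bool)
    if m.shape != f_map.f.shape:
        raise ValueError("mask shape does not match map shape")
    use = m & f_map.valid
    n_mask = int(m.sum())
    n_use = int(use.sum())
    if n_use == 0:
        raise ValueError(f"no valid voxels inside {mask.roi_kind} mask")
    vals = f_map.f[use]
    sd = float(np.std(vals, ddof=1)) if n_use > 1 else 0.0
    return RegionStats(
        roi_kind=mask.roi_kind,
        pld=float(f_map.meta.get("pld_nominal", np.nan)),
        mean_f=float(vals.mean()),
        sd_f=sd,
        n_voxels=n_mask,
        frac_valid=n_use / n_mask,
    )


# cohort CSV schema shared with the synthetic-cohort generator
COHORT_COLUMNS = (
    "patient_id",
    "mvi",
    "diameter_cm",
    "margin",
    "shape",
    "isup",
    "entire_pld1",
    "entire_pld2",
    "entire_pld3",
    "solid_pld1",
    "solid_pld2",
    "solid_pld3",
)

_ROI_TO_PREFIX = {"tumor_entire": "entire", "tumor_solid": "solid"}


def build_patient_row(
    stats: Iterable[RegionStats],
    metadata: Dict[str, object],
    plds: Sequence[float] = (500.0, 1000.0, 2000.0),
) -> Dict[str, object]:
    """Assemble one cohort-table row from per-(ROI, PLD) summaries.

    Missing (roi_kind, PLD) combinations yield explicit empty cells (NaN),
    never silently dropped rows; duplicate combinations are an error.
    ``metadata`` supplies patient_id, mvi and the covariate cells.
    """
    row: Dict[str, object] = {c: np.nan for c in COHORT_COLUMNS}
    for key in ("patient_id", "mvi", "diameter_cm", "margin", "shape", "isup"):
        if key in metadata:
            row[key] = metadata[key]
    seen = set()
    pld_index = {float(p): i + 1 for i, p in enumerate(plds)}
    for st in stats:
        if st.roi_kind not in _ROI_TO_PREFIX:
            continue  # cortex/medulla summaries live in the sessions table
        key = (st.roi_kind, float(st.pld))
        if key in seen:
            raise ValueError(f"duplicate stats for {key}")
        seen.add(key)
        if float(st.pld) not in pld_index:
            raise ValueError(f"pld {st.pld} not one of the configured PLDs {plds}")
        col = f"{_ROI_TO_PREFIX[st.roi_kind]}_pld{pld_index[float(st.pld)]}"
        row[col] = st.mean_f
    return row
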