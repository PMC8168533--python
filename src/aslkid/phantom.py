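"""Digital kidney/tumor phantoms.

A phantom is a 3-D label map plus per-voxel ground-truth tissue parameter
maps (perfusion, tissue T1, arterial transit time, equilibrium
magnetization).  Regions are geometric primitives — spheres, ellipsoids and
spherical shells — rasterized in order, with later regions overwriting
earlier ones on overlap.  The default phantom mimics the topology seen on
renal perfusion maps: a high-perfusion cortical shell around a lower-flow
medullary core, and a hyperperfused tumor with a necrotic low-flow center.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "TissueParams",
    "Region",
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "default_phantom_spec",
    "REGION_LABELS",
]

#: canonical region taxonomy; background voxels carry code 0
REGION_LABELS = ("background", "cortex", "medulla", "tumor_solid", "tumor_necrosis")


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth tissue parameters of one phantom region.

    f_true is perfusion in ml/100 g/min, t1_tissue and att in ms, m0 in
    arbitrary signal units.
    """

    f_true: float
    t1_tissue: float
    att: float = 0.0
    m0: float = 100.0

    def __post_init__(self) -> None:
        if self.f_true < 0:
            raise ValueError("f_true must be non-negative")
        if self.t1_tissue <= 0:
            raise ValueError("t1_tissue must be positive")
        if self.att < 0:
            raise ValueError("att must be non-negative")
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")


@dataclass(frozen=True)
class Region:
    """One geometric region: a sphere, ellipsoid, or spherical shell.

    ``center`` and radii are in millimetres (the phantom's voxel_size converts
    them to voxels).  For ``shape == "shell"``, ``radii`` is
    (inner_radius, outer_radius); for a sphere a single radius; for an
    ellipsoid one semi-axis per grid dimension.
    """

    label: str
    shape: str
    center: Tuple[float, ...]
    radii: Tuple[float, ...]
    params: TissueParams

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if self.shape not in ("sphere", "ellipsoid", "shell"):
            raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomSpec:
    grid_shape: Tuple[int, int, int]
    regions: Tuple[Region, ...]
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")


@dataclass
class Phantom:
    """Rasterized phantom: label codes and ground-truth parameter maps."""

    spec: PhantomSpec
    labels: np.ndarray  # int codes indexing REGION_LABELS
    f_true: np.ndarray
    t1_tissue: np.ndarray
    att: np.ndarray
    m0: np.ndarray

    def mask(self, label: str) -> np.ndarray:
        """Boolean mask of all voxels carrying ``label``."""
        code = REGION_LABELS.index(label)
        return self.labels == code

    @property
    def tumor_entire_mask(self) -> np.ndarray:
        return self.mask("tumor_solid") | self.mask("tumor_necrosis")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels > 0


def _region_mask(region: Region, spec: PhantomSpec) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * v for n, v in zip(spec.grid_shape, spec.voxel_size)],
        indexing="ij",
    )
    if region.shape == "shell":
        r_in, r_out = region.radii
        d2 = sum((g - c) ** 2 for g, c in zip(grids, region.center))
        return (d2 <= r_out**2) & (d2 > r_in**2)
    radii = region.radii if region.shape == "ellipsoid" else region.radii * 3
    if len(radii) < 3:
        radii = tuple(radii) + (radii[-1],) * (3 - len(radii))
    q = sum(
        ((g - c) / r) ** 2 for g, c, r in zip(grids, region.center, radii)
    )
    return q <= 1.0


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a phantom spec into label and parameter maps.

    Regions are painted in list order; on overlap the later region wins.
    Background voxels get f_true = 0, m0 = 0 and a placeholder T1 of 1 ms so
    downstream exponentials stay finite.

    Raises
    ------
    ValueError
        If the region list is empty or a region rasterizes to no voxels
        inside the grid (the error names the offending region).
    """
    if len(spec.regions) == 0:
        raise ValueError("phantom spec has no regions")
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    f_true = np.zeros(spec.grid_shape, dtype=float)
    t1 = np.ones(spec.grid_shape, dtype=float)
    att = np.zeros(spec.grid_shape, dtype=float)
    m0 = np.zeros(spec.grid_shape, dtype=float)
    for region in spec.regions:
        mask = _region_mask(region, spec)
        if not mask.any():
            raise ValueError(
                f"region {region.label!r} ({region.shape} at {region.center}) "
                "lies outside the grid"
            )
        labels[mask] = REGION_LABELS.index(region.label)
        f_true[mask] = region.params.f_true
        t1[mask] = region.params.t1_tissue
        att[mask] = region.params.att
        m0[mask] = region.params.m0
    return Phantom(spec=spec, labels=labels, f_true=f_true, t1_tissue=t1, att=att, m0=m0)


# physiological defaults; perfusion in ml/100 g/min, T1 in ms
DEFAULT_TISSUE = {
    "cortex": TissueParams(f_true=250.0, t1_tissue=1150.0),
    "medulla": TissueParams(f_true=60.0, t1_tissue=1500.0),
    "tumor_solid": TissueParams(f_true=300.0, t1_tissue=1400.0),
    "tumor_necrosis": TissueParams(f_true=10.0, t1_tissue=1800.0),
}


def default_phantom_spec(
    grid_shape: Tuple[int, int, int] = (32, 32, 7),
    tissue: Dict[str, TissueParams] | None = None,
    seed: int = 0,
) -> PhantomSpec:
    """Kidney-and-tumor phantom scaled to an arbitrary grid.

    One kidney (cortical shell around a medullary core) in the left half of
    the grid and a tumor with a necrotic center in the right half.  Region
    sizes scale with the grid so small test grids keep all five labels.
    """
    t = dict(DEFAULT_TISSUE)
    if tissue:
        t.update(tissue)
    nx, ny, nz = grid_shape
    zc = (nz - 1) / 2.0
    kidney_c = (nx * 0.30, ny * 0.50, zc)
    tumor_c = (nx * 0.72, ny * 0.50, zc)
    r_kid = min(nx, ny) * 0.22
    r_med = r_kid * 0.55
    r_tum = min(nx, ny) * 0.16
    r_nec = r_tum * 0.45
    rz = max(1.0, nz * 0.45)
    regions = (
        Region("cortex", "ellipsoid", kidney_c, (r_kid, r_kid, rz), t["cortex"]),
        Region("medulla", "ellipsoid", kidney_c, (r_med, r_med, rz * 0.6), t["medulla"]),
        Region("tumor_solid", "ellipsoid", tumor_c, (r_tum, r_tum, rz * 0.8), t["tumor_solid"]),
        Region("tumor_necrosis", "ellipsoid", tumor_c, (r_nec, r_nec, rz * 0.4), t["tumor_necrosis"]),
    )
    return PhantomSpec(grid_shape=grid_shape, regions=regions, seed=seed)
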