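"""Forward simulation of ASL sessions: signal model, noise, motion.

A session holds, per nominal PLD, a stack of control/label image pairs in
acquisition order ``[control_1, label_1, control_2, label_2, ...]`` along the
fourth axis, plus a base M0 image and an inversion-recovery series for T1
mapping.  The control image is the equilibrium-magnetization-weighted
signal; the label image is control − ΔM_true, with ΔM_true evaluated from
the kinetic model at each voxel's tissue parameters and each slice's
effective post-label delay.  Noise is additive Gaussian, independent per
image (subtraction of two Gaussian images stays Gaussian, which keeps the
ΔM noise model zero-mean).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .kinetics import buxton_delta_m
from .phantom import Phantom
from .protocol import ASLProtocol, effective_pld

__all__ = [
    "ASLSession",
    "simulate_asl_session",
    "simulate_ir_series",
    "inject_motion",
]


@dataclass
class ASLSession:
    """One subject's multi-PLD ASL acquisition.

    ``stacks[pld]`` has shape ``grid_shape + (2 * n_pairs,)`` with controls
    at even and labels at odd fourth-axis indices.  The slice axis is the
    third voxel axis; slice index 0 is acquired first unless the protocol
    configures an ordering table.
    """

    stacks: Dict[float, np.ndarray]
    m0: np.ndarray
    ir: np.ndarray  # shape grid + (n_TI,)
    protocol: ASLProtocol
    meta: dict = field(default_factory=dict)

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.m0.shape

    def n_pairs(self, pld: float) -> int:
        return self.stacks[pld].shape[-1] // 2

    def controls(self, pld: float) -> np.ndarray:
        return self.stacks[pld][..., 0::2]

    def labels(self, pld: float) -> np.ndarray:
        return self.stacks[pld][..., 1::2]


def simulate_ir_series(phantom: Phantom, ir_tis) -> np.ndarray:
    """Noise-free signed inversion-recovery series.

    Voxel signal at inversion time TI is ``m0 · (1 − 2·exp(−TI/T1))``: fully
    inverted at TI → 0, through the null point at TI = T1·ln 2, recovering
    to m0.  Polarity is preserved (signed convention); take ``np.abs`` of
    the result for a magnitude-mode series.
    """
    tis = np.asarray(ir_tis, dtype=float)
    if tis.size == 0:
        raise ValueError("ir_tis must be non-empty")
    if np.any(tis <= 0):
        raise ValueError("all inversion times must be positive")
    ti = tis.reshape((1, 1, 1, -1))
    t1 = phantom.t1_tissue[..., None]
    m0 = phantom.m0[..., None]
    return m0 * (1.0 - 2.0 * np.exp(-ti / t1))


def _slice_pld_grid(protocol: ASLProtocol, pld: float, grid_shape) -> np.ndarray:
    effs = np.array(
        [effective_pld(protocol, pld, s) for s in range(grid_shape[2])]
    )
    return effs.reshape((1, 1, -1))


def simulate_asl_session(
    phantom: Phantom,
    protocol: ASLProtocol,
    noise_sd: float,
    seed: int,
    calib_noise_sd: Optional[float] = None,
) -> ASLSession:
    """Forward-simulate one ASL session from a phantom.

    Parameters
    ----------
    noise_sd:
        Standard deviation of the additive Gaussian noise on every image,
        in signal units.  0 gives the exact forward model.
    calib_noise_sd:
        Optional separate noise level for the M0 and inversion-recovery
        images.  Default ``None`` applies ``noise_sd`` to every image; in
        practice the single-shot difference pairs are far noisier than the
        calibration images, so the repro-study pipeline sets this lower.
    seed:
        Seeds a dedicated generator; identical seeds give bit-identical
        sessions.
    """
    if phantom.m0.shape[2] != protocol.n_slices:
        raise ValueError(
            f"phantom has {phantom.m0.shape[2]} slices, protocol expects "
            f"{protocol.n_slices}"
        )
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if calib_noise_sd is None:
        calib_noise_sd = noise_sd
    if calib_noise_sd < 0:
        raise ValueError("calib_noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    stacks: Dict[float, np.ndarray] = {}
    for pld in protocol.plds:
        pld_eff = _slice_pld_grid(protocol, pld, phantom.m0.shape)
        dm_true = buxton_delta_m(
            phantom.f_true,
            protocol.constants,
            phantom.t1_tissue,
            pld_eff,
            phantom.m0,
            att=phantom.att,
        )
        stack = np.empty(phantom.m0.shape + (2 * protocol.n_pairs,), dtype=float)
        for i in range(protocol.n_pairs):
            noise_c = rng.normal(0.0, noise_sd, phantom.m0.shape) if noise_sd else 0.0
            noise_l = rng.normal(0.0, noise_sd, phantom.m0.shape) if noise_sd else 0.0
            stack[..., 2 * i] = phantom.m0 + noise_c
            stack[..., 2 * i + 1] = phantom.m0 - dm_true + noise_l
        stacks[pld] = stack

    m0_img = phantom.m0 + (
        rng.normal(0.0, calib_noise_sd, phantom.m0.shape) if calib_noise_sd else 0.0
    )
    ir = simulate_ir_series(phantom, protocol.ir_tis)
    if calib_noise_sd:
        ir = ir + rng.normal(0.0, calib_noise_sd, ir.shape)
    return ASLSession(
        stacks=stacks,
        m0=m0_img,
        ir=ir,
        protocol=protocol,
        meta={"noise_sd": noise_sd, "calib_noise_sd": calib_noise_sd, "seed": seed},
    )


def _shift_replicate(img: np.ndarray, axis: int, shift: int) -> np.ndarray:
    """Rigid in-plane translation with edge-voxel replication."""
    n = img.shape[axis]
    idx = np.clip(np.arange(n) - shift, 0, n - 1)
    return np.take(img, idx, axis=axis)


def inject_motion(
    session: ASLSession,
    fraction: float,
    shift_voxels: int,
    seed: int,
) -> Tuple[ASLSession, Dict[float, List[int]]]:
    """Corrupt a random fraction of pairs with a rigid in-plane shift.

    In each PLD stack, ``floor(fraction · n_pairs)`` randomly chosen pairs
    have their label image translated by ``shift_voxels`` along a random
    in-plane axis and direction (edge voxels replicated) — emulating a
    failed breath-hold between the control and label acquisitions.  Returns
    a new session and, per PLD, the sorted list of corrupted pair indices
    (the ground truth for rejection tests).  The input session is not
    modified.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if shift_voxels < 1:
        raise ValueError("shift_voxels must be >= 1")
    if shift_voxels >= min(session.grid_shape[0], session.grid_shape[1]):
        raise ValueError("shift_voxels exceeds the in-plane grid size")

    rng = np.random.default_rng(seed)
    new_stacks: Dict[float, np.ndarray] = {}
    corrupted: Dict[float, List[int]] = {}
    for pld, stack in session.stacks.items():
        stack = stack.copy()
        n_pairs = stack.shape[-1] // 2
        n_bad = int(np.floor(fraction * n_pairs))
        idx = sorted(rng.choice(n_pairs, size=n_bad, replace=False).tolist())
        for i in idx:
            axis = int(rng.integers(0, 2))
            sign = 1 if rng.integers(0, 2) else -1
            stack[..., 2 * i + 1] = _shift_replicate(
                stack[..., 2 * i + 1], axis, sign * shift_voxels
            )
        new_stacks[pld] = stack
        corrupted[pld] = idx
    shifted = ASLSession(
        stacks=new_stacks,
        m0=session.m0.copy(),
        ir=session.ir.copy(),
        protocol=session.protocol,
        meta={**session.meta, "motion_fraction": fraction, "motion_shift": shift_voxels},
    )
    return shifted, corrupted
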