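"""ASL quantification: ΔM formation, motion rejection, T1 mapping, inversion.

The processing chain mirrors the standard renal pCASL recipe: per-pair
difference images are formed by control − label subtraction, pairs corrupted
by breath-hold failure are rejected by a robust outlier statistic, the
survivors are averaged and normalized to the base M0 image, a two-parameter
inversion-recovery fit supplies the tissue T1 map, and the kinetic model is
inverted — per slice, at the exact post-label delay that slice was acquired
at — to yield perfusion in ml/100 g/min.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .kinetics import KineticConstants, buxton_delta_m, whitepaper_perfusion
from .protocol import ASLProtocol, effective_pld
from .simulate import ASLSession

__all__ = [
    "PairStack",
    "T1Map",
    "PerfusionMap",
    "compute_delta_m",
    "reject_misaligned_pairs",
    "average_and_normalize",
    "fit_t1_map",
    "invert_single_pld",
    "fit_multi_pld",
    "quantify_session",
]


@dataclass
class PairStack:
    """Stack of per-pair ΔM images for one nominal PLD."""

    delta_m: np.ndarray  # grid + (n_pairs,)
    pld_nominal: float
    kept_mask: np.ndarray  # (n_pairs,) bool
    scores: Optional[np.ndarray] = None  # filled by reject_misaligned_pairs

    @property
    def n_pairs(self) -> int:
        return self.delta_m.shape[-1]


@dataclass
class T1Map:
    t1: np.ndarray  # ms
    amplitude: np.ndarray
    fit_ok: np.ndarray  # bool


@dataclass
class PerfusionMap:
    """Voxelwise perfusion with a validity mask and per-slice timing."""

    f: np.ndarray  # ml/100 g/min
    valid: np.ndarray  # bool
    pld_effective: np.ndarray  # (n_slices,) ms
    att: Optional[np.ndarray] = None  # only from the multi-PLD fit
    meta: dict = field(default_factory=dict)


def compute_delta_m(
    session: ASLSession, pld: float, subtraction_order: str = "control-label"
) -> PairStack:
    """Form the per-pair perfusion-weighted difference stack.

    The default convention subtracts label from control so that perfusion
    yields a positive ΔM; ``subtraction_order="label-control"`` flips the
    sign for data following the opposite selective/non-selective naming.
    """
    if pld not in session.stacks:
        raise KeyError(f"session has no PLD {pld}; available: {list(session.stacks)}")
    stack = session.stacks[pld]
    if stack.shape[-1] % 2:
        raise ValueError("odd image count: controls and labels must alternate")
    controls = stack[..., 0::2]
    labels = stack[..., 1::2]
    if controls.shape != labels.shape:
        raise ValueError("control/label shape mismatch")
    if subtraction_order == "control-label":
        dm = controls - labels
    elif subtraction_order == "label-control":
        dm = labels - controls
    else:
        raise ValueError(f"unknown subtraction_order {subtraction_order!r}")
    kept = np.ones(dm.shape[-1], dtype=bool)
    return PairStack(delta_m=dm, pld_nominal=float(pld), kept_mask=kept)


def reject_misaligned_pairs(stack: PairStack, z_threshold: float = 3.0) -> PairStack:
    """Flag motion-corrupted pairs by a robust outlier statistic.

    Each pair is scored by the mean absolute deviation of its ΔM image from
    the voxelwise median ΔM image; scores are standardized by median/MAD and
    pairs with robust z-score above ``z_threshold`` are dropped.  At least
    one pair always survives: if everything is flagged, the lowest-scoring
    pair is kept.
    """
    n = stack.n_pairs
    if n < 3:
        raise ValueError("need at least 3 pairs for a robust median reference")
    median_img = np.median(stack.delta_m, axis=-1)
    flat = stack.delta_m.reshape(-1, n)
    scores = np.mean(np.abs(flat - median_img.reshape(-1, 1)), axis=0)
    med = np.median(scores)
    mad = np.median(np.abs(scores - med))
    if mad == 0.0:
        z = np.where(scores == med, 0.0, np.inf)
    else:
        z = (scores - med) / (1.4826 * mad)
    kept = z <= z_threshold
    if not kept.any():
        kept[np.argmin(scores)] = True
    return PairStack(
        delta_m=stack.delta_m,
        pld_nominal=stack.pld_nominal,
        kept_mask=kept & stack.kept_mask,
        scores=scores,
    )


def average_and_normalize(
    stack: PairStack, m0_image: np.ndarray, m0_floor: float = 1e-6
) -> Tuple[np.ndarray, np.ndarray]:
    """Average the kept ΔM pairs and normalize to the base M0 image.

    Returns ``(dm_norm, valid)`` where voxels with M0 below ``m0_floor``
    are marked invalid (and divided by the floor rather than blowing up).
    """
    if not stack.kept_mask.any():
        raise ValueError("no kept pairs to average")
    mean_dm = stack.delta_m[..., stack.kept_mask].mean(axis=-1)
    valid = m0_image >= m0_floor
    dm_norm = mean_dm / np.maximum(m0_image, m0_floor)
    return dm_norm, valid


# ---------------------------------------------------------------------------
# T1 mapping


def _ir_profile_sse(t1: float, signals: np.ndarray, tis: np.ndarray) -> float:
    """Profiled residual: amplitude solved in closed form for a given T1."""
    g = 1.0 - 2.0 * np.exp(-tis / t1)
    gg = float(g @ g)
    a = float(signals @ g) / gg
    r = signals - a * g
    return float(r @ r)


def fit_t1_map(
    ir_stack: np.ndarray,
    ir_tis,
    t1_bounds: Tuple[float, float] = (200.0, 3000.0),
    n_grid: int = 20,
    rel_resid_tol: float = 0.05,
    mask: Optional[np.ndarray] = None,
) -> T1Map:
    """Two-parameter inversion-recovery fit, ``S(TI) = A·(1 − 2·exp(−TI/T1))``.

    The fit exploits the model's conditional linearity: for any candidate
    T1 the amplitude A has a closed-form least-squares solution, so the
    2-parameter problem reduces to a 1-D profiled search over T1.  A coarse
    log-spaced grid over ``t1_bounds`` (default 20 nodes) brackets the
    optimum and a bounded local refinement polishes it.

    ``fit_ok`` is set False where the relative residual norm exceeds
    ``rel_resid_tol``, where T1 lands on a bound, or where the signal is
    degenerate (e.g. an all-zero voxel).

    Parameters operate on signed IR data by default.  For magnitude data,
    restore polarity first by negating samples before the signal minimum.
    """
    tis = np.asarray(ir_tis, dtype=float)
    if tis.size < 3:
        raise ValueError("need at least 3 inversion times for a 2-parameter fit")
    lo, hi = t1_bounds
    if not (0 < lo < hi):
        raise ValueError("t1_bounds must satisfy 0 < lo < hi")

    grid_shape = ir_stack.shape[:-1]
    signals = ir_stack.reshape(-1, tis.size)
    n_vox = signals.shape[0]
    vox_mask = (
        np.ones(n_vox, dtype=bool) if mask is None else np.asarray(mask).reshape(-1)
    )

    nodes = np.logspace(np.log10(lo), np.log10(hi), n_grid)
    # vectorized coarse grid: design vectors g_k and closed-form amplitudes
    g = 1.0 - 2.0 * np.exp(-tis.reshape(-1, 1) / nodes.reshape(1, -1))  # (nTI, K)
    gg = np.sum(g * g, axis=0)  # (K,)
    sg = signals @ g  # (V, K)
    amp = sg / gg
    ss = np.sum(signals**2, axis=1, keepdims=True)
    sse = ss - amp * sg  # profiled SSE per node (V, K)
    best = np.argmin(sse, axis=1)

    t1_out = np.full(n_vox, np.nan)
    a_out = np.zeros(n_vox)
    ok = np.zeros(n_vox, dtype=bool)
    log_nodes = np.log10(nodes)
    for v in np.nonzero(vox_mask)[0]:
        s = signals[v]
        energy = float(s @ s)
        if energy <= 0.0:
            continue
        k = best[v]
        blo = nodes[max(k - 1, 0)]
        bhi = nodes[min(k + 1, n_grid - 1)]
        if blo == bhi:  # best at a grid edge
            blo, bhi = max(lo, blo * 0.8), min(hi, bhi * 1.25)
        res = minimize_scalar(
            _ir_profile_sse,
            bounds=(blo, bhi),
            args=(s, tis),
            method="bounded",
            options={"xatol": 1e-6},
        )
        t1_hat = float(res.x)
        gv = 1.0 - 2.0 * np.exp(-tis / t1_hat)
        a_hat = float(s @ gv) / float(gv @ gv)
        resid = float(np.sum((s - a_hat * gv) ** 2))
        t1_out[v] = t1_hat
        a_out[v] = a_hat
        at_bound = t1_hat <= lo * 1.001 or t1_hat >= hi * 0.999
        ok[v] = (resid <= rel_resid_tol**2 * energy) and not at_bound and a_hat > 0
    return T1Map(
        t1=t1_out.reshape(grid_shape),
        amplitude=a_out.reshape(grid_shape),
        fit_ok=ok.reshape(grid_shape),
    )


# ---------------------------------------------------------------------------
# Kinetic inversion


def _slice_plds(protocol: ASLProtocol, pld: float, n_slices: int) -> np.ndarray:
    return np.array([effective_pld(protocol, pld, s) for s in range(n_slices)])


def invert_single_pld(
    dm_norm: np.ndarray,
    t1_map: T1Map,
    protocol: ASLProtocol,
    constants: KineticConstants,
    pld: float,
    valid_in: Optional[np.ndarray] = None,
    mode: str = "buxton",
    f_max: float = 5000.0,
    nonpositive_as_nan: bool = False,
) -> PerfusionMap:
    """Invert the kinetic model at one nominal PLD.

    ΔM is linear in perfusion, so each voxel solves in closed form:
    ``f = dm_norm / buxton_delta_m(f=1, m0=1, ...)`` evaluated at that
    voxel's fitted T1 and its slice's effective post-label delay.  Voxels
    with non-positive or non-finite ΔM get f = 0 and ``valid = False``
    (NaN instead if ``nonpositive_as_nan``); estimates above ``f_max`` are
    clipped and invalidated.  ``mode="whitepaper"`` uses the one-compartment
    shortcut formula instead of the compartment-model division.
    """
    if pld not in protocol.plds:
        raise ValueError(f"pld {pld} not in protocol plds {protocol.plds}")
    n_slices = dm_norm.shape[2]
    slice_plds = _slice_plds(protocol, pld, n_slices)
    tau, att = constants.label_duration, constants.att
    if np.all(slice_plds + tau <= att):
        raise ValueError(
            "bolus never arrives before readout at any slice: model uninformative"
        )
    pld_grid = slice_plds.reshape((1, 1, -1))
    if mode == "buxton":
        with np.errstate(divide="ignore", invalid="ignore"):
            unit = buxton_delta_m(1.0, constants, t1_map.t1, pld_grid, 1.0)
            f = np.where(unit > 0, dm_norm / np.where(unit > 0, unit, 1.0), np.nan)
        model_ok = (unit > 0) & t1_map.fit_ok
    elif mode == "whitepaper":
        f = whitepaper_perfusion(dm_norm, pld_grid, constants)
        f = np.broadcast_to(f, dm_norm.shape).copy()
        model_ok = np.ones_like(dm_norm, dtype=bool)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    valid = model_ok if valid_in is None else (model_ok & valid_in)
    nonpos = ~(dm_norm > 0) | ~np.isfinite(f)
    fill = np.nan if nonpositive_as_nan else 0.0
    f = np.where(nonpos, fill, f)
    valid = valid & ~nonpos
    over = valid & (f > f_max)
    f = np.where(over, f_max, f)
    valid = valid & ~over
    return PerfusionMap(
        f=f,
        valid=valid,
        pld_effective=slice_plds,
        meta={"pld_nominal": float(pld), "mode": mode},
    )


def fit_multi_pld(
    dm_norm_by_pld: Dict[float, np.ndarray],
    t1_map: T1Map,
    protocol: ASLProtocol,
    constants: KineticConstants,
    valid_in: Optional[np.ndarray] = None,
    f_max: float = 5000.0,
) -> PerfusionMap:
    """Joint (f, ATT) nonlinear least squares across all PLDs.

    Extension mode: per voxel, minimizes the squared misfit of the kinetic
    model to the normalized ΔM observed at every effective PLD, over
    perfusion and arterial transit time; ATT is bounded to
    ``[0, min(PLD) + τ]``.  Voxels whose observations are all non-positive
    get f = 0, ATT at the lower bound, and ``valid = False``.

    ATT is only identifiable when at least one readout falls before the
    end of bolus delivery (effective PLD ≤ ATT): once every sample sits in
    the post-bolus regime, all observations share the same exponential
    decay and (f, ATT) trade off along an exact ridge.  In that regime the
    fit returns one point of the ridge (f then still matches the ATT-free
    single-PLD estimate when the data were generated with ATT = 0).
    """
    plds = sorted(dm_norm_by_pld)
    if len(plds) < 2:
        raise ValueError("need >= 2 PLDs; use invert_single_pld for one PLD")
    shape = dm_norm_by_pld[plds[0]].shape
    n_slices = shape[2]
    tau = constants.label_duration
    att_hi = min(plds) + tau

    eff = {p: _slice_plds(protocol, p, n_slices) for p in plds}
    f_out = np.zeros(shape)
    att_out = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)
    base_ok = t1_map.fit_ok if valid_in is None else (t1_map.fit_ok & valid_in)

    for idx in np.ndindex(shape):
        if not base_ok[idx]:
            continue
        s = idx[2]
        obs = np.array([dm_norm_by_pld[p][idx] for p in plds])
        times = np.array([eff[p][s] for p in plds])
        t1v = t1_map.t1[idx]
        if not np.all(np.isfinite(obs)) or np.all(obs <= 0):
            continue

        def resid(x):
            return (
                buxton_delta_m(x[0], constants, t1v, times, 1.0, att=x[1]) - obs
            )

        best = None
        f0 = max(float(obs[-1]) / max(
            buxton_delta_m(1.0, constants, t1v, times[-1], 1.0, att=0.0), 1e-12
        ), 1.0)
        exact_fit = 1e-16 * float(obs @ obs)  # data fully explained
        for att0 in (0.0, att_hi * 0.25, att_hi * 0.5):
            sol = least_squares(
                resid,
                x0=(f0, att0),
                bounds=((0.0, 0.0), (f_max * 2, att_hi)),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            # on a (f, att) ridge every start fits exactly; keep the first
            # (smallest-att) solution rather than an arbitrary ridge point
            if best.cost <= exact_fit:
                break
        f_hat, att_hat = best.x
        ok = f_hat <= f_max
        f_out[idx] = min(f_hat, f_max)
        att_out[idx] = att_hat
        valid[idx] = ok
    return PerfusionMap(
        f=f_out,
        valid=valid,
        pld_effective=np.array([eff[p] for p in plds]).min(axis=0),
        att=att_out,
        meta={"plds": plds, "mode": "multi_pld"},
    )


def quantify_session(
    session: ASLSession,
    constants: Optional[KineticConstants] = None,
    z_threshold: float = 3.0,
    m0_floor: float = 1e-6,
    mode: str = "buxton",
    t1_bounds: Tuple[float, float] = (200.0, 3000.0),
) -> Tuple[Dict[float, PerfusionMap], T1Map, dict]:
    """Full single-PLD chain for every PLD of a session.

    Runs ΔM formation → motion rejection → averaging/M0 normalization →
    IR T1 fit → kinetic inversion, and returns per-PLD perfusion maps, the
    T1 map, and a QC report with rejected pair indices and per-slice
    effective PLDs.
    """
    protocol = session.protocol
    constants = constants if constants is not None else protocol.constants
    t1_map = fit_t1_map(session.ir, protocol.ir_tis, t1_bounds=t1_bounds)
    maps: Dict[float, PerfusionMap] = {}
    qc: dict = {"rejected_pairs": {}, "pld_effective": {}}
    for pld in protocol.plds:
        stack = compute_delta_m(session, pld)
        stack = reject_misaligned_pairs(stack, z_threshold=z_threshold)
        dm_norm, valid = average_and_normalize(stack, session.m0, m0_floor=m0_floor)
        fmap = invert_single_pld(
            dm_norm, t1_map, protocol, constants, pld, valid_in=valid, mode=mode
        )
        maps[pld] = fmap
        qc["rejected_pairs"][pld] = np.nonzero(~stack.kept_mask)[0].tolist()
        qc["pld_effective"][pld] = fmap.pld_effective.tolist()
    return maps, t1_map, qc
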