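"""Single-compartment pCASL kinetic model and acquisition timing.

The perfusion-weighted difference signal ΔM produced by a pseudo-continuous
labeling bolus of duration τ, observed at a post-label delay PLD, is modeled
with the standard single-compartment solution for continuous labeling: the
labeled bolus arrives after an arterial transit time Δt, accumulates while
delivery lasts, and decays with the tissue longitudinal relaxation time
afterwards.  ΔM is linear in perfusion f, which is what makes single-PLD
quantification a closed-form division.

Perfusion f is carried in ml/100 g/min throughout the package; times are in
milliseconds.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KineticConstants", "buxton_delta_m", "whitepaper_perfusion"]

#: converts f in ml/100 g/min into the per-ms delivery rate used by the model
F_UNIT = 6000.0


@dataclass(frozen=True)
class KineticConstants:
    """Kinetic constants shared by simulation and quantification.

    None of these are measured per subject; they are protocol-level
    conventions.  Defaults are the consensus 3 T pCASL values.

    Parameters
    ----------
    t1_blood:
        Longitudinal relaxation time of arterial blood, ms.
    label_duration:
        Labeling bolus duration τ, ms.
    label_efficiency:
        Inversion efficiency α of the labeling train, in (0, 1].
    partition_coefficient:
        Blood-tissue water partition coefficient λ, ml/g.  Only the
        one-compartment shortcut formula uses it.
    att:
        Arterial transit time Δt, ms.  Default 0 (bolus arrives
        immediately); per-voxel transit maps may override it.
    """

    t1_blood: float = 1650.0
    label_duration: float = 1500.0
    label_efficiency: float = 0.85
    partition_coefficient: float = 0.9
    att: float = 0.0

    def __post_init__(self) -> None:
        if self.t1_blood <= 0 or self.label_duration <= 0:
            raise ValueError("t1_blood and label_duration must be positive")
        if not (0.0 < self.label_efficiency <= 1.0):
            raise ValueError("label_efficiency must be in (0, 1]")
        if self.partition_coefficient <= 0:
            raise ValueError("partition_coefficient must be positive")
        if self.att < 0:
            raise ValueError("att must be non-negative")


def buxton_delta_m(f, constants: KineticConstants, t1_tissue, pld, m0, att=None):
    """Closed-form ΔM for continuous labeling, single compartment.

    With t = pld + τ the time since labeling onset, Δt the transit time and
    T1app the (apparent) tissue T1::

        t <= Δt          : 0
        Δt < t <= Δt+τ   : S · (1 − exp(−(t−Δt)/T1app))
        t  > Δt+τ        : S · exp(−(t−Δt−τ)/T1app) · (1 − exp(−τ/T1app))

    where S = 2·α·m0·(f/6000)·T1app·exp(−Δt/t1_blood).

    All array arguments broadcast; returns a scalar for scalar input.

    Raises
    ------
    ValueError
        If any perfusion value is negative.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("perfusion f must be non-negative")
    t1app = np.asarray(t1_tissue, dtype=float)
    pld = np.asarray(pld, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    dt = np.asarray(constants.att if att is None else att, dtype=float)
    tau = constants.label_duration
    t = pld + tau

    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        scale = (
            2.0
            * constants.label_efficiency
            * m0
            * (f / F_UNIT)
            * t1app
            * np.exp(-dt / constants.t1_blood)
        )
        during = scale * (1.0 - np.exp(-(t - dt) / t1app))
        after = (
            scale
            * np.exp(-(t - dt - tau) / t1app)
            * (1.0 - np.exp(-tau / t1app))
        )
        out = np.where(t <= dt, 0.0, np.where(t <= dt + tau, during, after))
    out = np.where(np.isfinite(out), out, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def whitepaper_perfusion(dm_norm, pld, constants: KineticConstants):
    """One-compartment shortcut: perfusion from M0-normalized ΔM.

    The consensus single-formula quantification, which ignores the tissue T1
    map and attributes all decay to blood::

        f = 6000 · λ · ΔM/M0 · exp(PLD/T1b) / (2 · α · T1b · (1 − exp(−τ/T1b)))

    Provided as an alternative to the compartment-model inversion; both read
    the same normalized difference signal.
    """
    dm = np.asarray(dm_norm, dtype=float)
    pld = np.asarray(pld, dtype=float)
    c = constants
    denom = 2.0 * c.label_efficiency * c.t1_blood * (1.0 - np.exp(-c.label_duration / c.t1_blood))
    out = F_UNIT * c.partition_coefficient * dm * np.exp(pld / c.t1_blood) / denom
    if out.ndim == 0:
        return float(out)
    return out
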