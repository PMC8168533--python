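"""Acquisition protocol description and per-slice timing.

A multi-slice 2-D readout acquires slices sequentially after the labeling
bolus, so each slice sees its own effective post-label delay.  The protocol
object records the nominal PLDs, the pairs-per-PLD count, the slice grid and
the inversion-recovery series used for T1 mapping, plus the kinetic
constants shared between simulation and quantification.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .kinetics import KineticConstants

__all__ = ["ASLProtocol", "effective_pld", "default_protocol"]


@dataclass(frozen=True)
class ASLProtocol:
    """Multi-PLD pCASL acquisition protocol.

    Defaults mirror a breath-hold renal protocol: three nominal PLDs of
    500/1000/2000 ms and seven oblique-coronal slices.
    """

    plds: tuple = (500.0, 1000.0, 2000.0)
    n_pairs: int = 6
    n_slices: int = 7
    slice_acq_time: float = 45.0  # ms between consecutive slice readouts
    ir_tis: tuple = (100.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0)
    slice_order: Optional[tuple] = None  # acquisition order; None = ascending
    constants: KineticConstants = field(default_factory=KineticConstants)

    def __post_init__(self) -> None:
        if len(self.plds) == 0 or any(p <= 0 for p in self.plds):
            raise ValueError("plds must be non-empty and positive")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.slice_acq_time < 0:
            raise ValueError("slice_acq_time must be non-negative")
        if self.slice_order is not None:
            if sorted(self.slice_order) != list(range(self.n_slices)):
                raise ValueError(
                    "slice_order must be a permutation of range(n_slices)"
                )

    @property
    def label_duration(self) -> float:
        return self.constants.label_duration

    def acquisition_position(self, slice_index: int) -> int:
        """Position of a spatial slice in the acquisition sequence (0 = first)."""
        if not 0 <= slice_index < self.n_slices:
            raise IndexError(
                f"slice_index {slice_index} out of range [0, {self.n_slices})"
            )
        if self.slice_order is None:
            return slice_index
        return self.slice_order.index(slice_index)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["plds"] = list(self.plds)
        d["ir_tis"] = list(self.ir_tis)
        d["slice_order"] = None if self.slice_order is None else list(self.slice_order)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ASLProtocol":
        d = dict(d)
        const = d.pop("constants", {})
        if isinstance(const, dict):
            const = KineticConstants(**const)
        if d.get("slice_order") is not None:
            d["slice_order"] = tuple(d["slice_order"])
        return cls(
            plds=tuple(d["plds"]),
            n_pairs=int(d.get("n_pairs", 6)),
            n_slices=int(d.get("n_slices", 7)),
            slice_acq_time=float(d.get("slice_acq_time", 45.0)),
            ir_tis=tuple(d.get("ir_tis", (100.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0))),
            slice_order=d.get("slice_order"),
            constants=const,
        )


def effective_pld(protocol: ASLProtocol, pld_nominal: float, slice_index: int) -> float:
    """Effective post-label delay of a spatial slice, ms.

    The nominal PLD applies to the first slice acquired; every later slice
    adds one slice readout time per position in the acquisition sequence.
    With a configured slice ordering the delay follows acquisition order,
    not spatial order.
    """
    pos = protocol.acquisition_position(slice_index)
    return float(pld_nominal) + pos * protocol.slice_acq_time


def default_protocol(**overrides) -> ASLProtocol:
    """Convenience constructor for the default renal protocol."""
    return ASLProtocol(**overrides)
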