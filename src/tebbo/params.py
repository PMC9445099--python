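"""Growth-parameter container shared by the mean-field model and the spatial simulator.

Units are days and micrometres throughout the package.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass


class NoPlateauWarning(UserWarning):
    """Raised when kb >= kd0: branching outpaces proliferation and no finite
    positive plateau width exists (branches thin out indefinitely)."""


@dataclass(frozen=True)
class GrowthParameters:
    """Rate and geometry constants of the branching-growth model.

    Parameters
    ----------
    v0 : float
        Tip elongation (matrix-invasion) speed, µm/day. The calibrated
        extension-phase value is ~80 µm/day.
    kb : float
        Branching rate per elongating tip, 1/day (~0.55/day in the
        extension phase).
    kd0 : float
        Maximal cell-division rate, 1/day, attained in the thin-branch limit
        w -> 0 of the contact-inhibition feedback kd(w) = kd0 * (1 - w/w0).
    w0 : float
        Branch width at which proliferation is fully abrogated, µm.
    v_cell : float
        Volume per cell, µm^3; converts tissue volume to cell counts through
        the cylindrical closure Nc * v_cell = (pi/4) * w^2 * Ltot.
    l_init : float
        Length of a nascent daughter branch at a branching event, µm.
    w_min : float
        Breakage threshold, µm: a branch thinner than this ruptures and stops
        elongating and growing. Defaults to 0 (no rupture): unperturbed
        branches transiently pass through sub-cellular closure widths while
        nascent, and rupture is only observed when proliferation is blocked —
        drug-perturbation studies set a positive threshold explicitly.
    dim : int
        Spatial dimension of the simulator, 2 or 3.
    """

    v0: float = 80.0
    kb: float = 0.55
    kd0: float = 1.5
    w0: float = 60.0
    v_cell: float = 1000.0
    l_init: float = 5.0
    w_min: float = 0.0
    dim: int = 3

    def __post_init__(self) -> None:
        if self.v0 < 0:
            raise ValueError(f"v0 must be >= 0, got {self.v0}")
        if self.kb < 0:
            raise ValueError(f"kb must be >= 0, got {self.kb}")
        if self.kd0 < 0:
            raise ValueError(f"kd0 must be >= 0, got {self.kd0}")
        if self.w0 <= 0:
            raise ValueError(f"w0 must be > 0, got {self.w0}")
        if self.v_cell <= 0:
            raise ValueError(f"v_cell must be > 0, got {self.v_cell}")
        if self.l_init <= 0:
            raise ValueError(f"l_init must be > 0, got {self.l_init}")
        if not 0 <= self.w_min < self.w0:
            raise ValueError(
                f"w_min must satisfy 0 <= w_min < w0, got w_min={self.w_min}, w0={self.w0}"
            )
        if self.dim not in (2, 3):
            raise ValueError(f"dim must be 2 or 3, got {self.dim}")
        if self.kb >= self.kd0:
            warnings.warn(
                f"kb={self.kb} >= kd0={self.kd0}: branching consumes all "
                "proliferation, no positive plateau width exists",
                NoPlateauWarning,
                stacklevel=2,
            )

    def division_rate(self, width: float) -> float:
        """Width-feedback division rate kd(w) = kd0 * max(0, 1 - w/w0), 1/day.

        Clamped at zero: the feedback models contact inhibition of growth,
        not cell loss.
        """
        return self.kd0 * max(0.0, 1.0 - width / self.w0)

    def replace(self, **overrides: float) -> "GrowthParameters":
        """Return a copy with the given fields overridden.

        Unknown field names raise ``ValueError`` (perturbation schedules rely
        on this to reject typos).
        """
        valid = {f.name for f in dataclasses.fields(self)}
        unknown = set(overrides) - valid
        if unknown:
            raise ValueError(f"unknown growth parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GrowthParameters":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown growth parameter(s): {sorted(unknown)}")
        return cls(**d)


def width_from_closure(n_cells: float, total_length: float, v_cell: float) -> float:
    """Mean branch width under the cylindrical closure.

    Solves Nc * v_cell = (pi/4) * w^2 * Ltot for w.
    """
    import math

    if total_length <= 0:
        raise ValueError("total_length must be > 0")
    return math.sqrt(4.0 * n_cells * v_cell / (math.pi * total_length))
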