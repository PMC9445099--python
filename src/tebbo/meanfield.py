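"""Deterministic mean-field model of branching-organoid growth.

The model couples two ordinary differential equations:

    dLtot/dt = v0 * Nb(t),            Nb(t) = Nb(0) * exp(kb * t)
    dNc/dt   = kd0 * (1 - w/w0) * Nc  (clamped at 0 when w > w0)

where ``Ltot`` is the summed branch length of the organoid, ``Nc`` the total
cell number, ``Nb`` the tip (branch) count, and the mean branch width ``w``
follows from the cylindrical closure ``Nc * v_cell = (pi/4) * w^2 * Ltot``.

Tip elongation makes total length grow in proportion to the exponentially
increasing number of tips, while proliferation is down-regulated linearly as
branches widen (contact inhibition). The competition produces two growth
phases: an early phase where cell number grows at the maximal division rate
kd0 (thin branches), and a late phase where width settles at the fixed point
w* = w0 * (1 - kb/kd0) and cell number grows at the branching rate kb.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import GrowthParameters, width_from_closure

__all__ = [
    "MeanFieldState",
    "MeanFieldTrajectory",
    "MeanFieldModel",
    "IntegrationFailureError",
    "integrate_meanfield",
    "plateau_width",
    "growth_phase_rates",
]

_CLOSURE_RTOL = 1e-9


class IntegrationFailureError(RuntimeError):
    """Integration produced a non-finite state; carries the failure time."""

    def __init__(self, t_fail: float, message: str | None = None):
        self.t_fail = t_fail
        super().__init__(message or f"mean-field integration failed at t = {t_fail:g} d")


@dataclass(frozen=True)
class MeanFieldState:
    """Instantaneous mean-field state (t in days, lengths in µm)."""

    t: float
    Nc: float      # total cell number
    Ltot: float    # summed branch length, µm
    Nb: float      # branch (tip) count
    w: float       # mean branch width, µm

    def __post_init__(self):
        if self.Nc < 1 or self.Nb < 1 or self.Ltot <= 0 or self.w <= 0:
            raise ValueError(
                f"invalid mean-field state: Nc={self.Nc}, Nb={self.Nb}, "
                f"Ltot={self.Ltot}, w={self.w}"
            )

    def check_closure(self, v_cell: float, rtol: float = _CLOSURE_RTOL) -> None:
        lhs = self.Nc * v_cell
        rhs = math.pi / 4.0 * self.w**2 * self.Ltot
        if abs(lhs - rhs) > rtol * lhs:
            raise ValueError(
                f"state violates the cylindrical width closure at t={self.t}: "
                f"Nc*v_cell={lhs:g} vs (pi/4)w^2*Ltot={rhs:g}"
            )

    @classmethod
    def from_closure(
        cls, t: float, Nc: float, Ltot: float, Nb: float, v_cell: float
    ) -> "MeanFieldState":
        """Build a state with w computed from the cylindrical closure."""
        return cls(t=t, Nc=Nc, Ltot=Ltot, Nb=Nb, w=width_from_closure(Nc, Ltot, v_cell))


@dataclass(frozen=True)
class MeanFieldTrajectory:
    """Time-ordered mean-field states on a regular grid."""

    states: tuple[MeanFieldState, ...]
    params: GrowthParameters
    init: MeanFieldState

    @property
    def t(self) -> np.ndarray:
        return np.array([s.t for s in self.states])

    @property
    def Nc(self) -> np.ndarray:
        return np.array([s.Nc for s in self.states])

    @property
    def Ltot(self) -> np.ndarray:
        return np.array([s.Ltot for s in self.states])

    @property
    def Nb(self) -> np.ndarray:
        return np.array([s.Nb for s in self.states])

    @property
    def w(self) -> np.ndarray:
        return np.array([s.w for s in self.states])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t [day]": self.t,
                "Nc [cells]": self.Nc,
                "Ltot [um]": self.Ltot,
                "Nb [count]": self.Nb,
                "w [um]": self.w,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def interp(self, times: Sequence[float]) -> pd.DataFrame:
        """Linear interpolation of all columns onto arbitrary times."""
        times = np.asarray(times, dtype=float)
        t = self.t
        if times.min() < t[0] or times.max() > t[-1]:
            raise ValueError("requested times lie outside the trajectory span")
        return pd.DataFrame(
            {
                "t [day]": times,
                "Nc [cells]": np.interp(times, t, self.Nc),
                "Ltot [um]": np.interp(times, t, self.Ltot),
                "Nb [count]": np.interp(times, t, self.Nb),
                "w [um]": np.interp(times, t, self.w),
            }
        )


class MeanFieldModel:
    """Mechanistic mean-field growth model bound to a parameter set.

    Parameters
    ----------
    params : GrowthParameters
        Rate and geometry constants.
    init : MeanFieldState, optional
        Initial condition. Defaults to a single cell on a nascent branch:
        Nc(0) = 1, Nb(0) = 1, Ltot(0) = l_init, w(0) from the closure.

    Examples
    --------
    >>> model = MeanFieldModel(GrowthParameters())
    >>> traj = model.simulate(t_end=9.0)
    >>> traj.Nb[-1]  # tips grow as exp(kb * t)
    141.17496...
    """

    def __init__(self, params: GrowthParameters, init: MeanFieldState | None = None):
        self.params = params
        if init is None:
            init = MeanFieldState.from_closure(
                t=0.0, Nc=1.0, Ltot=params.l_init, Nb=1.0, v_cell=params.v_cell
            )
        init.check_closure(params.v_cell)
        self.init = init

    def plateau_width(self) -> float:
        return plateau_width(self.params)

    def simulate(self, t_end: float, dt: float = 0.01) -> MeanFieldTrajectory:
        """Integrate the ODE system and report states on {0, dt, ..., t_end}.

        Uses adaptive explicit Runge-Kutta (RK45) with dense output; the
        internal state is (Ltot, log Nc) so that exponential growth over tens
        of days stays well-conditioned. Width is reconstructed from the
        closure at every reported state, so the closure holds exactly.
        """
        p, init = self.params, self.init
        if t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {t_end}")
        if dt <= 0:
            raise ValueError(f"dt must be > 0, got {dt}")

        nb0 = init.Nb

        def rhs(t: float, y: np.ndarray) -> list[float]:
            ltot, log_nc = y
            if not (math.isfinite(ltot) and math.isfinite(log_nc)) or ltot <= 0:
                raise IntegrationFailureError(float(t))
            nc = math.exp(log_nc)
            w = width_from_closure(nc, ltot, p.v_cell)
            dltot = p.v0 * nb0 * math.exp(p.kb * t)
            dlog_nc = p.kd0 * max(0.0, 1.0 - w / p.w0)
            return [dltot, dlog_nc]

        # grid includes t_end even when t_end is not a multiple of dt
        n = int(round(t_end / dt))
        t_grid = np.arange(n + 1) * dt
        if t_grid[-1] < t_end - 1e-12:
            t_grid = np.append(t_grid, t_end)
        t_grid[-1] = min(t_grid[-1], t_end)
        t_grid = t_grid + init.t

        sol = solve_ivp(
            rhs,
            (init.t, init.t + t_end),
            [init.Ltot, math.log(init.Nc)],
            method="RK45",
            t_eval=t_grid,
            rtol=1e-10,
            atol=1e-12,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            bad = np.flatnonzero(~np.isfinite(sol.y).all(axis=0))
            t_fail = sol.t[bad[0]] if bad.size else sol.t[-1]
            raise IntegrationFailureError(float(t_fail))

        states = []
        for t_i, ltot_i, log_nc_i in zip(sol.t, sol.y[0], sol.y[1]):
            nc_i = math.exp(log_nc_i)
            states.append(
                MeanFieldState.from_closure(
                    t=float(t_i),
                    Nc=nc_i,
                    Ltot=float(ltot_i),
                    Nb=nb0 * math.exp(p.kb * (t_i - init.t)),
                    v_cell=p.v_cell,
                )
            )
        return MeanFieldTrajectory(states=tuple(states), params=p, init=init)


def integrate_meanfield(
    params: GrowthParameters,
    init: MeanFieldState | None = None,
    t_end: float = 9.0,
    dt: float = 0.01,
) -> MeanFieldTrajectory:
    """Integrate the mean-field growth ODEs (functional wrapper around
    :class:`MeanFieldModel`)."""
    return MeanFieldModel(params, init).simulate(t_end=t_end, dt=dt)


def plateau_width(params: GrowthParameters) -> float:
    """Stationary mean branch width w* = w0 * (1 - kb/kd0).

    At the fixed point of the feedback, proliferation exactly balances the
    dilution of cells into new length created by the exponentially branching
    tips. Returns 0 when kb >= kd0 (branching consumes all proliferation; a
    ``NoPlateauWarning`` was already recorded at parameter construction).
    """
    if params.kd0 == 0:
        raise ValueError("plateau width is undefined for kd0 = 0")
    return params.w0 * max(0.0, 1.0 - params.kb / params.kd0)


def growth_phase_rates(
    traj: MeanFieldTrajectory,
    early_window: tuple[float, float],
    late_window: tuple[float, float],
) -> tuple[float, float]:
    """Exponential cell-number growth rates in two time windows, 1/day.

    Each rate is the least-squares slope of log Nc against t on its window.
    In the thin-branch limit the early rate approaches kd0; once the width
    has reached its plateau the late rate approaches kb.
    """
    t, log_nc = traj.t, np.log(traj.Nc)

    def slope(window: tuple[float, float]) -> float:
        lo, hi = window
        if lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise ValueError(f"window {window} lies outside the trajectory span")
        mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        if mask.sum() < 3:
            raise ValueError(f"window {window} contains fewer than 3 grid points")
        return float(np.polyfit(t[mask], log_nc[mask], 1)[0])

    return slope(early_window), slope(late_window)
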