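"""Stochastic spatial version of the branching-growth model.

Each organoid is a rooted tree of branches. Per time step (fixed-step
tau-leaping, default dt = 0.01 day):

* every terminal, unbroken branch's tip advances ``v0 * dt`` along its
  heading; the heading diffuses with angular variance ``dtheta * dt``;
* every unbroken branch widens by local proliferation under the
  contact-inhibition feedback ``kd(w) = kd0 * max(0, 1 - w/w0)``
  (``d ln w^2 = kd(w)``), while every elongating tip is additionally thinned
  by the dilution of cells into new length — split between a local share
  ``v0/L_i`` and the collective supply-network share (cells flow from the
  organoid core toward the tips); non-terminal branches are not thinned by
  elongation and widen toward ``w0``. Volumes follow the cylindrical closure
  ``V = (pi/4) * w^2 * L`` identically;
* terminal branches branch as a Poisson process at rate ``kb``: the mother
  becomes non-terminal and two daughters are seeded at ``±theta_b`` around
  the mother heading, with length ``l_init`` and the mother's tip width;
  When branching is coupled to division, branching events fire only at
  division events in the tip compartment (the leading 6 cells), thinned so
  that the long-run branching rate stays exactly ``kb``; this reproduces the
  observed dominance of division-preceded branching events;
* a branch thinner than ``w_min`` ruptures ("broken") and stops elongating
  and growing.

Perturbation schedules override growth parameters mid-run; the presets mirror
drug treatments: batimastat (matrix-metalloproteinase inhibition) sets
``v0 -> 0`` and scales ``kd0`` to its measured 23% residual, aphidicolin
(DNA-polymerase inhibition) sets ``kd0 -> 0``.

The per-step state lives in flat numpy arrays; :class:`OrganoidTree` /
:class:`Branch` objects are materialised only at snapshot times.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .params import GrowthParameters

__all__ = [
    "Branch",
    "OrganoidTree",
    "SimulationConfig",
    "PerturbationSchedule",
    "BranchingEvent",
    "SimulationRun",
    "SimulationFailureError",
    "simulate_organoid",
    "run_ensemble",
    "apply_perturbation",
    "perturbation_preset",
    "branch_count_statistics",
]

_VOLUME_RTOL = 1e-6


class SimulationFailureError(RuntimeError):
    """Non-finite coordinates appeared during stepping; carries the step index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"spatial simulation failed at step {step}: non-finite state")


@dataclass(frozen=True)
class Branch:
    """One branch of an organoid tree.

    ``nodes`` is the centerline polyline in µm (``(k, dim)`` array); ``length``
    is the arc length accumulated by tip elongation, which equals the polyline
    arc length when full node recording is on. ``width`` and ``volume`` obey
    the cylindrical closure ``volume = (pi/4) * width**2 * length``.
    """

    id: int
    parent_id: int | None
    nodes: np.ndarray
    length: float
    width: float
    volume: float
    birth_time: float
    terminal: bool
    broken: bool

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"branch {self.id}: length must be > 0")
        if self.width <= 0 and not self.broken:
            raise ValueError(f"branch {self.id}: width must be > 0 unless broken")
        expected = math.pi / 4.0 * self.width**2 * self.length
        if self.volume > 0 and abs(self.volume - expected) > _VOLUME_RTOL * self.volume:
            raise ValueError(
                f"branch {self.id}: volume {self.volume:g} violates the "
                f"cylindrical closure (expected {expected:g})"
            )

    @property
    def polyline_length(self) -> float:
        return float(np.linalg.norm(np.diff(self.nodes, axis=0), axis=1).sum())

    @property
    def tip(self) -> np.ndarray:
        return self.nodes[-1]


@dataclass(frozen=True)
class OrganoidTree:
    """A rooted tree of branches at one time point."""

    branches: dict[int, Branch]
    time: float
    rng_seed: int

    def __post_init__(self):
        roots = [b for b in self.branches.values() if b.parent_id is None]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        for b in self.branches.values():
            if b.parent_id is not None and b.parent_id not in self.branches:
                raise ValueError(f"branch {b.id} has dangling parent {b.parent_id}")

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def n_terminal(self) -> int:
        return sum(1 for b in self.branches.values() if b.terminal)

    @property
    def n_nonterminal(self) -> int:
        return sum(1 for b in self.branches.values() if not b.terminal)

    @property
    def total_length(self) -> float:
        return sum(b.length for b in self.branches.values())

    @property
    def total_volume(self) -> float:
        return sum(b.volume for b in self.branches.values())

    def children_of(self, branch_id: int) -> list[int]:
        return [b.id for b in self.branches.values() if b.parent_id == branch_id]


@dataclass(frozen=True)
class PerturbationSchedule:
    """Timed partial overrides of the growth parameters.

    ``events`` is a list of ``(time_in_days, {field: value, ...})``. Override
    keys are validated against :class:`GrowthParameters` at construction.
    """

    events: tuple = ()

    def __post_init__(self):
        events = tuple((float(t), dict(ov)) for t, ov in self.events)
        times = [t for t, _ in events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("perturbation event times must be non-decreasing")
        if any(t < 0 for t in times):
            raise ValueError("perturbation event times must be >= 0")
        valid = {f.name for f in dataclasses.fields(GrowthParameters)}
        for t, ov in events:
            unknown = set(ov) - valid
            if unknown:
                raise ValueError(
                    f"perturbation at t={t} overrides unknown parameter(s): {sorted(unknown)}"
                )
        object.__setattr__(self, "events", events)


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one spatial simulation.

    ``dtheta`` is the angular diffusion coefficient of the tip heading
    (rad^2/day) and ``theta_b`` the branching half-angle (daughters leave at
    ``±theta_b`` around the mother heading). ``dilution_locality`` (gamma in
    [0, 1]) sets how the elongation dilution of a terminal branch is split
    between its own length (``gamma * v0/L_i`` — nascent branches thin
    fastest) and the organoid's collective supply network
    (``(1-gamma) * v0 * sum(w^2)/sum(w^2 L)`` over tips — cells flow from
    the core toward all tips). ``record_nodes`` keeps the full centerline
    polylines; switching it off stores only base and tip per branch, which
    large ensembles use for speed. ``snapshot_times`` defaults to daily;
    ``tip_track_interval`` additionally samples every terminal tip's
    cumulative path length on that interval (for tip-speed regressions).
    """

    params: GrowthParameters = field(default_factory=GrowthParameters)
    dtheta: float = 0.5
    theta_b: float = 0.6
    dt: float = 0.01
    duration: float = 9.0
    seed: int = 0
    couple_branching_to_division: bool = True
    self_avoidance_distance: float | None = None
    dilution_locality: float = 0.3
    record_nodes: bool = True
    snapshot_times: tuple[float, ...] | None = None
    tip_track_interval: float | None = None
    schedule: PerturbationSchedule | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not 0 < self.theta_b < math.pi / 2:
            raise ValueError(f"theta_b must lie in (0, pi/2), got {self.theta_b}")
        if self.dtheta < 0:
            raise ValueError(f"dtheta must be >= 0, got {self.dtheta}")
        if self.schedule is not None:
            for t, _ in self.schedule.events:
                if t > self.duration:
                    raise ValueError(
                        f"perturbation at t={t} lies beyond duration {self.duration}"
                    )

    def resolved_snapshot_times(self) -> np.ndarray:
        if self.snapshot_times is not None:
            times = np.asarray(self.snapshot_times, dtype=float)
            if times.size and (times.min() < 0 or times.max() > self.duration + 1e-9):
                raise ValueError("snapshot times must lie within [0, duration]")
            return np.sort(times)
        times = np.arange(0.0, self.duration + 1e-9, 1.0)
        if times[-1] < self.duration - 1e-9:
            times = np.append(times, self.duration)
        return times


@dataclass(frozen=True)
class BranchingEvent:
    """One branching event: mother branch, when it fired, and the time of the
    last division in the mother's tip compartment before (or at) the event."""

    time: float
    mother_id: int
    last_division_time: float | None

    @property
    def preceded_by_division(self) -> bool:
        return self.last_division_time is not None

    def division_within(self, window: float) -> bool:
        return (
            self.last_division_time is not None
            and self.time - self.last_division_time <= window + 1e-12
        )


class SimulationRun(Sequence):
    """Time-ordered sequence of :class:`OrganoidTree` snapshots plus the
    branching-event log and optional tip tracks."""

    def __init__(
        self,
        trees: list[OrganoidTree],
        events: list[BranchingEvent],
        config: SimulationConfig,
        tip_tracks: pd.DataFrame | None = None,
    ):
        self.trees = trees
        self.events = events
        self.config = config
        self.tip_tracks = tip_tracks

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i) -> OrganoidTree:
        return self.trees[i]

    def __iter__(self) -> Iterator[OrganoidTree]:
        return iter(self.trees)

    @property
    def final(self) -> OrganoidTree:
        return self.trees[-1]

    def index_table(self) -> pd.DataFrame:
        """Per-snapshot summary: time, branch counts, total length and volume."""
        return pd.DataFrame(
            {
                "time [day]": [t.time for t in self.trees],
                "n_branches [count]": [t.n_branches for t in self.trees],
                "n_terminal [count]": [t.n_terminal for t in self.trees],
                "total_length [um]": [t.total_length for t in self.trees],
                "total_volume [um3]": [t.total_volume for t in self.trees],
            }
        )


class _State:
    """Flat-array simulation state; branch i occupies index i."""

    def __init__(self, cap: int, dim: int):
        self.n = 0
        self.dim = dim
        self.parent = np.full(cap, -1, dtype=np.int64)
        self.birth = np.zeros(cap)
        self.length = np.zeros(cap)
        self.volume = np.zeros(cap)
        self.width = np.zeros(cap)
        self.terminal = np.zeros(cap, dtype=bool)
        self.broken = np.zeros(cap, dtype=bool)
        self.arrested = np.zeros(cap, dtype=bool)
        self.last_div = np.full(cap, np.nan)
        self.base = np.zeros((cap, dim))
        self.tip = np.zeros((cap, dim))
        self.head = np.zeros((cap, dim))

    def grow(self):
        cap = len(self.birth) * 2
        for name in ("parent", "birth", "length", "volume", "width",
                     "terminal", "broken", "arrested", "last_div"):
            arr = getattr(self, name)
            new = np.empty(cap, dtype=arr.dtype)
            if name == "parent":
                new[:] = -1
            elif name == "last_div":
                new[:] = np.nan
            else:
                new[:] = 0
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)
        for name in ("base", "tip", "head"):
            arr = getattr(self, name)
            new = np.zeros((cap, self.dim))
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)


def _perp_unit(head: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vectors perpendicular to each row of ``head``."""
    n, dim = head.shape
    if dim == 2:
        return np.column_stack([-head[:, 1], head[:, 0]])
    v = rng.standard_normal((n, 3))
    v -= (v * head).sum(axis=1, keepdims=True) * head
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # degenerate draws (v parallel to head) are vanishingly rare; regularise
    norm[norm < 1e-12] = 1.0
    return v / norm


def simulate_organoid(
    config: SimulationConfig,
    schedule: PerturbationSchedule | None = None,
) -> SimulationRun:
    """Run one stochastic spatial simulation.

    The run is fully determined by ``config`` (including its seed): identical
    configurations give bit-identical trees. ``schedule`` overrides the
    config's own schedule when given.
    """
    if schedule is None:
        schedule = config.schedule or PerturbationSchedule()
    else:
        # re-validate against duration
        config = dataclasses.replace(config, schedule=schedule)
        schedule = config.schedule

    p = config.params
    dim = p.dim
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    rng = np.random.default_rng(config.seed)

    st = _State(cap=64, dim=dim)
    st.n = 1
    # root: nascent branch from the origin in a random direction
    head0 = rng.standard_normal(dim)
    head0 /= np.linalg.norm(head0)
    st.head[0] = head0
    st.base[0] = 0.0
    st.tip[0] = head0 * p.l_init
    st.length[0] = p.l_init
    st.volume[0] = p.v_cell  # a single cell's worth of tissue
    st.width[0] = math.sqrt(4.0 * st.volume[0] / (math.pi * st.length[0]))
    st.terminal[0] = True

    # per-step node log: (branch indices, positions) — replayed into polylines
    node_log: list[tuple[np.ndarray, np.ndarray]] = []
    if config.record_nodes:
        node_log.append((np.array([0]), st.base[0:1].copy()))
        node_log.append((np.array([0]), st.tip[0:1].copy()))

    events: list[BranchingEvent] = []
    track_rows: list[tuple[float, np.ndarray, np.ndarray]] = []

    snap_times = config.resolved_snapshot_times()
    snap_steps = set(np.round(snap_times / dt).astype(int).tolist())
    if config.tip_track_interval is not None:
        k = max(1, int(round(config.tip_track_interval / dt)))
        track_steps = set(range(0, n_steps + 1, k))
    else:
        track_steps = set()

    sched_events = list(schedule.events)
    next_event = 0

    trees: list[OrganoidTree] = []

    def take_snapshot(t_now: float):
        trees.append(_build_tree(st, node_log, t_now, config))

    def take_track(t_now: float):
        live = np.flatnonzero(st.terminal[: st.n] & ~st.broken[: st.n] & ~st.arrested[: st.n])
        track_rows.append((t_now, live.copy(), st.length[live].copy()))

    if 0 in snap_steps:
        take_snapshot(0.0)
    if 0 in track_steps:
        take_track(0.0)

    avoid_tree = None
    avoid_pts_n = 0

    for step in range(1, n_steps + 1):
        t = step * dt
        # parameter overrides that have come due
        while next_event < len(sched_events) and sched_events[next_event][0] <= t - dt + 1e-12:
            p = p.replace(**sched_events[next_event][1])
            next_event += 1

        n = st.n
        active = st.terminal[:n] & ~st.broken[:n] & ~st.arrested[:n]
        idx = np.flatnonzero(active)

        # -- tip heading diffusion + elongation ---------------------------
        if idx.size and p.v0 > 0:
            head = st.head[idx]
            phi = rng.normal(0.0, math.sqrt(config.dtheta * dt), idx.size)
            u = _perp_unit(head, rng)
            head = np.cos(phi)[:, None] * head + np.sin(phi)[:, None] * u
            head /= np.linalg.norm(head, axis=1, keepdims=True)
            st.head[idx] = head
            st.tip[idx] += p.v0 * dt * head
            st.length[idx] += p.v0 * dt
            if config.record_nodes:
                node_log.append((idx.copy(), st.tip[idx].copy()))
        elif idx.size:
            # headings still diffuse even when invasion is abolished
            phi = rng.normal(0.0, math.sqrt(config.dtheta * dt), idx.size)
            u = _perp_unit(st.head[idx], rng)
            head = np.cos(phi)[:, None] * st.head[idx] + np.sin(phi)[:, None] * u
            st.head[idx] = head / np.linalg.norm(head, axis=1, keepdims=True)

        # -- self-avoidance: arrest tips near foreign branches ------------
        if config.self_avoidance_distance is not None and config.record_nodes and idx.size:
            from scipy.spatial import cKDTree

            total_pts = sum(len(ix) for ix, _ in node_log)
            if avoid_tree is None or total_pts > 1.25 * avoid_pts_n:
                pts = np.concatenate([pos for _, pos in node_log])
                owners = np.concatenate([ix for ix, _ in node_log])
                avoid_tree = (cKDTree(pts), owners)
                avoid_pts_n = total_pts
            tree, owners = avoid_tree
            d = config.self_avoidance_distance
            for i in idx:
                hits = tree.query_ball_point(st.tip[i], d)
                if any(owners[h] != i and owners[h] != st.parent[i] for h in hits):
                    st.arrested[i] = True

        # -- width dynamics: proliferation vs elongation dilution ---------
        # every unbroken branch widens by local proliferation,
        # d ln w^2 = kd(w); an elongating tip additionally pays the dilution
        # of spreading cells into new length, split between a local share
        # v0/L_i (its own fresh segment) and the collective supply-network
        # share v0 * sum(w_t^2) / sum(w_t^2 L_t) (cells flow from the
        # network toward all tips). Non-terminal branches are not thinned by
        # elongation and widen toward w0. Volumes follow the cylindrical
        # closure V = (pi/4) w^2 L identically.
        kd = p.kd0 * np.maximum(0.0, 1.0 - st.width[:n] / p.w0)
        dlnw2 = kd.copy()
        if idx.size and p.v0 > 0:
            w2_all = st.width[:n] ** 2
            # collective share: new tip volume relative to the whole supply
            # network (all unbroken branches), the spatial counterpart of the
            # mean-field dilution v0 * Nb / Ltot
            live = ~st.broken[:n]
            w2l = w2_all[live] * st.length[:n][live]
            pool = p.v0 * w2_all[idx].sum() / w2l.sum()
            # the collective share is carried by proliferative (tipward) cell
            # flux; when network proliferation cannot cover the tips' demand,
            # the uncovered fraction is borne locally — a branch then
            # stretches its own tissue, so nascent (short) branches thin
            # fastest (their fragility under proliferation block)
            prolif = (kd[live] * w2l).sum()
            demand = p.v0 * w2_all[idx].sum()
            cover = min(1.0, prolif / demand) if demand > 0 else 1.0
            gamma = 1.0 - (1.0 - config.dilution_locality) * cover
            dlnw2[idx] -= gamma * p.v0 / st.length[idx] + (1.0 - gamma) * pool
        dlnw2[st.broken[:n]] = 0.0
        st.width[:n] *= np.exp(0.5 * dlnw2 * dt)
        st.volume[:n] = math.pi / 4.0 * st.width[:n] ** 2 * st.length[:n]

        # -- divisions in the tip compartment (leading 6 cells) -----------
        if idx.size:
            p_div = 1.0 - np.exp(-6.0 * kd[idx] * dt)
            divided = rng.random(idx.size) < p_div
            st.last_div[idx[divided]] = t

        # -- branching ----------------------------------------------------
        # per-step probability e^{kb dt} - 1 makes the per-step tip
        # multiplication factor exactly e^{kb dt} (compensates the
        # one-birth-per-step truncation of tau-leaping)
        if idx.size and p.kb > 0:
            p_b = min(1.0, math.exp(p.kb * dt) - 1.0)
            if config.couple_branching_to_division:
                # thin the tip-compartment division process: branchings fire
                # only at divisions, with conditional probability p_b / p_div,
                # so every branching is preceded by a division while the
                # long-run branching rate stays kb (exact whenever the
                # division rate 6 kd exceeds kb; with kd = 0 branching stops,
                # as observed under proliferation block)
                with np.errstate(divide="ignore", invalid="ignore"):
                    cond = np.where(p_div > 0, np.minimum(1.0, p_b / p_div), 0.0)
                fire = idx[divided & (rng.random(idx.size) < cond)]
            else:
                fire = idx[rng.random(idx.size) < p_b]
            for i in fire:
                _branch(st, int(i), t, p, config, rng, events, node_log)
        # -- breakage -----------------------------------------------------
        newly_broken = (st.width[: st.n] < p.w_min) & ~st.broken[: st.n]
        st.broken[: st.n] |= newly_broken

        if not np.all(np.isfinite(st.tip[: st.n])):
            raise SimulationFailureError(step)

        if step in track_steps:
            take_track(t)
        if step in snap_steps:
            take_snapshot(t)

    tracks = None
    if config.tip_track_interval is not None:
        recs = [
            (t, int(b), float(l))
            for t, bs, ls in track_rows
            for b, l in zip(bs, ls)
        ]
        tracks = pd.DataFrame(recs, columns=["time [day]", "branch_id", "path_length [um]"])

    return SimulationRun(trees=trees, events=events, config=config, tip_tracks=tracks)


def _branch(
    st: _State,
    i: int,
    t: float,
    p: GrowthParameters,
    config: SimulationConfig,
    rng: np.random.Generator,
    events: list[BranchingEvent],
    node_log: list,
) -> None:
    """Turn terminal branch ``i`` into a mother with two daughters."""
    while st.n + 2 > len(st.birth):
        st.grow()
    last_div = st.last_div[i]
    events.append(
        BranchingEvent(
            time=t,
            mother_id=i,
            last_division_time=None if math.isnan(last_div) else float(last_div),
        )
    )
    st.terminal[i] = False

    head = st.head[i]
    u = _perp_unit(head[None, :], rng)[0]
    c, s = math.cos(config.theta_b), math.sin(config.theta_b)
    w_tip = st.width[i]
    for sign in (+1.0, -1.0):
        j = st.n
        st.n += 1
        d_head = c * head + sign * s * u
        d_head /= np.linalg.norm(d_head)
        st.parent[j] = i
        st.birth[j] = t
        st.length[j] = p.l_init
        # daughters bud off at the mother's tip width
        st.width[j] = w_tip
        st.volume[j] = math.pi / 4.0 * w_tip**2 * p.l_init
        st.terminal[j] = True
        st.base[j] = st.tip[i]
        st.tip[j] = st.tip[i] + p.l_init * d_head
        st.head[j] = d_head
        st.last_div[j] = st.last_div[i]
        if config.record_nodes:
            node_log.append((np.array([j]), st.base[j : j + 1].copy()))
            node_log.append((np.array([j]), st.tip[j : j + 1].copy()))


def _build_tree(
    st: _State, node_log: list, t_now: float, config: SimulationConfig
) -> OrganoidTree:
    n = st.n
    if config.record_nodes:
        nodes: list[list[np.ndarray]] = [[] for _ in range(n)]
        for ix, pos in node_log:
            for k, i in enumerate(ix):
                if i < n:
                    nodes[i].append(pos[k])
        polylines = [np.array(ns) for ns in nodes]
    else:
        polylines = [np.array([st.base[i], st.tip[i]]) for i in range(n)]

    branches = {}
    for i in range(n):
        branches[i] = Branch(
            id=i,
            parent_id=None if st.parent[i] < 0 else int(st.parent[i]),
            nodes=polylines[i],
            length=float(st.length[i]),
            width=float(st.width[i]),
            volume=float(st.volume[i]),
            birth_time=float(st.birth[i]),
            terminal=bool(st.terminal[i]),
            broken=bool(st.broken[i]),
        )
    return OrganoidTree(branches=branches, time=t_now, rng_seed=config.seed)


def run_ensemble(
    config: SimulationConfig, n_runs: int, base_seed: int | None = None
) -> list[SimulationRun]:
    """Run ``n_runs`` independent simulations.

    Run ``i`` uses seed ``base_seed + i`` (counter sub-seeding), so any subset
    of the ensemble can be regenerated independently.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if base_seed is None:
        base_seed = config.seed
    return [
        simulate_organoid(dataclasses.replace(config, seed=base_seed + i))
        for i in range(n_runs)
    ]


_PRESETS = {
    # batimastat abolishes matrix invasion; volumetric growth retains 23%
    # of its control value (a −77% perturbation)
    "batimastat": lambda p: {"v0": 0.0, "kd0": p.kd0 * 0.23},
    # aphidicolin blocks DNA replication: proliferation stops outright
    "aphidicolin": lambda p: {"kd0": 0.0},
}


def perturbation_preset(
    name: str, t_drug: float, params: GrowthParameters
) -> PerturbationSchedule:
    """Schedule for a named drug preset applied at ``t_drug`` (days)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}")
    return PerturbationSchedule(events=((t_drug, _PRESETS[name](params)),))


def apply_perturbation(
    config: SimulationConfig, schedule: PerturbationSchedule
) -> SimulationConfig:
    """Attach a (validated) perturbation schedule to a simulation config."""
    return dataclasses.replace(config, schedule=schedule)


def branch_count_statistics(
    ensemble: Sequence[SimulationRun | Sequence[OrganoidTree]],
    times: Sequence[float] | None = None,
    which: str = "tips",
) -> pd.DataFrame:
    """Ensemble mean and standard deviation of branch counts over time.

    ``which="tips"`` counts elongating (terminal) branches — the individuals
    of the underlying pure-birth (Yule) process, with mean ``exp(kb t)`` and
    variance ``m (m - 1)``; ``which="all"`` counts every branch segment
    (``2 * tips - 1`` on a binary tree), the convention used when counting
    branches in images.
    """
    if len(ensemble) == 0:
        raise ValueError("ensemble must contain at least one run")
    if which not in ("tips", "all"):
        raise ValueError("which must be 'tips' or 'all'")

    def counts_for(run) -> dict[float, int]:
        out = {}
        for tree in run:
            c = tree.n_terminal if which == "tips" else tree.n_branches
            out[round(tree.time, 9)] = c
        return out

    per_run = [counts_for(run) for run in ensemble]
    if times is None:
        common = set(per_run[0])
        for c in per_run[1:]:
            common &= set(c)
        times = sorted(common)
    else:
        times = [round(float(t), 9) for t in times]
    rows = []
    for t in times:
        vals = np.array([c[t] for c in per_run], dtype=float)
        rows.append((t, vals.mean(), vals.std(ddof=1) if len(vals) > 1 else 0.0))
    return pd.DataFrame(rows, columns=["time [day]", "mean_nb [count]", "sd_nb [count]"])
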