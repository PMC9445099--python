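"""Synthetic observation tables with the statistical structure the fits assume.

The generator runs the spatial simulator per organoid (organoid ``i`` uses
seed ``master_seed + i``), measures the trees with the morphometric
conventions, and corrupts the measurements with a configurable noise model:
multiplicative lognormal noise on widths and growth rates, lognormal noise on
cell counts, additive Gaussian jitter on tip-track samples. Lognormal factors
are mean-one (``mu = -sigma^2/2``), so noised measurements are unbiased.

Emulated tables:

* (width, normalized volumetric growth rate) pairs per branch, sampled on a
  short live-imaging window (default day 7–9 at 0.1-day intervals);
* branch counts per organoid at daily intervals (terminal, non-terminal, all);
* cell counts per organoid at daily intervals (total volume / cell volume);
* cumulative tip path-length tracks.

Every dataset embeds the generating parameters and the noise model, so it is
self-documenting.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitting, morphometrics
from .params import GrowthParameters
from .spatial import SimulationConfig, simulate_organoid

__all__ = [
    "ObservationNoiseModel",
    "SyntheticDataset",
    "generate_morphometric_dataset",
    "generate_feedback_pairs",
    "generate_worked_fixture",
]


@dataclass(frozen=True)
class ObservationNoiseModel:
    """Measurement-noise magnitudes (coefficients of variation) and the
    master seed of the dataset. The seed has no default: a dataset without an
    explicit seed is not reproducible, so generation refuses to run."""

    width_cv: float = 0.1
    growth_rate_cv: float = 0.1
    count_cv: float = 0.1
    track_jitter_sd: float = 2.0   # µm
    seed: int | None = None

    def __post_init__(self):
        for name in ("width_cv", "growth_rate_cv", "count_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.track_jitter_sd < 0:
            raise ValueError("track_jitter_sd must be >= 0")

    def require_seed(self) -> int:
        if self.seed is None:
            raise ValueError(
                "ObservationNoiseModel.seed is None: synthetic-data generation "
                "requires an explicit seed"
            )
        return int(self.seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


@dataclass
class SyntheticDataset:
    """Observation tables plus the generating truth (self-documenting)."""

    pairs: pd.DataFrame          # width / growth-rate pairs (non-terminal)
    branch_counts: pd.DataFrame  # per organoid per day
    cell_counts: pd.DataFrame    # per organoid per day
    widths: pd.DataFrame         # per-branch widths by class over time
    tip_tracks: pd.DataFrame     # cumulative tip path lengths
    truth: GrowthParameters
    noise: ObservationNoiseModel

    def cell_count_summary(self) -> pd.DataFrame:
        """Ensemble mean ± sd of cell counts per time point."""
        g = self.cell_counts.groupby("time [day]")["n_cells [count]"]
        out = g.agg(["mean", "std"]).reset_index()
        out.columns = ["time [day]", "mean_nc [cells]", "sd_nc [cells]"]
        out["sd_nc [cells]"] = out["sd_nc [cells]"].fillna(0.0)
        return out

    def fit(self, n_boot: int = 0, seed: int | None = None) -> dict:
        """Run the full fitting pipeline on this dataset's tables."""
        return fitting.fit_report(
            self.pairs, self.branch_counts, self.tip_tracks, n_boot=n_boot, seed=seed
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.pairs.to_csv(directory / "pairs.csv", index=False)
        self.branch_counts.to_csv(directory / "branch_counts.csv", index=False)
        self.cell_counts.to_csv(directory / "cell_counts.csv", index=False)
        self.widths.to_csv(directory / "widths.csv", index=False)
        self.tip_tracks.to_csv(directory / "tip_tracks.csv", index=False)
        from . import __version__

        sidecar = {
            "truth": self.truth.to_dict(),
            "noise": dataclasses.asdict(self.noise),
            "package_version": __version__,
        }
        (directory / "truth.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path) -> "SyntheticDataset":
        directory = Path(directory)
        sidecar = json.loads((directory / "truth.json").read_text())
        return cls(
            pairs=pd.read_csv(directory / "pairs.csv"),
            branch_counts=pd.read_csv(directory / "branch_counts.csv"),
            cell_counts=pd.read_csv(directory / "cell_counts.csv"),
            widths=pd.read_csv(directory / "widths.csv"),
            tip_tracks=pd.read_csv(directory / "tip_tracks.csv"),
            truth=GrowthParameters.from_dict(sidecar["truth"]),
            noise=ObservationNoiseModel(**sidecar["noise"]),
        )


def generate_morphometric_dataset(
    truth: GrowthParameters,
    noise: ObservationNoiseModel,
    n_organoids: int,
    t_grid: np.ndarray | None = None,
    pair_window: tuple[float, float] = (7.0, 9.0),
    pair_interval: float = 0.1,
    n_pairs: int | None = None,
    couple_branching_to_division: bool = True,
) -> SyntheticDataset:
    """Simulate, measure and noise a full observation dataset.

    ``t_grid`` (default days 0–9, daily) sets the branch- and cell-count
    reporting times and the simulation duration; ``pair_window`` and
    ``pair_interval`` define the live-imaging window over which the
    (width, growth-rate) pairs and tip tracks are sampled. ``n_pairs``
    optionally subsamples the pair table to a fixed size, emulating a
    hand-measured scatter of that many points.
    """
    if n_organoids < 1:
        raise ValueError("n_organoids must be >= 1")
    master_seed = noise.require_seed()
    if t_grid is None:
        t_grid = np.arange(0.0, 9.0 + 1e-9, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    duration = float(t_grid.max())
    if t_grid.min() < 0 or duration <= 0:
        raise ValueError("t_grid must contain non-negative times with a positive span")
    lo, hi = pair_window
    if not (0 <= lo < hi <= duration):
        raise ValueError(f"pair_window {pair_window} must lie within [0, {duration}]")

    pair_times = np.round(np.arange(lo, hi + 1e-9, pair_interval), 9)
    snapshot_times = np.unique(np.concatenate([t_grid, pair_times]))

    pair_rows, count_rows, cell_rows, width_rows, track_frames = [], [], [], [], []
    for i in range(n_organoids):
        org = f"org{i:03d}"
        config = SimulationConfig(
            params=truth,
            duration=duration,
            seed=master_seed + i,
            couple_branching_to_division=couple_branching_to_division,
            record_nodes=False,
            snapshot_times=tuple(snapshot_times),
            tip_track_interval=pair_interval,
        )
        run = simulate_organoid(config)
        by_time = {round(t.time, 9): t for t in run.trees}

        # width / growth-rate pairs on consecutive live-imaging frames.
        # Only non-terminal branches are measured: they are fixed segments
        # between branching points, so the volume change of the segment is
        # purely proliferative. A terminal branch extends during the
        # interval, which conflates elongation with growth.
        for t1, t2 in zip(pair_times[:-1], pair_times[1:]):
            tree1, tree2 = by_time[round(t1, 9)], by_time[round(t2, 9)]
            for bid, b1 in tree1.branches.items():
                b2 = tree2.branches.get(bid)
                if b2 is None or b1.terminal or b1.broken or b2.broken:
                    continue
                if b2.terminal:  # cannot happen (branches never revert)
                    continue
                width = morphometrics.body_width(tree1, bid).value
                rate = morphometrics.normalized_volumetric_growth(
                    b1.volume, b2.volume, t2 - t1
                )
                pair_rows.append((org, float(t1), bid, width, rate, False))

        # branch and cell counts plus per-branch widths on the reporting grid
        for t in t_grid:
            tree = by_time[round(float(t), 9)]
            n_term, n_nonterm = morphometrics.count_branches(tree)
            count_rows.append((org, float(t), n_term + n_nonterm, n_term, n_nonterm))
            cell_rows.append((org, float(t), tree.total_volume / truth.v_cell))
            for b in tree.branches.values():
                if b.broken:
                    continue
                if b.terminal:
                    w = morphometrics.terminal_branch_width(tree, b.id)
                else:
                    w = morphometrics.body_width(tree, b.id).value
                width_rows.append((org, float(t), b.id, b.terminal, w))

        # tip tracks, restricted to the live-imaging window
        tr = run.tip_tracks
        tr = tr[(tr["time [day]"] >= lo - 1e-9) & (tr["time [day]"] <= hi + 1e-9)].copy()
        tr.insert(0, "organoid_id", org)
        tr["branch_id"] = [f"{org}:{b}" for b in tr["branch_id"]]
        track_frames.append(tr)

    pairs = pd.DataFrame(
        pair_rows,
        columns=["organoid_id", "time [day]", "branch_id", "width [um]",
                 "growth_rate [1/day]", "terminal"],
    )
    branch_counts = pd.DataFrame(
        count_rows,
        columns=["organoid_id", "time [day]", "n_branches [count]",
                 "n_terminal [count]", "n_nonterminal [count]"],
    )
    cell_counts = pd.DataFrame(
        cell_rows, columns=["organoid_id", "time [day]", "n_cells [count]"]
    )
    widths = pd.DataFrame(
        width_rows,
        columns=["organoid_id", "time [day]", "branch_id", "terminal", "width [um]"],
    )
    tracks = pd.concat(track_frames, ignore_index=True)

    rng = np.random.default_rng([master_seed, 0x6E015E])
    if n_pairs is not None:
        if n_pairs > len(pairs):
            raise ValueError(f"requested {n_pairs} pairs but only {len(pairs)} measured")
        pairs = pairs.iloc[rng.choice(len(pairs), n_pairs, replace=False)].reset_index(
            drop=True
        )
    pairs["width [um]"] *= _lognormal_factor(rng, noise.width_cv, len(pairs))
    pairs["growth_rate [1/day]"] *= _lognormal_factor(rng, noise.growth_rate_cv, len(pairs))
    cell_counts["n_cells [count]"] *= _lognormal_factor(rng, noise.count_cv, len(cell_counts))
    widths["width [um]"] *= _lognormal_factor(rng, noise.width_cv, len(widths))
    if noise.track_jitter_sd > 0:
        tracks["path_length [um]"] += rng.normal(0.0, noise.track_jitter_sd, len(tracks))

    return SyntheticDataset(
        pairs=pairs,
        branch_counts=branch_counts,
        cell_counts=cell_counts,
        widths=widths,
        tip_tracks=tracks,
        truth=truth,
        noise=noise,
    )


def generate_feedback_pairs(
    truth: GrowthParameters,
    noise: ObservationNoiseModel,
    n_pairs: int,
    width_range: tuple[float, float] = (10.0, 60.0),
) -> pd.DataFrame:
    """Scatter of (width, growth-rate) pairs drawn directly from the feedback
    line — the cheap stand-in for a hand-measured growth-rate scatter when no
    spatial simulation is needed."""
    master_seed = noise.require_seed()
    rng = np.random.default_rng([master_seed, 0xF8])
    widths = rng.uniform(*width_range, n_pairs)
    rates = truth.kd0 * np.maximum(0.0, 1.0 - widths / truth.w0)
    widths = widths * _lognormal_factor(rng, noise.width_cv, n_pairs)
    rates = rates * _lognormal_factor(rng, noise.growth_rate_cv, n_pairs)
    return pd.DataFrame({"width [um]": widths, "growth_rate [1/day]": rates})


WORKED_FIXTURE_SEED = 2093
"""Fixed master seed of the small versioned fixture used in docs and tests."""


def generate_worked_fixture() -> SyntheticDataset:
    """Deterministic tiny dataset: 3 organoids over days 1–9, fixed seed."""
    truth = GrowthParameters()
    noise = ObservationNoiseModel(seed=WORKED_FIXTURE_SEED)
    return generate_morphometric_dataset(
        truth,
        noise,
        n_organoids=3,
        t_grid=np.arange(1.0, 9.0 + 1e-9, 1.0),
    )
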