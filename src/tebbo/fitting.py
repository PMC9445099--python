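"""Parameter recovery from morphometric tables.

Three estimators mirror how the growth parameters are extracted from data:

* :class:`ProliferationFeedbackModel` — ordinary least squares of the
  normalized volumetric growth rate on branch width. Under the feedback
  ``kd(w) = kd0 * (1 - w/w0)`` the intercept is the maximal division rate
  ``kd0`` and the x-axis zero crossing ``-intercept/slope`` is the width
  ``w0`` at which proliferation is abrogated.
* :class:`BranchingRateModel` — log-linear fit of branch counts against
  time; the slope estimates the branching rate ``kb`` of the underlying
  pure-birth process. Both the free-intercept and the pinned-intercept
  (count(0) = 1) variants are reported.
* :class:`TipSpeedModel` — per-track least-squares slope of cumulative tip
  path length against time; path length grows at exactly ``v0`` regardless
  of directional noise, so the mean slope estimates the invasion speed.

Each model follows the Model -> fit() -> Results pattern: results carry the
estimates, their standard errors, optional bootstrap confidence intervals,
and a ``summary()`` table.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .meanfield import MeanFieldTrajectory

__all__ = [
    "ProliferationFeedbackModel",
    "FeedbackFit",
    "BranchingRateModel",
    "ExponentialFit",
    "TipSpeedModel",
    "TipSpeedFit",
    "TipTrack",
    "fit_proliferation_feedback",
    "fit_branching_rate",
    "fit_tip_speed",
    "compare_cellcount_prediction",
    "fit_report",
]


def _bootstrap_ci(
    stat_fn, n: int, n_boot: int, seed: int, level: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI of ``stat_fn(resample_indices)``."""
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        stats[b] = stat_fn(idx)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# proliferation feedback (growth rate vs width)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeedbackFit:
    """OLS fit of growth rate on width and the derived feedback parameters.

    ``kd0`` equals the intercept; ``w0 = -intercept/slope`` is only reported
    when the fitted line actually decreases from a positive intercept
    (``w0_valid``); otherwise accessing ``w0`` raises.
    """

    slope: float            # 1/(day*µm)
    intercept: float        # 1/day
    stderr_slope: float
    stderr_intercept: float
    r2: float
    n: int
    ci95_kd0: tuple[float, float] | None = None
    ci95_w0: tuple[float, float] | None = None
    bootstrap_seed: int | None = None

    @property
    def kd0(self) -> float:
        return self.intercept

    @property
    def w0_valid(self) -> bool:
        return self.slope < 0 and self.intercept > 0

    @property
    def w0(self) -> float:
        if not self.w0_valid:
            raise ValueError(
                "w0 is undefined: the fitted line must decrease from a "
                f"positive intercept (slope={self.slope:g}, intercept={self.intercept:g})"
            )
        return -self.intercept / self.slope

    def summary(self) -> str:
        lines = [
            "Proliferation feedback fit: rate = kd0 * (1 - w / w0)",
            f"  n                 {self.n}",
            f"  slope             {self.slope:.6g} 1/(day*um)  (se {self.stderr_slope:.3g})",
            f"  intercept = kd0   {self.intercept:.6g} 1/day     (se {self.stderr_intercept:.3g})",
            f"  R^2               {self.r2:.4f}",
        ]
        if self.w0_valid:
            lines.append(f"  w0                {self.w0:.6g} um")
        else:
            lines.append("  w0                invalid (non-negative slope or non-positive intercept)")
        if self.ci95_kd0 is not None:
            lines.append(f"  kd0 95% CI (boot) [{self.ci95_kd0[0]:.6g}, {self.ci95_kd0[1]:.6g}]")
        if self.ci95_w0 is not None:
            lines.append(f"  w0  95% CI (boot) [{self.ci95_w0[0]:.6g}, {self.ci95_w0[1]:.6g}]")
        return "\n".join(lines)


class ProliferationFeedbackModel:
    """Linear contact-inhibition feedback fitted to (width, growth-rate) pairs."""

    def __init__(self, width: Sequence[float], rate: Sequence[float]):
        width = np.asarray(width, dtype=float)
        rate = np.asarray(rate, dtype=float)
        if width.shape != rate.shape or width.ndim != 1:
            raise ValueError("width and rate must be 1-d arrays of equal length")
        if width.size < 2:
            raise ValueError("need at least 2 (width, rate) pairs")
        if np.unique(width).size < 2:
            raise ValueError("degenerate design: all widths identical")
        self.width = width
        self.rate = rate

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        width_col: str = "width [um]",
        rate_col: str = "growth_rate [1/day]",
    ) -> "ProliferationFeedbackModel":
        return cls(df[width_col].to_numpy(), df[rate_col].to_numpy())

    def fit(self, n_boot: int = 0, seed: int | None = None) -> FeedbackFit:
        """OLS of rate on width; optional seeded nonparametric bootstrap CIs."""
        X = sm.add_constant(self.width)
        res = sm.OLS(self.rate, X).fit()
        intercept, slope = res.params
        se_i, se_s = res.bse
        ci_kd0 = ci_w0 = None
        if n_boot > 0:
            if seed is None:
                raise ValueError("bootstrap requires an explicit seed")

            def boot_kd0(idx):
                r = sm.OLS(self.rate[idx], sm.add_constant(self.width[idx])).fit()
                return r.params[0]

            def boot_w0(idx):
                r = sm.OLS(self.rate[idx], sm.add_constant(self.width[idx])).fit()
                i, s = r.params
                return -i / s if (s < 0 and i > 0) else np.nan

            n = self.width.size
            ci_kd0 = _bootstrap_ci(boot_kd0, n, n_boot, seed)
            ci_w0 = _bootstrap_ci(boot_w0, n, n_boot, seed + 1)
        return FeedbackFit(
            slope=float(slope),
            intercept=float(intercept),
            stderr_slope=float(se_s),
            stderr_intercept=float(se_i),
            r2=float(res.rsquared) if np.isfinite(res.rsquared) else 1.0,
            n=int(self.width.size),
            ci95_kd0=ci_kd0,
            ci95_w0=ci_w0,
            bootstrap_seed=seed if n_boot > 0 else None,
        )


def fit_proliferation_feedback(
    pairs: Sequence[tuple[float, float]] | pd.DataFrame,
    n_boot: int = 0,
    seed: int | None = None,
) -> FeedbackFit:
    """Fit the feedback line to ``(width, normalized growth rate)`` pairs."""
    if isinstance(pairs, pd.DataFrame):
        model = ProliferationFeedbackModel.from_dataframe(pairs)
    else:
        arr = np.asarray(pairs, dtype=float)
        model = ProliferationFeedbackModel(arr[:, 0], arr[:, 1])
    return model.fit(n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# branching rate (log-linear count fit)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialFit:
    """Log-linear fit ``log(count) = log_intercept + rate * t``."""

    rate: float                      # 1/day, free-intercept slope
    log_intercept: float
    ci95_rate: tuple[float, float]
    n: int
    rate_pinned: float               # slope with intercept pinned at count(0)=1

    def summary(self) -> str:
        return "\n".join(
            [
                "Exponential branch-count fit: count = exp(log_intercept + rate * t)",
                f"  n                {self.n}",
                f"  rate             {self.rate:.6g} 1/day",
                f"  rate 95% CI      [{self.ci95_rate[0]:.6g}, {self.ci95_rate[1]:.6g}]",
                f"  log intercept    {self.log_intercept:.6g}",
                f"  rate (pinned)    {self.rate_pinned:.6g} 1/day  [intercept pinned at count(0)=1]",
            ]
        )


class BranchingRateModel:
    """Exponential growth of branch counts, fitted on the log scale."""

    def __init__(self, times: Sequence[float], counts: Sequence[float]):
        times = np.asarray(times, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if times.shape != counts.shape or times.ndim != 1:
            raise ValueError("times and counts must be 1-d arrays of equal length")
        if times.size < 3:
            raise ValueError("need at least 3 time points")
        bad = np.flatnonzero(counts <= 0)
        if bad.size:
            raise ValueError(
                f"counts must be positive for a log-linear fit; "
                f"row {bad[0]} has count {counts[bad[0]]!r} at t={times[bad[0]]!r}"
            )
        self.times = times
        self.counts = counts

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time [day]",
        count_col: str = "mean_nb [count]",
    ) -> "BranchingRateModel":
        return cls(df[time_col].to_numpy(), df[count_col].to_numpy())

    def fit(self) -> ExponentialFit:
        y = np.log(self.counts)
        X = sm.add_constant(self.times)
        res = sm.OLS(y, X).fit()
        lo, hi = res.conf_int()[1]
        # pinned variant: log(count) = rate * t through the origin
        denom = float(self.times @ self.times)
        pinned = float(self.times @ y) / denom if denom > 0 else float("nan")
        return ExponentialFit(
            rate=float(res.params[1]),
            log_intercept=float(res.params[0]),
            ci95_rate=(float(lo), float(hi)),
            n=int(self.times.size),
            rate_pinned=pinned,
        )


def fit_branching_rate(counts: pd.DataFrame | Sequence[tuple[float, float]]) -> ExponentialFit:
    """Fit the exponential branch-count growth rate (slope of log count vs t)."""
    if isinstance(counts, pd.DataFrame):
        model = BranchingRateModel.from_dataframe(counts)
    else:
        arr = np.asarray(counts, dtype=float)
        model = BranchingRateModel(arr[:, 0], arr[:, 1])
    return model.fit()


# ---------------------------------------------------------------------------
# tip speed
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TipTrack:
    """Cumulative tip path length (µm) sampled at increasing times (days)."""

    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.positions, dtype=float)
        if t.shape != x.shape or t.ndim != 1:
            raise ValueError("times and positions must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("track times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", x)

    @property
    def slope(self) -> float:
        return float(np.polyfit(self.times, self.positions, 1)[0])


@dataclass(frozen=True)
class TipSpeedFit:
    v0: float       # mean per-track slope, µm/day
    sd: float       # across-track standard deviation, µm/day
    n_tracks: int
    n_skipped: int

    def summary(self) -> str:
        return (
            f"Tip-speed fit: v0 = {self.v0:.6g} ± {self.sd:.3g} um/day "
            f"(mean ± sd over {self.n_tracks} tracks, {self.n_skipped} skipped)"
        )


class TipSpeedModel:
    """Per-tip elongation-speed regression on cumulative path-length tracks."""

    def __init__(self, tracks: Sequence[TipTrack]):
        self.tracks = list(tracks)
        if not self.tracks:
            raise ValueError("need at least one tip track")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        id_col: str = "branch_id",
        time_col: str = "time [day]",
        pos_col: str = "path_length [um]",
        min_samples: int = 3,
    ) -> "TipSpeedModel":
        """Build tracks from a long table, keeping tips with enough samples."""
        tracks = []
        for _, g in df.groupby(id_col):
            if len(g) >= min_samples:
                g = g.sort_values(time_col)
                tracks.append(TipTrack(g[time_col].to_numpy(), g[pos_col].to_numpy()))
        if not tracks:
            raise ValueError("no track has the minimum number of samples")
        return cls(tracks)

    @staticmethod
    def fit_dataframe(
        df: pd.DataFrame,
        id_col: str = "branch_id",
        time_col: str = "time [day]",
        pos_col: str = "path_length [um]",
        min_samples: int = 3,
    ) -> TipSpeedFit:
        """Vectorized per-track slope fit on a long table (no per-group
        Python loop; identical result to :meth:`from_dataframe` + ``fit``)."""
        codes, _ = pd.factorize(df[id_col], sort=False)
        t = df[time_col].to_numpy(dtype=float)
        x = df[pos_col].to_numpy(dtype=float)
        k = codes.max() + 1 if codes.size else 0
        if k == 0:
            raise ValueError("no tip tracks in table")
        n = np.bincount(codes, minlength=k).astype(float)
        st = np.bincount(codes, weights=t, minlength=k)
        sx = np.bincount(codes, weights=x, minlength=k)
        stt = np.bincount(codes, weights=t * t, minlength=k)
        stx = np.bincount(codes, weights=t * x, minlength=k)
        keep = n >= min_samples
        if not keep.any():
            raise ValueError("no track has the minimum number of samples")
        denom = n[keep] * stt[keep] - st[keep] ** 2
        slopes = (n[keep] * stx[keep] - st[keep] * sx[keep]) / denom
        return TipSpeedFit(
            v0=float(slopes.mean()),
            sd=float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0,
            n_tracks=int(slopes.size),
            n_skipped=int((~keep).sum()),
        )

    def fit(self, min_samples: int = 3) -> TipSpeedFit:
        slopes = []
        skipped = 0
        for tr in self.tracks:
            if tr.times.size < min_samples:
                warnings.warn(
                    f"skipping tip track with {tr.times.size} < {min_samples} samples",
                    stacklevel=2,
                )
                skipped += 1
                continue
            slopes.append(tr.slope)
        if not slopes:
            raise ValueError("all tip tracks were skipped (too few samples)")
        slopes = np.asarray(slopes)
        return TipSpeedFit(
            v0=float(slopes.mean()),
            sd=float(slopes.std(ddof=1)) if slopes.size > 1 else 0.0,
            n_tracks=int(slopes.size),
            n_skipped=skipped,
        )


def fit_tip_speed(tracks: Sequence[TipTrack] | pd.DataFrame) -> tuple[float, float]:
    """Mean and sd of per-track elongation speeds, µm/day."""
    model = (
        TipSpeedModel.from_dataframe(tracks)
        if isinstance(tracks, pd.DataFrame)
        else TipSpeedModel(tracks)
    )
    res = model.fit()
    return res.v0, res.sd


# ---------------------------------------------------------------------------
# cell-count comparison
# ---------------------------------------------------------------------------


def compare_cellcount_prediction(
    traj: MeanFieldTrajectory,
    observed: pd.DataFrame,
    time_col: str = "time [day]",
    mean_col: str = "mean_nc [cells]",
    sd_col: str = "sd_nc [cells]",
) -> tuple[float, float]:
    """Compare a mean-field cell-number prediction with observed counts.

    Returns ``(rmse, coverage)``: the root-mean-square error between predicted
    and observed mean cell numbers on the log scale over matched times, and
    the fraction of times at which the prediction lies within mean ± sd
    (boundary counted in).
    """
    times = observed[time_col].to_numpy(dtype=float)
    if times.size == 0:
        raise ValueError("no observation times")
    t = traj.t
    in_span = (times >= t[0] - 1e-9) & (times <= t[-1] + 1e-9)
    if not in_span.any():
        raise ValueError("no observation times overlap the trajectory span")
    if not in_span.all():
        raise ValueError("observation times lie outside the trajectory span")
    pred = np.interp(times, t, traj.Nc)
    mean = observed[mean_col].to_numpy(dtype=float)
    sd = observed[sd_col].to_numpy(dtype=float)
    rmse = float(np.sqrt(np.mean((np.log(pred) - np.log(mean)) ** 2)))
    covered = np.abs(pred - mean) <= sd + 1e-9 * np.maximum(np.abs(mean), 1.0)
    return rmse, float(np.mean(covered))


# ---------------------------------------------------------------------------
# whole-dataset report
# ---------------------------------------------------------------------------


def fit_report(
    pairs: pd.DataFrame,
    branch_counts: pd.DataFrame,
    tip_tracks: pd.DataFrame,
    n_boot: int = 0,
    seed: int | None = None,
) -> dict:
    """Fit all three estimators on a dataset's tables and return a JSON-ready
    report (estimates, uncertainties, n, and the bootstrap seed used)."""
    fb = ProliferationFeedbackModel.from_dataframe(pairs).fit(n_boot=n_boot, seed=seed)
    # ensemble-mean terminal (tip) count per time point: tips are the
    # individuals of the pure-birth process, so log(mean tips) is linear in t
    # with slope kb from t = 0 on (the all-segment count 2m - 1 only reaches
    # that slope asymptotically)
    counts = (
        branch_counts.groupby("time [day]")["n_terminal [count]"]
        .mean()
        .reset_index()
        .rename(columns={"n_terminal [count]": "mean_nb [count]"})
    )
    bc = BranchingRateModel.from_dataframe(counts).fit()
    ts = TipSpeedModel.fit_dataframe(tip_tracks)
    report = {
        "feedback": {
            "kd0 [1/day]": fb.kd0,
            "w0 [um]": fb.w0 if fb.w0_valid else None,
            "slope [1/(day*um)]": fb.slope,
            "stderr_slope": fb.stderr_slope,
            "stderr_intercept": fb.stderr_intercept,
            "r2": fb.r2,
            "n": fb.n,
            "ci95_kd0": list(fb.ci95_kd0) if fb.ci95_kd0 else None,
            "ci95_w0": list(fb.ci95_w0) if fb.ci95_w0 else None,
        },
        "branching": {
            "kb [1/day]": bc.rate,
            "kb_pinned [1/day]": bc.rate_pinned,
            "ci95_kb": list(bc.ci95_rate),
            "log_intercept": bc.log_intercept,
            "n": bc.n,
        },
        "tip_speed": {
            "v0 [um/day]": ts.v0,
            "sd [um/day]": ts.sd,
            "n_tracks": ts.n_tracks,
        },
        "seed": seed,
    }
    return report
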