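"""Dissociation kinetics and mode populations from trajectory sets.

The central object is the time-averaged survival probability distribution.
With N(i, j) the number of trajectories present at frame i that last through
frame i+j-1 (j = 1 means "present at frame i"), the per-start-frame survival
is N(i, j)/N(i, 1) and the time-averaged distribution is its mean over all
window starts i with N(i, 1) > 0.  Because sampling a molecule "present at
frame i" is length-biased, the amplitudes of this distribution weight each
dwell population by its occupancy, not by its arrival frequency; lag j maps
to the further-survival time t = (j - 1) * dt, so P_survival(t=0) = 1 exactly.

P_survival(t) is fit to the bi-exponential mixture

    P_survival(t) = P1 * exp(-k_off1 * t) + P2 * exp(-k_off2 * t),  P1 + P2 = 1

whose rates are the dissociation rate constants of the Dynamic (fast) and
Stable (slow) membrane-binding modes.  No censoring or photobleaching
correction is applied; the estimator inherits the raw window counts, and the
generator's truth labels let tests quantify the resulting (small) biases.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import lmfit
import numpy as np
import pandas as pd

from .synthetic_trajectories import TrajectorySet

__all__ = [
    "SurvivalCurve",
    "BiExpFitResult",
    "ModePopulations",
    "ApparentAssociationRates",
    "BleachFitResult",
    "compute_survival",
    "fit_biexponential",
    "classify_modes",
    "estimate_association",
    "fit_bleaching",
]


@dataclass
class SurvivalCurve:
    """Time-averaged survival probability distribution with window counts."""

    lags: np.ndarray          # j = 1..j_max
    times: np.ndarray         # (j - 1) * dt, s
    p_survival: np.ndarray
    n_windows: np.ndarray     # number of contributing window starts per lag
    n_start: np.ndarray       # occupancy N(i, 1) per frame i
    dt: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.p_survival = np.asarray(self.p_survival, dtype=float)
        self.n_windows = np.asarray(self.n_windows, dtype=int)
        self.n_start = np.asarray(self.n_start)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag": self.lags,
                "t_s": self.times,
                "p_survival": self.p_survival,
                "n_windows": self.n_windows,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dt: float | None = None) -> "SurvivalCurve":
        df = pd.read_csv(path)
        lags = df["lag"].to_numpy(int)
        times = df["t_s"].to_numpy(float)
        if dt is None:
            dt = float(np.diff(times).mean()) if len(times) > 1 else 1.0
        return cls(
            lags=lags,
            times=times,
            p_survival=df["p_survival"].to_numpy(float),
            n_windows=df["n_windows"].to_numpy(int),
            n_start=np.array([]),
            dt=dt,
        )


def _gather(ts: TrajectorySet | Iterable[TrajectorySet]):
    sets = [ts] if isinstance(ts, TrajectorySet) else list(ts)
    if not sets:
        raise ValueError("no trajectory sets supplied")
    cfg = sets[0].config
    starts, lengths = [], []
    for s in sets:
        if s.config.n_frames != cfg.n_frames or s.config.dt != cfg.dt:
            raise ValueError("all trajectory sets must share n_frames and dt")
        for tr in s.trajectories:
            starts.append(tr.start_frame)
            lengths.append(tr.n_bound_frames)
    if not starts:
        raise ValueError("empty trajectory set")
    return np.asarray(starts), np.asarray(lengths), cfg


def compute_survival(
    ts: TrajectorySet | Iterable[TrajectorySet], j_max: int | None = None
) -> SurvivalCurve:
    """Time-averaged survival probability from one movie or a pool of movies.

    Pooling replicate movies (aligned at frame 1) simply sums their window
    counts, mirroring averaging over independent observation areas.
    Censored trajectories contribute to every window they span; no censoring
    correction is applied.
    """
    starts, lengths, cfg = _gather(ts)
    m = cfg.n_frames
    if j_max is None:
        j_max = m
    elif j_max > m:
        warnings.warn(f"j_max={j_max} exceeds movie length {m}; truncating")
        j_max = m
    ends = starts + lengths - 1

    # occupancy N(i, 1), i = 1..m (index 0 unused)
    occ = np.zeros(m + 2, dtype=np.int64)
    np.add.at(occ, starts, 1)
    np.add.at(occ, ends + 1, -1)
    occ = np.cumsum(occ)[: m + 1]  # occ[i] = N(i, 1)

    # N(i, j) = (# active with start <= i) - (# active with end <= i+j-2),
    # where "active" means length >= j. Maintained incrementally in j.
    start_hist = np.bincount(starts, minlength=m + 2).astype(np.int64)
    end_hist = np.bincount(ends, minlength=m + 2).astype(np.int64)
    asc = np.argsort(lengths, kind="stable")
    ptr = 0
    n = len(starts)

    p = np.full(j_max, np.nan)
    n_windows = np.zeros(j_max, dtype=np.int64)
    for j in range(1, j_max + 1):
        while ptr < n and lengths[asc[ptr]] < j:
            k = asc[ptr]
            start_hist[starts[k]] -= 1
            end_hist[ends[k]] -= 1
            ptr += 1
        cum_s = np.cumsum(start_hist)
        cum_e = np.cumsum(end_hist)
        i = np.arange(1, m - j + 2)
        shift = i + j - 2
        n_ij = cum_s[i] - np.where(shift >= 1, cum_e[np.minimum(shift, m + 1)], 0)
        denom = occ[i]
        valid = denom > 0
        n_windows[j - 1] = int(valid.sum())
        if n_windows[j - 1]:
            p[j - 1] = float(np.mean(n_ij[valid] / denom[valid]))

    keep = ~np.isnan(p)
    lags = np.arange(1, j_max + 1)[keep]
    return SurvivalCurve(
        lags=lags,
        times=(lags - 1) * cfg.dt,
        p_survival=p[keep],
        n_windows=n_windows[keep],
        n_start=occ[1:],
        dt=cfg.dt,
    )


@dataclass
class BiExpFitResult:
    """Constrained bi-exponential fit of a survival curve (P1 + P2 = 1).

    Two components are only identifiable as distinct kinetic modes when both
    amplitudes are appreciable, the rates are well separated, and each rate
    lies inside the observable band.  Otherwise ``effectively_single`` is set
    and ``dominant_rate`` carries the rate of a single-exponential refit;
    ``fast_rate``/``slow_rate`` then both fall back to it (a
    near-single-exponential curve pins only one rate).
    """

    P1: float
    P2: float
    k_off1: float
    k_off2: float
    residual_norm: float
    converged: bool
    n_restarts_used: int
    k_off2_near_window_limit: bool = False
    window_limit: float = 0.0
    effectively_single: bool = False
    dominant_rate: float | None = None

    @property
    def fast_rate(self) -> float:
        return self.dominant_rate if self.effectively_single else self.k_off1

    @property
    def slow_rate(self) -> float:
        return self.dominant_rate if self.effectively_single else self.k_off2

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _biexp(t, p1, k_fast, k_slow):
    return p1 * np.exp(-k_fast * t) + (1.0 - p1) * np.exp(-k_slow * t)


def fit_biexponential(
    curve: SurvivalCurve,
    restarts: int = 16,
    weight_by_windows: bool = False,
    min_window_support: float = 0.75,
    seed: int = 0,
) -> BiExpFitResult:
    """Nonlinear least squares of the two-exponential mixture.

    Multi-start from a fixed log-spaced grid of rate-pair guesses; amplitudes
    are constrained to sum to 1 and the slow/fast ordering is enforced by a
    post-hoc swap.  ``k_off2_near_window_limit`` flags a slow rate within a
    factor of 3 of the slowest observable rate 1/(movie duration): such a
    value is a lower bound on the kinetic stability of the Stable mode.

    By default only lags whose window count is at least ``min_window_support``
    times the maximum are fit: the longest lags are sampled from a handful of
    strongly correlated window starts dominated by the movie's non-stationary
    start-up, and letting them into an unweighted fit corrupts the fast rate.
    Set ``min_window_support=0`` to fit the full curve.
    """
    mask = np.isfinite(curve.p_survival)
    if min_window_support > 0 and curve.n_windows.size:
        mask &= curve.n_windows >= min_window_support * curve.n_windows.max()
    t = curve.times[mask]
    y = curve.p_survival[mask]
    if len(t) < 6:
        raise ValueError("survival curve must have at least 6 lags to fit")
    w = np.sqrt(np.maximum(curve.n_windows[mask], 1)) if weight_by_windows else None

    t_pos = t[t > 0]
    k_lo = max(1.0 / (t_pos[-1] * 3.0), 1e-6)
    k_hi = 1.0 / t_pos[0]
    grid = np.geomspace(k_lo, k_hi, 6)
    pairs = [(kf, ks) for kf in grid for ks in grid if kf > ks][:restarts]
    if not pairs:
        pairs = [(k_hi, k_lo)]

    def residual(params):
        r = _biexp(t, params["p1"].value, params["k_fast"].value, params["k_slow"].value) - y
        return r * w if w is not None else r

    best, best_cost, n_used = None, np.inf, 0
    for kf0, ks0 in pairs:
        params = lmfit.Parameters()
        params.add("p1", value=0.5, min=0.0, max=1.0)
        params.add("k_fast", value=kf0, min=1e-9)
        params.add("k_slow", value=ks0, min=1e-9)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        n_used += 1
        cost = float(np.sum(res.residual**2))
        if res.success and cost < best_cost:
            best, best_cost = res, cost
    if best is None:
        raise RuntimeError("bi-exponential fit failed to converge from all restarts")

    p1 = best.params["p1"].value
    kf, ks = best.params["k_fast"].value, best.params["k_slow"].value
    if kf < ks:  # enforce k_off2 < k_off1
        kf, ks, p1 = ks, kf, 1.0 - p1

    # degeneracy resolution: an unresolved mixture pins only one rate, so
    # refit a single exponential and report its rate as the only resolved
    # component (canonically in slot 1 with P1 = 1). Unresolved means: a
    # vanishing component amplitude, rates not separated, or a minor
    # component whose rate lies outside the observable band (slower than the
    # fit window or faster than the frame rate).
    window_limit = 1.0 / (t_pos[-1] + curve.dt)
    effectively_single = (
        min(p1, 1.0 - p1) < 0.01
        or (ks > 0 and kf / ks < 3.0)
        or ((1.0 - p1) < 0.1 and ks < window_limit)
        or (p1 < 0.1 and kf > 2.0 / curve.dt)
    )
    dominant = None
    if effectively_single:
        sp = lmfit.Parameters()
        sp.add("k", value=kf if p1 >= 0.5 else ks, min=1e-9)

        def single_residual(params):
            r = np.exp(-params["k"].value * t) - y
            return r * w if w is not None else r

        sres = lmfit.minimize(single_residual, sp, method="leastsq")
        dominant = float(sres.params["k"].value)
        p1, kf, ks = 1.0, dominant, dominant

    return BiExpFitResult(
        P1=float(p1),
        P2=float(1.0 - p1),
        k_off1=float(kf),
        k_off2=float(ks),
        residual_norm=float(np.sqrt(best_cost)),
        converged=bool(best.success),
        n_restarts_used=n_used,
        k_off2_near_window_limit=bool(ks <= 3.0 * window_limit),
        window_limit=float(window_limit),
        effectively_single=bool(effectively_single),
        dominant_rate=dominant,
    )


@dataclass
class ModePopulations:
    """Trajectory fractions classified Dynamic/Stable by a lifetime cutoff."""

    P1: float  # Dynamic (lifetime <= cutoff)
    P2: float  # Stable (lifetime > cutoff)
    cutoff: float
    n_total: int
    amplitude_P1: float | None = None  # bi-exponential amplitudes, if supplied
    amplitude_P2: float | None = None
    amplitude_discrepancy: float | None = None


def classify_modes(
    ts: TrajectorySet | Iterable[TrajectorySet],
    cutoff: float = 0.25,
    biexp: BiExpFitResult | None = None,
) -> ModePopulations:
    """Classify trajectories by lifetime: > cutoff -> Stable, else Dynamic.

    A tie at exactly the cutoff counts as Dynamic (strict > for Stable).
    When a bi-exponential fit is supplied, its (occupancy-weighted) amplitudes
    are attached for an agreement diagnostic against the classified
    (arrival-weighted) fractions.
    """
    sets = [ts] if isinstance(ts, TrajectorySet) else list(ts)
    lifetimes = np.concatenate([s.lifetimes() for s in sets]) if sets else np.array([])
    if lifetimes.size == 0:
        raise ValueError("empty trajectory set")
    p2 = float(np.mean(lifetimes > cutoff))
    pops = ModePopulations(P1=1.0 - p2, P2=p2, cutoff=cutoff, n_total=int(lifetimes.size))
    if biexp is not None:
        pops.amplitude_P1 = biexp.P1
        pops.amplitude_P2 = biexp.P2
        pops.amplitude_discrepancy = abs(pops.P2 - biexp.P2)
    return pops


@dataclass
class ApparentAssociationRates:
    """Per-mode apparent association rate constants from cumulative arrivals.

    Slopes of cumulative new-trajectory counts vs time (per observation
    area), normalized by total protein concentration; uncorrected for the
    solution-phase conformational fractions.
    """

    k1_app: float
    k2_app: float
    slope_se: tuple[float, float]
    window: tuple[float, float]
    k1_wide_error: bool = False
    k2_wide_error: bool = False


def _origin_ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin with its standard error."""
    stt = float(np.sum(t * t))
    slope = float(np.sum(t * y)) / stt
    resid = y - slope * t
    dof = max(len(t) - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / stt))
    return slope, se


def estimate_association(
    ts: TrajectorySet | Iterable[TrajectorySet],
    conc: float,
    cutoff: float = 0.25,
) -> ApparentAssociationRates:
    """Apparent association rates from cumulative appearances of new tracks.

    New-trajectory arrival times (start frames) are split into Dynamic and
    Stable classes by the lifetime cutoff; cumulative counts over the full
    movie are regressed linearly against time with the intercept forced
    through the origin (the count starts at 0 by construction).  For a pool
    of movies the mean cumulative count per movie is used.  Classes with
    fewer than 10 events carry a wide-error flag.
    """
    if conc <= 0:
        raise ValueError("conc must be > 0")
    sets = [ts] if isinstance(ts, TrajectorySet) else list(ts)
    if not sets or all(len(s) == 0 for s in sets):
        raise ValueError("empty trajectory set")
    cfg = sets[0].config
    dt, m = cfg.dt, cfg.n_frames
    grid = np.arange(1, m + 1) * dt

    slopes, ses, counts = [], [], []
    for is_stable in (False, True):
        cum = np.zeros(m)
        n_events = 0
        for s in sets:
            for tr in s.trajectories:
                stable = tr.n_bound_frames * dt > cutoff
                if stable == is_stable:
                    cum[tr.start_frame - 1:] += 1
                    n_events += 1
        cum /= len(sets)
        slope, se = _origin_ols(grid, cum)
        slopes.append(max(slope, 0.0) / conc)
        ses.append(se / conc)
        counts.append(n_events)

    return ApparentAssociationRates(
        k1_app=slopes[0],
        k2_app=slopes[1],
        slope_se=(ses[0], ses[1]),
        window=(float(grid[0]), float(grid[-1])),
        k1_wide_error=counts[0] < 10,
        k2_wide_error=counts[1] < 10,
    )


@dataclass
class BleachFitResult:
    """Single-exponential photobleaching rate of a tethered-control trace."""

    bleach_rate: float
    ratio_to_koff2: float | None = None


def fit_bleaching(
    times: Sequence[float],
    intensity: Sequence[float],
    biexp: BiExpFitResult | None = None,
) -> BleachFitResult:
    """Fit total-intensity decay of a surface-tethered control to A*exp(-k*t).

    A constant trace yields rate 0; a clearly increasing trace is rejected.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 points")
    slope = np.polyfit(t, y, 1)[0]
    y_scale = float(np.max(np.abs(y)))
    if slope > 0 and (y[-1] - y[0]) > 1e-6 * max(y_scale, 1e-12):
        raise ValueError("intensity trace is increasing; not a bleaching decay")
    if np.allclose(y, y[0]):
        return BleachFitResult(0.0, _bleach_ratio(0.0, biexp))

    params = lmfit.Parameters()
    params.add("amp", value=float(y[0]), min=0.0)
    params.add("rate", value=max(-slope / max(y[0], 1e-12), 1e-6), min=0.0)

    def residual(p):
        return p["amp"].value * np.exp(-p["rate"].value * t) - y

    res = lmfit.minimize(residual, params, method="leastsq")
    rate = float(res.params["rate"].value)
    return BleachFitResult(rate, _bleach_ratio(rate, biexp))


def _bleach_ratio(rate: float, biexp: BiExpFitResult | None) -> float | None:
    if biexp is None or biexp.k_off2 == 0:
        return None
    return rate / biexp.k_off2
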