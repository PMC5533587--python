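"""Synthetic single-molecule membrane-binding trajectories.

Emulates smTIRF movies of a receptor that binds a supported lipid bilayer
(SLB) in two kinetically distinct modes:

* a *Dynamic* mode — fast dissociation (rate ``k_off1``), and
* a *Stable* mode — slow dissociation (``k_off2 <= k_off1``).

Membrane arrivals form a Poisson process whose per-mode intensity is
``f_x * k_x * conc * area`` (solution fraction x association rate constant x
protein concentration x observed membrane area).  Each arrival draws an
exponential dwell with rate ``k_off_x + bleach_rate`` (dissociation competes
with photobleaching); while bound the molecule performs 2D Brownian motion.
Dwell times are quantized to camera frames: a molecule bound during any part
of a frame is detected in that frame, so a dwell of duration tau occupies
``ceil(tau / dt)`` frames starting at its arrival frame.  Trajectories that
are still bound at the end of the movie are truncated and flagged censored.

The solution phase is treated as a well-mixed, undepleted reservoir: arrival
modes are drawn directly from the per-mode intensities and molecules do not
interconvert between modes while membrane-bound (the dwell-time analysis
assumes two non-interconverting populations).  An optional switch enables
membrane-side Dynamic<->Stable interconversion for stress-testing estimators.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GroundTruthKinetics",
    "ImagingConfig",
    "Trajectory",
    "TrajectorySet",
    "FREE_RECEPTOR_TRUTH",
    "COMPLEX_TRUTH",
    "simulate_trajectories",
    "simulate_movies",
    "apply_qc_filters",
    "QCReport",
]

DYNAMIC = "Dynamic"
STABLE = "Stable"
BLEACHED = "bleached"


@dataclass(frozen=True)
class GroundTruthKinetics:
    """Rate/equilibrium parameters of the two-mode membrane-binding model.

    ``k1``/``k2`` are true association rate constants (per µM per µm² per s);
    ``k_off1``/``k_off2`` dissociation rates (1/s); ``f1``/``f2`` the solution
    fractions of the Dynamic- and Stable-binding conformations; ``conc`` the
    total protein concentration (µM).
    """

    k1: float
    k_off1: float
    k2: float
    k_off2: float
    f1: float
    f2: float
    conc: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1", "k_off1", "k2", "k_off2", "f1", "f2", "conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.k_off2 > self.k_off1:
            raise ValueError(
                "k_off2 must be <= k_off1 (the Stable mode dwells longer by definition)"
            )
        if abs(self.f1 + self.f2 - 1.0) > 1e-12:
            raise ValueError("f1 + f2 must equal 1")

    def arrival_intensities(self, area: float) -> tuple[float, float]:
        """Poisson arrival intensities (events/s) of the two modes over `area` µm²."""
        lam1 = self.f1 * self.k1 * self.conc * area
        lam2 = self.f2 * self.k2 * self.conc * area
        return lam1, lam2


# Default study conditions. Dissociation rates are the measured dwell
# constants of the two modes; the true association ratio k1/k2 = 10 and the
# arrival-mode fractions (92/8 for the free receptor, 8/92 for the SRP-bound
# complex) jointly fix the solution fractions below, which places the
# conformational equilibrium shift at 132-fold and the membrane bias
# K2/K1 at 17.3. The absolute scale of k1 gives ~315 arrivals per 20 s movie
# at 1 µM over 6 µm².
FREE_RECEPTOR_TRUTH = GroundTruthKinetics(
    k1=4.5, k_off1=14.0, k2=0.45, k_off2=0.081, f1=23 / 43, f2=20 / 43, conc=1.0
)
COMPLEX_TRUTH = GroundTruthKinetics(
    k1=4.5, k_off1=14.0, k2=0.45, k_off2=0.081, f1=1 / 116, f2=115 / 116, conc=1.0
)


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition settings of a synthetic smTIRF movie.

    dt: frame interval (s); n_frames: movie length; area: observed membrane
    area (µm²); bleach_rate: photobleaching rate (1/s); diffusion_coeff: 2D
    diffusion coefficient of bound molecules (µm²/s); intensity_noise:
    fractional per-frame fluorescence noise; seed: mandatory RNG seed.
    """

    seed: int
    dt: float = 0.020
    n_frames: int = 1000
    area: float = 6.0
    bleach_rate: float = 0.005
    diffusion_coeff: float = 1.0
    intensity_noise: float = 0.03
    mode_switching: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be >= 0")

    @property
    def duration(self) -> float:
        return self.n_frames * self.dt


@dataclass
class Trajectory:
    """One membrane-bound track with frame-quantized dwell time."""

    traj_id: int
    start_frame: int  # 1-based
    n_bound_frames: int
    positions: np.ndarray  # (n_bound_frames, 2), µm
    intensity: np.ndarray  # (n_bound_frames,)
    mode_truth: str  # Dynamic | Stable | bleached
    censored: bool
    arrival_mode: str = ""  # arrival-mode label, kept also for bleached tracks
    movie_id: int = 0
    single_frame_qc_exempt: bool = False

    def __post_init__(self) -> None:
        if self.n_bound_frames < 1:
            raise ValueError("n_bound_frames must be >= 1")
        if len(self.positions) != self.n_bound_frames:
            raise ValueError("positions length must equal n_bound_frames")
        if not self.arrival_mode:
            self.arrival_mode = self.mode_truth

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.n_bound_frames - 1

    def lifetime(self, dt: float) -> float:
        return self.n_bound_frames * dt


@dataclass
class TrajectorySet:
    """A movie's worth of trajectories plus the settings that produced them."""

    trajectories: list[Trajectory]
    config: ImagingConfig
    truth: GroundTruthKinetics | None = None
    empty_warning: bool = False

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def lifetimes(self) -> np.ndarray:
        dt = self.config.dt
        return np.array([tr.n_bound_frames * dt for tr in self.trajectories])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per bound frame (the trajectory CSV layout)."""
        rows = []
        dt = self.config.dt
        for tr in self.trajectories:
            frames = np.arange(tr.start_frame, tr.end_frame + 1)
            rows.append(
                pd.DataFrame(
                    {
                        "traj_id": tr.traj_id,
                        "start_frame": tr.start_frame,
                        "frame": frames,
                        "t_s": (frames - 1) * dt,
                        "x_um": tr.positions[:, 0],
                        "y_um": tr.positions[:, 1],
                        "intensity": tr.intensity,
                        "mode_truth": tr.mode_truth,
                        "censored": tr.censored,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=[
                    "traj_id", "start_frame", "frame", "t_s", "x_um", "y_um",
                    "intensity", "mode_truth", "censored",
                ]
            )
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: ImagingConfig, truth: GroundTruthKinetics | None = None
    ) -> "TrajectorySet":
        trajectories = []
        for tid, grp in df.groupby("traj_id", sort=True):
            grp = grp.sort_values("frame")
            trajectories.append(
                Trajectory(
                    traj_id=int(tid),
                    start_frame=int(grp["start_frame"].iloc[0]),
                    n_bound_frames=len(grp),
                    positions=grp[["x_um", "y_um"]].to_numpy(float),
                    intensity=grp["intensity"].to_numpy(float),
                    mode_truth=str(grp["mode_truth"].iloc[0]),
                    censored=bool(grp["censored"].iloc[0]),
                )
            )
        return cls(trajectories, config, truth)

    @classmethod
    def from_csv(
        cls, path, config: ImagingConfig, truth: GroundTruthKinetics | None = None
    ) -> "TrajectorySet":
        return cls.from_dataframe(pd.read_csv(path), config, truth)


def load_generator_config(path) -> tuple[GroundTruthKinetics, ImagingConfig]:
    """Read a YAML file whose keys mirror the two config dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    truth = GroundTruthKinetics(**raw["kinetics"])
    config = ImagingConfig(**raw["imaging"])
    return truth, config


def simulate_trajectories(
    truth: GroundTruthKinetics,
    config: ImagingConfig,
    rng: np.random.Generator | None = None,
    movie_id: int = 0,
) -> TrajectorySet:
    """Generate one synthetic movie of membrane-binding trajectories.

    Fully reproducible for a fixed ``config.seed``: the supplied (or derived)
    generator is consumed in a fixed, documented order — arrival counts, then
    arrival times, dwells, bleach labels, and finally per-track positions and
    intensities.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam1, lam2 = truth.arrival_intensities(config.area)
    if lam1 + lam2 == 0:
        warnings.warn("zero total arrival intensity: returning an empty trajectory set")
        return TrajectorySet([], config, truth, empty_warning=True)

    T = config.duration
    n1 = rng.poisson(lam1 * T)
    n2 = rng.poisson(lam2 * T)
    arrival_t = np.concatenate([rng.uniform(0.0, T, n1), rng.uniform(0.0, T, n2)])
    mode = np.array([DYNAMIC] * n1 + [STABLE] * n2)
    k_off = np.where(mode == DYNAMIC, truth.k_off1, truth.k_off2)

    # competing dissociation/bleaching; zero total rate means the molecule
    # never leaves (dwell = inf, censored at the movie end)
    total_rate = k_off + config.bleach_rate
    scale = np.divide(
        1.0, total_rate, out=np.full_like(total_rate, np.inf), where=total_rate > 0
    )
    dwell = rng.exponential(scale)
    p_bleach = np.divide(
        config.bleach_rate, total_rate, out=np.zeros_like(total_rate), where=total_rate > 0
    )
    bleached = rng.random(n1 + n2) < p_bleach

    if config.mode_switching:
        dwell, mode, bleached = _apply_membrane_switching(
            rng, dwell, mode, bleached, truth, config
        )

    order = np.argsort(arrival_t, kind="stable")
    arrival_t, mode, dwell, bleached = (
        arrival_t[order], mode[order], dwell[order], bleached[order]
    )

    dt, m = config.dt, config.n_frames
    start_frame = np.floor(arrival_t / dt).astype(int) + 1
    with np.errstate(over="ignore"):
        n_bound_f = np.ceil(dwell / dt)
    n_bound = np.where(np.isfinite(n_bound_f), np.minimum(n_bound_f, m + 1), m + 1)
    n_bound = np.maximum(1, n_bound.astype(int))
    end_frame = start_frame + n_bound - 1
    censored = end_frame > m
    n_bound = np.where(censored, m - start_frame + 1, n_bound)

    sigma_step = math.sqrt(2.0 * config.diffusion_coeff * dt)
    box = math.sqrt(config.area)
    trajectories: list[Trajectory] = []
    for i in range(len(arrival_t)):
        n = int(n_bound[i])
        steps = rng.normal(0.0, sigma_step, size=(n, 2))
        steps[0] = rng.uniform(0.0, box, size=2)
        positions = np.cumsum(steps, axis=0)
        intensity = 1.0 + rng.normal(0.0, config.intensity_noise, size=n)
        label = BLEACHED if (bleached[i] and not censored[i]) else str(mode[i])
        trajectories.append(
            Trajectory(
                traj_id=i,
                start_frame=int(start_frame[i]),
                n_bound_frames=n,
                positions=positions,
                intensity=intensity,
                mode_truth=label,
                censored=bool(censored[i]),
                arrival_mode=str(mode[i]),
                movie_id=movie_id,
            )
        )
    return TrajectorySet(trajectories, config, truth)


def _apply_membrane_switching(rng, dwell, mode, bleached, truth, config):
    """Optional membrane-side Dynamic<->Stable interconversion (stress test only).

    Uses the detailed-balance-consistent switching rates implied by the mode
    bias K2/K1: Dynamic->Stable at k_sw, Stable->Dynamic at k_sw/(K2/K1), with
    k_sw set to k_off2 (slow relative to Dynamic dwells). The final dwell is the
    total membrane residence; the reported mode is the mode at dissociation.
    """
    K_ratio = (truth.k2 / truth.k_off2) / (truth.k1 / truth.k_off1) if truth.k1 else 1.0
    k_sw12 = truth.k_off2
    k_sw21 = k_sw12 / K_ratio if K_ratio > 0 else 0.0
    out_dwell = np.empty_like(dwell)
    out_mode = mode.copy()
    out_bleach = bleached.copy()
    for i in range(len(dwell)):
        t, cur = 0.0, mode[i]
        while True:
            k_off = truth.k_off1 if cur == DYNAMIC else truth.k_off2
            k_sw = k_sw12 if cur == DYNAMIC else k_sw21
            total = k_off + k_sw + config.bleach_rate
            t += rng.exponential(1.0 / total)
            u = rng.random() * total
            if u < k_off:
                out_bleach[i] = False
                break
            if u < k_off + config.bleach_rate:
                out_bleach[i] = True
                break
            cur = STABLE if cur == DYNAMIC else DYNAMIC
        out_dwell[i], out_mode[i] = t, cur
    return out_dwell, out_mode, out_bleach


def simulate_movies(
    truth: GroundTruthKinetics, config: ImagingConfig, n_movies: int
) -> list[TrajectorySet]:
    """Independent replicate movies (distinct observation areas) from one seed."""
    seeds = np.random.SeedSequence(config.seed).spawn(n_movies)
    sets = []
    for i, ss in enumerate(seeds):
        sets.append(
            simulate_trajectories(
                truth, config, rng=np.random.default_rng(ss), movie_id=i
            )
        )
    return sets


@dataclass
class QCReport:
    n_input: int
    n_removed_immobile: int
    n_removed_intensity: int
    n_single_frame_exempt: int


def apply_qc_filters(
    ts: TrajectorySet,
    mobility_floor: float = 1e-4,
    intensity_cv_ceiling: float = 0.2,
) -> tuple[TrajectorySet, QCReport]:
    """Discard immobile tracks (aggregates at bilayer defects) and tracks with
    unstable fluorescence intensity (noise).

    Mobility is the mean squared frame-to-frame displacement (µm²); tracks
    below ``mobility_floor`` are removed.  Tracks whose intensity coefficient
    of variation exceeds ``intensity_cv_ceiling`` are removed.  Single-frame
    tracks have no displacement and are exempt from the mobility test; they
    are passed through flagged.
    """
    kept: list[Trajectory] = []
    n_immobile = n_intensity = n_exempt = 0
    for tr in ts.trajectories:
        mean_i = float(np.mean(tr.intensity))
        cv = float(np.std(tr.intensity) / mean_i) if mean_i > 0 else np.inf
        if cv > intensity_cv_ceiling:
            n_intensity += 1
            continue
        if tr.n_bound_frames == 1:
            n_exempt += 1
            kept.append(replace(tr, single_frame_qc_exempt=True))
            continue
        msd = float(np.mean(np.sum(np.diff(tr.positions, axis=0) ** 2, axis=1)))
        if msd < mobility_floor:
            n_immobile += 1
            continue
        kept.append(tr)
    report = QCReport(len(ts), n_immobile, n_intensity, n_exempt)
    return TrajectorySet(kept, ts.config, ts.truth), report
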