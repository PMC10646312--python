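"""Descriptive random-walk statistics of centroid trajectory ensembles.

All estimators operate on the *observed* velocity, the forward difference of
sampled positions at the fixed interval ``dt``; the acceleration is the
forward difference of that velocity.  Speed-conditioned statistics bin on
the current speed with left-closed bins of width ``dv`` (default 0.1 um/s).
Steps of exactly zero speed have no direction and are excluded from any
statistic that needs one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gle_model import Trajectory

__all__ = [
    "VelocitySeries",
    "velocities",
    "msd",
    "msd_exponent",
    "speed_distribution",
    "SpeedDistribution",
    "vac",
    "conditional_acceleration",
    "turning_cosine",
    "split_autocorrelations",
    "split_trajectory",
]

DEFAULT_DV = 0.1  # um/s, speed bin width


@dataclass(frozen=True)
class VelocitySeries:
    """Finite-difference velocity/acceleration series of one trajectory.

    ``v`` has one sample fewer than the positions, ``a`` one fewer than
    ``v``.  ``a_par``/``a_perp`` are the components of the acceleration
    parallel and orthogonal (2D scalar cross product) to the current
    velocity; they are NaN where the current speed is zero.
    """

    dt: float
    v: np.ndarray
    a: np.ndarray
    speed: np.ndarray
    a_par: np.ndarray
    a_perp: np.ndarray


def velocities(traj: Trajectory) -> VelocitySeries:
    """Forward-difference velocity and acceleration with the ``a_par/a_perp`` split."""
    if len(traj) < 3:
        raise ValueError("need >= 3 positions for velocity and acceleration")
    v = np.diff(traj.positions, axis=0) / traj.dt
    a = np.diff(v, axis=0) / traj.dt
    speed = np.linalg.norm(v, axis=1)
    sp = speed[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        a_par = (a[:, 0] * v[:-1, 0] + a[:, 1] * v[:-1, 1]) / sp
        a_perp = (v[:-1, 0] * a[:, 1] - v[:-1, 1] * a[:, 0]) / sp
    a_par[sp == 0] = np.nan
    a_perp[sp == 0] = np.nan
    return VelocitySeries(dt=traj.dt, v=v, a=a, speed=speed,
                          a_par=a_par, a_perp=a_perp)


def _check_shared_dt(items) -> float:
    dts = {round(float(x.dt), 12) for x in items}
    if len(dts) != 1:
        raise ValueError("all trajectories must share the sampling interval")
    return dts.pop()


def msd(trajs: list[Trajectory], max_lag_steps: int | None = None):
    """Ensemble-and-time averaged mean squared displacement.

    Averages the squared displacement over every valid (trajectory, start,
    start+m) pair.  Returns ``(lag_times, msd_values)`` with lag 0 included
    (msd(0) = 0).
    """
    dt = _check_shared_dt(trajs)
    if max_lag_steps is None:
        max_lag_steps = max(len(t) for t in trajs) - 1
    sums = np.zeros(max_lag_steps + 1)
    counts = np.zeros(max_lag_steps + 1, dtype=np.int64)
    for t in trajs:
        p = t.positions
        n = len(p)
        for m in range(1, min(max_lag_steps, n - 1) + 1):
            d = p[m:] - p[:-m]
            sums[m] += np.einsum("ij,ij->", d, d)
            counts[m] += n - m
    counts[0] = 1  # msd(0) = 0 by definition
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return np.arange(max_lag_steps + 1) * dt, out


def msd_exponent(lag_times: np.ndarray, msd_values: np.ndarray,
                 fit_window: tuple[float, float] = (10.0, 100.0)) -> float:
    """Log-log OLS slope of the MSD over ``fit_window`` (seconds)."""
    lag_times = np.asarray(lag_times, dtype=float)
    msd_values = np.asarray(msd_values, dtype=float)
    sel = ((lag_times >= fit_window[0]) & (lag_times <= fit_window[1])
           & (msd_values > 0))
    if sel.sum() < 2:
        raise ValueError("fit window contains fewer than 2 usable lags")
    slope, _ = np.polyfit(np.log(lag_times[sel]), np.log(msd_values[sel]), 1)
    return float(slope)


@dataclass(frozen=True)
class SpeedDistribution:
    """Normalized speed histogram plus the Rayleigh fit implied by isotropy.

    ``sigma_g`` is the zero-mean Gaussian SD fitted to the pooled x- and
    y-velocity components.  If the velocity is an isotropic 2D Gaussian the
    speed follows a Rayleigh density ``(v/sigma_g^2) exp(-v^2/(2 sigma_g^2))``
    with mode ``sigma_g`` and median ``sigma_g * sqrt(2 ln 2)``.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    dv: float
    sigma_g: float
    median_speed: float  # empirical median of |v|

    @property
    def rayleigh_median(self) -> float:
        return self.sigma_g * np.sqrt(2.0 * np.log(2.0))

    @property
    def rayleigh_mode(self) -> float:
        return self.sigma_g

    def rayleigh_density(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        s2 = self.sigma_g ** 2
        return v / s2 * np.exp(-v * v / (2.0 * s2))


def speed_distribution(vels: list[VelocitySeries],
                       dv: float = DEFAULT_DV) -> SpeedDistribution:
    """Histogram of |v| and the Rayleigh scale from the component Gaussian fit."""
    speeds = np.concatenate([vs.speed for vs in vels])
    comps = np.concatenate([vs.v.ravel() for vs in vels])
    if len(speeds) == 0:
        raise ValueError("no velocity samples")
    n_bins = int(np.floor(speeds.max() / dv)) + 1
    edges = np.arange(n_bins + 1) * dv
    counts, _ = np.histogram(speeds, bins=edges)
    density = counts / (counts.sum() * dv)
    sigma_g = float(np.sqrt(np.mean(comps ** 2)))  # zero-mean Gaussian MLE
    return SpeedDistribution(bin_edges=edges, density=density, counts=counts,
                             dv=dv, sigma_g=sigma_g,
                             median_speed=float(np.median(speeds)))


def vac(vels: list[VelocitySeries], max_lag_steps: int | None = None):
    """Ensemble-averaged velocity autocorrelation ``<v(t) . v(t+m dt)>``."""
    dt = _check_shared_dt(vels)
    if max_lag_steps is None:
        max_lag_steps = max(len(vs.v) for vs in vels) - 1
    sums = np.zeros(max_lag_steps + 1)
    counts = np.zeros(max_lag_steps + 1, dtype=np.int64)
    for vs in vels:
        v = vs.v
        n = len(v)
        for m in range(min(max_lag_steps, n - 1) + 1):
            sums[m] += np.einsum("ij,ij->", v[: n - m], v[m:])
            counts[m] += n - m
    with np.errstate(invalid="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return np.arange(max_lag_steps + 1) * dt, out


def _binned(speeds: np.ndarray, values: dict[str, np.ndarray],
            dv: float, min_count: int = 1) -> pd.DataFrame:
    """Group values by left-closed speed bins [v', v'+dv); empty bins omitted."""
    valid = np.isfinite(speeds)
    for arr in values.values():
        valid &= np.isfinite(arr)
    speeds = speeds[valid]
    idx = np.floor(speeds / dv).astype(int)
    df = pd.DataFrame({"bin": idx, **{k: v[valid] for k, v in values.items()}})
    rows = []
    for b, grp in df.groupby("bin"):
        if len(grp) < min_count:
            continue
        row = {"speed_bin": b * dv, "n": len(grp)}
        for k in values:
            row[f"{k}_mean"] = grp[k].mean()
            row[f"{k}_sd"] = grp[k].std(ddof=1) if len(grp) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def conditional_acceleration(vels: list[VelocitySeries],
                             dv: float = DEFAULT_DV) -> pd.DataFrame:
    """Mean and unbiased SD of a_par / a_perp per current-speed bin.

    Returns a frame with columns speed_bin, n, a_par_mean, a_par_sd,
    a_perp_mean, a_perp_sd.  Bins with no samples are absent (not zero);
    SDs need >= 2 samples and are NaN otherwise.
    """
    speeds = np.concatenate([vs.speed[:-1] for vs in vels])
    a_par = np.concatenate([vs.a_par for vs in vels])
    a_perp = np.concatenate([vs.a_perp for vs in vels])
    return _binned(speeds, {"a_par": a_par, "a_perp": a_perp}, dv)


def turning_cosine(vels: list[VelocitySeries],
                   dv: float = DEFAULT_DV) -> pd.DataFrame:
    """Mean cosine of the one-step direction change, binned by current speed."""
    speeds, cosines = [], []
    for vs in vels:
        v = vs.v
        n0 = np.linalg.norm(v[:-1], axis=1)
        n1 = np.linalg.norm(v[1:], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.einsum("ij,ij->i", v[:-1], v[1:]) / (n0 * n1)
        c[(n0 == 0) | (n1 == 0)] = np.nan
        speeds.append(n0)
        cosines.append(c)
    df = _binned(np.concatenate(speeds), {"cos_theta": np.concatenate(cosines)}, dv)
    return df.rename(columns={"cos_theta_mean": "cos_theta"})


def split_autocorrelations(vels: list[VelocitySeries],
                           max_lag_steps: int | None = None,
                           normalized: bool = False):
    """Separate autocorrelations of the speed magnitude and the orientation.

    The magnitude statistic is the raw centered product
    ``<(|v|(t) - <|v|>)(|v|(t+m) - <|v|>)>`` with the *global* ensemble mean
    subtracted, exactly as conventionally written for this analysis (it is a
    covariance, not scaled to 1 at lag 0); pass ``normalized=True`` to divide
    by the lag-0 value.  The orientation statistic is the mean inner product
    of unit velocity vectors (1 at lag 0 by construction); zero-speed steps
    are excluded.
    """
    dt = _check_shared_dt(vels)
    if max_lag_steps is None:
        max_lag_steps = max(len(vs.v) for vs in vels) - 1
    global_mean = np.mean(np.concatenate([vs.speed for vs in vels]))

    mag_sum = np.zeros(max_lag_steps + 1)
    mag_cnt = np.zeros(max_lag_steps + 1, dtype=np.int64)
    ori_sum = np.zeros(max_lag_steps + 1)
    ori_cnt = np.zeros(max_lag_steps + 1, dtype=np.int64)
    for vs in vels:
        s = vs.speed - global_mean
        n = len(s)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = vs.v / vs.speed[:, None]
        ok = vs.speed > 0
        for m in range(min(max_lag_steps, n - 1) + 1):
            mag_sum[m] += np.dot(s[: n - m], s[m:])
            mag_cnt[m] += n - m
            pair_ok = ok[: n - m] & ok[m:]
            ori_sum[m] += np.einsum("ij,ij->", u[: n - m][pair_ok],
                                    u[m:][pair_ok])
            ori_cnt[m] += pair_ok.sum()
    with np.errstate(invalid="ignore"):
        mag = mag_sum / mag_cnt
        ori = ori_sum / ori_cnt
    mag[mag_cnt == 0] = np.nan
    ori[ori_cnt == 0] = np.nan
    if normalized and mag[0] != 0:
        mag = mag / mag[0]
    return np.arange(max_lag_steps + 1) * dt, mag, ori


def split_trajectory(traj: Trajectory, window: float) -> list[Trajectory]:
    """Cut a trajectory into non-overlapping sub-trajectories of ``window`` seconds."""
    steps = int(round(window / traj.dt))
    if steps < 1:
        raise ValueError("window shorter than the sampling interval")
    out = []
    for start in range(0, len(traj) - steps, steps):
        sl = slice(start, start + steps + 1)
        out.append(Trajectory(times=traj.times[sl], positions=traj.positions[sl],
                              dt=traj.dt))
    return out
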