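"""Generalized Langevin model of amoeboid centroid motion.

The centroid velocity is modeled by a linear generalized Langevin equation
(GLE) with an exponential memory kernel,

    dv/dt = -beta * v + alpha * V + sigma * xi(t),
    dV/dt =  alpha * v - gamma * V,

where ``V`` is the exponentially weighted velocity history (memory variable),
``xi`` is a unit-intensity 2D Gaussian white noise, and all rates are
positive.  The pair (v, V) is a 2D Ornstein-Uhlenbeck process with symmetric
drift matrix ``C = [[beta, -alpha], [-alpha, gamma]]``, so the steady-state
velocity autocorrelation (VAC) is a sum of two exponentials with decay rates
``lambda_+ > lambda_- > 0`` (the eigenvalues of C) and weights
``phi_+, phi_-`` fixed by the eigenvectors and the noise strength.

Observation effects are modeled explicitly: positions are sampled at a finite
interval ``delta_t`` and may carry additive Gaussian positional noise of SD
``sigma_x``; both modify the VAC of the *observed* (finite-difference)
velocity, and the closed forms implemented here include these corrections, so
model parameters can be fitted directly to an empirical VAC curve.

The module exposes both a functional surface (:func:`simulate_gle`,
:func:`eigen_decompose`, :func:`analytic_vac`, :func:`fit_two_exponentials`,
:func:`fit_gle_to_vac`) and a statsmodels-flavoured model/results pair
(:class:`GLEModel` -> :class:`GLEResults`, :class:`ExponentialVACModel`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "GLEParams",
    "GLEEigen",
    "Trajectory",
    "VACExponentialFit",
    "GLEFitResult",
    "simulate_gle",
    "eigen_decompose",
    "analytic_vac",
    "fit_two_exponentials",
    "fit_gle_to_vac",
    "GLEModel",
    "GLEResults",
    "ExponentialVACModel",
]

#: Parameters fitted to the experimental VAC (with and without the
#: positional-noise correction).  Units: alpha, beta, gamma in 1/s,
#: sigma in um s^-3/2, sigma_x in um.
TABLE_GLE = None  # set below, after GLEParams is defined


@dataclass(frozen=True)
class GLEParams:
    """Parameter set of the generalized Langevin equation.

    Parameters
    ----------
    alpha : float
        Memory-coupling rate (1/s).
    beta : float
        Velocity decay rate (1/s).
    gamma : float
        Memory decay rate (1/s).
    sigma : float
        Noise strength (um * s^-3/2).
    sigma_x : float, optional
        SD of additive positional measurement noise (um); 0 disables it.
    """

    alpha: float
    beta: float
    gamma: float
    sigma: float
    sigma_x: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.alpha, self.beta, self.gamma, self.sigma, self.sigma_x)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("GLE parameters must be finite")
        if min(self.alpha, self.beta, self.gamma) <= 0 or self.sigma < 0:
            raise ValueError("alpha, beta, gamma must be > 0 and sigma >= 0")
        if self.beta * self.gamma <= self.alpha ** 2:
            raise ValueError("beta * gamma must exceed alpha^2: otherwise the "
                             "slow decay rate is nonpositive and the velocity "
                             "process has no stationary state")
        if self.sigma_x < 0:
            raise ValueError("sigma_x must be >= 0")

    def drift_matrix(self) -> np.ndarray:
        """The symmetric 2x2 drift matrix C of the (v, V) system."""
        return np.array([[self.beta, -self.alpha], [-self.alpha, self.gamma]])

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "sigma_x": self.sigma_x,
        }


@dataclass(frozen=True)
class GLEEigen:
    """Eigen-structure of the GLE drift matrix and the derived VAC weights.

    ``lambda_plus >= lambda_minus > 0`` are the VAC decay rates (1/s),
    ``phi_plus/phi_minus`` the corresponding weights (um^2/s^2) and
    ``theta_plus/theta_minus`` the eigenvector angles (rad).
    """

    lambda_plus: float
    lambda_minus: float
    phi_plus: float
    phi_minus: float
    theta_plus: float
    theta_minus: float

    @property
    def e_plus(self) -> np.ndarray:
        return np.array([math.cos(self.theta_plus), math.sin(self.theta_plus)])

    @property
    def e_minus(self) -> np.ndarray:
        return np.array([math.cos(self.theta_minus), math.sin(self.theta_minus)])

    @property
    def decay_times(self) -> tuple[float, float]:
        """(T1, T2) = (1/lambda_plus, 1/lambda_minus), fast first."""
        return 1.0 / self.lambda_plus, 1.0 / self.lambda_minus

    def continuous_vac(self, lag: np.ndarray) -> np.ndarray:
        """phi+ e^(-lambda+ |lag|) + phi- e^(-lambda- |lag|)."""
        lag = np.abs(np.asarray(lag, dtype=float))
        return (self.phi_plus * np.exp(-self.lambda_plus * lag)
                + self.phi_minus * np.exp(-self.lambda_minus * lag))


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled 2D centroid trajectory (times in s, positions in um)."""

    times: np.ndarray
    positions: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.positions) or len(self.times) < 2:
            raise ValueError("trajectory needs >= 2 matching time/position samples")
        steps = np.diff(self.times)
        if not np.allclose(steps, self.dt, rtol=1e-6, atol=1e-9):
            raise ValueError("trajectory sampling must be uniform")

    def __len__(self) -> int:
        return len(self.times)


# --- Table of fitted parameters used throughout examples/tests -------------
TABLE_GLE = GLEParams(alpha=0.0741, beta=0.116, gamma=0.0641, sigma=0.266)
TABLE_GLE_NOISY = GLEParams(alpha=0.0741, beta=0.116, gamma=0.0641,
                            sigma=0.266, sigma_x=0.155)


def eigen_decompose(params: GLEParams) -> GLEEigen:
    """Closed-form eigen-structure of the GLE and the VAC weights.

    Decay rates are ``lambda_+- = (beta + gamma +- D) / 2`` with
    ``D = sqrt((beta-gamma)^2 + 4 alpha^2)``; eigenvector angles satisfy
    ``tan(theta_+-) = (beta - gamma -+ D) / (2 alpha)``; the weights are

        phi_+- = 2 sigma^2 (e_x,+-^4 / (2 lambda_+-)
                            + e_x,+^2 e_x,-^2 / (lambda_+ + lambda_-)),

    with ``e_x,+-`` the x-components of the unit eigenvectors.  Independent
    of ``sigma_x`` (measurement noise does not alter the underlying process).
    """
    a, b, g, s = params.alpha, params.beta, params.gamma, params.sigma
    disc = math.sqrt((b - g) ** 2 + 4.0 * a * a)
    lam_p = 0.5 * (b + g + disc)
    lam_m = 0.5 * (b + g - disc)
    theta_p = math.atan2((b - g) - disc, 2.0 * a)
    theta_m = math.atan2((b - g) + disc, 2.0 * a)
    ex_p2 = math.cos(theta_p) ** 2
    ex_m2 = math.cos(theta_m) ** 2
    cross = ex_p2 * ex_m2 / (lam_p + lam_m)
    phi_p = 2.0 * s * s * (ex_p2 ** 2 / (2.0 * lam_p) + cross)
    phi_m = 2.0 * s * s * (ex_m2 ** 2 / (2.0 * lam_m) + cross)
    return GLEEigen(lambda_plus=lam_p, lambda_minus=lam_m,
                    phi_plus=phi_p, phi_minus=phi_m,
                    theta_plus=theta_p, theta_minus=theta_m)


def _sampled_component(lam: float, lags: np.ndarray, delta_t: float) -> np.ndarray:
    """VAC of the finite-difference velocity contributed by one exponential mode.

    For integer lag m >= 1 the double time-integral over the two sampling
    windows gives ``e^(-(m-1) lam dt) ((1 - e^(-lam dt)) / (lam dt))^2``;
    at m = 0 it gives ``2 (e^(-lam dt) - 1 + lam dt) / (lam dt)^2``.
    """
    x = lam * delta_t
    out = np.empty(len(lags), dtype=float)
    m0 = lags == 0
    out[m0] = 2.0 * (math.exp(-x) - 1.0 + x) / (x * x)
    m = lags[~m0].astype(float)
    out[~m0] = np.exp(-(m - 1.0) * x) * ((1.0 - math.exp(-x)) / x) ** 2
    return out


def analytic_vac(params: GLEParams, delta_t: float = 1.0,
                 max_lag_steps: int = 100) -> np.ndarray:
    """Steady-state VAC of the observed (sampled, finite-difference) velocity.

    Returns ``vac_ss(m * delta_t)`` for ``m = 0 .. max_lag_steps``.  When
    ``params.sigma_x > 0`` the positional-noise correction is applied:
    ``+2 sigma_x^2 / delta_t^2`` at lag 0 and ``-sigma_x^2 / delta_t^2`` at
    lag 1; lags >= 2 are unchanged.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if max_lag_steps < 0:
        raise ValueError("max_lag_steps must be >= 0")
    eig = eigen_decompose(params)
    lags = np.arange(max_lag_steps + 1)
    vac = (eig.phi_plus * _sampled_component(eig.lambda_plus, lags, delta_t)
           + eig.phi_minus * _sampled_component(eig.lambda_minus, lags, delta_t))
    if params.sigma_x > 0:
        corr = params.sigma_x ** 2 / delta_t ** 2
        vac[0] += 2.0 * corr
        if max_lag_steps >= 1:
            vac[1] -= corr
    return vac


def simulate_gle(params: GLEParams, n_traj: int, duration: float,
                 dt_internal: float = 0.002, sample_interval: float = 1.0,
                 seed: int | None = None,
                 burn_in: float | None = None) -> list[Trajectory]:
    """Simulate GLE trajectories by Euler-Maruyama integration.

    The (v, V) system is integrated at ``dt_internal`` (default 2 ms), the
    position accumulated as the time integral of v, and positions recorded
    every ``sample_interval``.  I.i.d. Gaussian positional noise of SD
    ``params.sigma_x`` is added to each recorded position.  A burn-in of
    ``10 / lambda_minus`` (overridable) from (v, V) = (0, 0) is discarded so
    recorded statistics are stationary.

    Same seed => bit-identical output.
    """
    if duration <= 0 or dt_internal <= 0 or sample_interval <= 0:
        raise ValueError("duration and time steps must be positive")
    if dt_internal > sample_interval:
        raise ValueError("dt_internal must not exceed sample_interval")
    if duration < sample_interval:
        raise ValueError("duration must cover at least one sample interval")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")

    a, b, g, s = params.alpha, params.beta, params.gamma, params.sigma
    if burn_in is None:
        burn_in = 10.0 / eigen_decompose(params).lambda_minus
    rng = np.random.default_rng(seed)
    dt = dt_internal
    sq = s * math.sqrt(dt)
    steps_per_sample = int(round(sample_interval / dt))
    n_samples = int(round(duration / sample_interval))
    n_burn = int(math.ceil(burn_in / dt))

    v = np.zeros((n_traj, 2))
    V = np.zeros((n_traj, 2))
    for _ in range(n_burn):
        xi = rng.standard_normal((n_traj, 2))
        v, V = (v + (-b * v + a * V) * dt + sq * xi,
                V + (a * v - g * V) * dt)

    r = np.zeros((n_traj, 2))
    pos = np.empty((n_samples + 1, n_traj, 2))
    pos[0] = r
    for m in range(n_samples):
        for _ in range(steps_per_sample):
            xi = rng.standard_normal((n_traj, 2))
            v, V = (v + (-b * v + a * V) * dt + sq * xi,
                    V + (a * v - g * V) * dt)
            r = r + v * dt
        pos[m + 1] = r
    if params.sigma_x > 0:
        # total 2D noise variance sigma_x^2 (per-component SD sigma_x/sqrt(2)),
        # the convention under which the lag-0/1 VAC corrections of
        # analytic_vac hold exactly for the vector dot-product VAC
        pos = pos + params.sigma_x / math.sqrt(2.0) * rng.standard_normal(pos.shape)

    times = np.arange(n_samples + 1) * sample_interval
    return [Trajectory(times=times, positions=pos[:, i, :], dt=sample_interval)
            for i in range(n_traj)]


# ---------------------------------------------------------------------------
# Exponential-mixture fit of a VAC curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VACExponentialFit:
    """Least-squares fit of ``sum_j Phi_j exp(-tau / T_j)`` to a VAC curve.

    ``decay_times`` are sorted ascending (fast component first); ``bic`` is
    the Gaussian-error Bayesian information criterion
    ``N ln(RSS/N) + k ln N`` with ``k = 2 * n_components``.
    """

    weights: tuple
    decay_times: tuple
    rss: float
    bic: float
    n_obs: int
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.weights)

    # Two-component convenience accessors (Phi1/T1 fast, Phi2/T2 slow)
    @property
    def Phi1(self) -> float:
        return self.weights[0]

    @property
    def Phi2(self) -> float:
        return self.weights[1]

    @property
    def T1(self) -> float:
        return self.decay_times[0]

    @property
    def T2(self) -> float:
        return self.decay_times[1]

    def predict(self, lags: np.ndarray) -> np.ndarray:
        lags = np.asarray(lags, dtype=float)
        return sum(w * np.exp(-lags / T)
                   for w, T in zip(self.weights, self.decay_times))


def _profile_amplitudes(rates: np.ndarray, lags: np.ndarray,
                        values: np.ndarray) -> tuple[np.ndarray, float]:
    """Nonnegative least-squares amplitudes for fixed decay rates."""
    rates = np.clip(rates, 1e-12, 1e12)  # avoid 0*inf at lag 0
    X = np.exp(-np.outer(lags, rates))
    amps, _ = optimize.nnls(X, values)
    resid = values - X @ amps
    return amps, float(resid @ resid)


def fit_two_exponentials(lags: np.ndarray, vac: np.ndarray,
                         n_components: int = 2) -> VACExponentialFit:
    """Fit a sum of 1-3 exponentials to a VAC curve by multi-start least squares.

    Amplitudes are profiled out linearly (nonnegative) for each candidate set
    of decay rates; the rates start from a log-spaced grid and are refined by
    a local optimizer.  Non-convergence of every start is flagged on the
    result rather than raised.
    """
    lags = np.asarray(lags, dtype=float)
    vac = np.asarray(vac, dtype=float)
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    if len(lags) < 2 * n_components + 1:
        raise ValueError("need at least 2*n_components + 1 lags")
    positive = lags[lags > 0]
    if len(positive) == 0:
        raise ValueError("need positive lags to constrain decay times")
    lo, hi = positive.min() / 5.0, positive.max() * 5.0
    grid = np.geomspace(lo, hi, 8)

    def objective(log_rates: np.ndarray) -> float:
        _, rss = _profile_amplitudes(np.exp(log_rates), lags, vac)
        return rss

    best = None
    converged = False
    from itertools import combinations
    starts = list(combinations(1.0 / grid, n_components))
    for start in starts:
        x0 = np.log(np.asarray(start))
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    rates = np.exp(best.x)
    amps, rss = _profile_amplitudes(rates, lags, vac)
    order = np.argsort(1.0 / rates)  # ascending decay time
    times = tuple((1.0 / rates)[order])
    weights = tuple(amps[order])
    n = len(lags)
    k = 2 * n_components
    # Floor the RSS at the squared solver tolerance of the data scale so the
    # BIC stays finite and the parameter penalty decides between nested models
    # that both fit a noiseless curve to within optimizer precision.
    floor = n * (1e-8 * max(1.0, float(np.abs(vac).max()))) ** 2
    bic = n * math.log(max(rss, floor) / n) + k * math.log(n)
    return VACExponentialFit(weights=weights, decay_times=times, rss=rss,
                             bic=bic, n_obs=n, converged=converged)


# ---------------------------------------------------------------------------
# GLE parameter fit to a VAC curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLEFitResult:
    params: GLEParams
    eigen: GLEEigen
    mse: float
    n_obs: int
    converged: bool


def _params_from_modes(lam_p: float, lam_m: float, phi_p: float,
                       phi_m: float, sigma_x: float = 0.0) -> GLEParams:
    """Invert (lambda+-, phi+-) to (alpha, beta, gamma, sigma).

    Writing p = e_x,+^2 (so e_x,-^2 = 1 - p), the weight ratio
    phi+/phi- fixes p by a monotone 1D root; then
    sigma^2 = phi+ / (2 g+(p)), beta = lam+ p + lam- (1-p),
    gamma = lam+ + lam- - beta, alpha = (lam+ - lam-) sqrt(p (1-p)).
    """
    lam_sum = lam_p + lam_m

    def g_plus(p):
        return p * p / (2.0 * lam_p) + p * (1.0 - p) / lam_sum

    def g_minus(p):
        q = 1.0 - p
        return q * q / (2.0 * lam_m) + p * q / lam_sum

    eps = 1e-9
    if phi_p <= 0:
        p = eps
    elif phi_m <= 0:
        p = 1.0 - eps
    else:
        f = lambda p: phi_p * g_minus(p) - phi_m * g_plus(p)
        try:
            p = optimize.brentq(f, eps, 1.0 - eps)
        except ValueError:  # no sign change at numerical extremes
            grid = np.linspace(eps, 1.0 - eps, 2001)
            p = float(grid[np.argmin(np.abs([f(x) for x in grid]))])
    p = min(max(p, eps), 1.0 - eps)
    sigma2 = (phi_p / (2.0 * g_plus(p)) if phi_p > 0
              else phi_m / (2.0 * g_minus(p)))
    beta = lam_p * p + lam_m * (1.0 - p)
    gamma = lam_sum - beta
    alpha = (lam_p - lam_m) * math.sqrt(p * (1.0 - p))
    alpha = max(alpha, 1e-12)
    return GLEParams(alpha=alpha, beta=beta, gamma=gamma,
                     sigma=math.sqrt(max(sigma2, 0.0)), sigma_x=sigma_x)


def fit_gle_to_vac(lags: np.ndarray, vac: np.ndarray, delta_t: float = 1.0,
                   tau_min: float = 2.0,
                   with_positional_noise: bool = False) -> GLEFitResult:
    """Fit GLE parameters by least squares on the analytic sampled VAC.

    Only lags ``>= tau_min`` enter the objective (the field practice is
    ``tau_min = 2 s`` when ignoring measurement noise, 0 when co-fitting
    ``sigma_x``).  For fixed decay rates the model is linear in
    (phi+, phi-, sigma_x^2), which are profiled out by nonnegative least
    squares over a (lambda+, lambda-) grid with local refinement; a final
    bounded polish runs in the native (alpha, beta, gamma, sigma[, sigma_x])
    space.  Deterministic for a given input.
    """
    lags = np.asarray(lags, dtype=float)
    vac = np.asarray(vac, dtype=float)
    keep = lags >= tau_min - 1e-12
    lags_f = lags[keep]
    vac_f = vac[keep]
    if len(lags_f) < (5 if with_positional_noise else 4):
        raise ValueError("not enough lags above tau_min for a GLE fit")
    if np.allclose(vac_f, vac_f[0]) or vac_f.max() <= 0:
        raise ValueError("degenerate VAC curve (constant or nonpositive)")
    steps = np.rint(lags_f / delta_t).astype(int)
    if not np.allclose(steps * delta_t, lags_f, atol=1e-9 + 1e-6 * delta_t):
        raise ValueError("lags must be integer multiples of delta_t")

    noise_basis = None
    if with_positional_noise:
        nb = np.zeros(len(steps))
        nb[steps == 0] = 2.0 / delta_t ** 2
        nb[steps == 1] = -1.0 / delta_t ** 2
        noise_basis = nb

    def design(lam_p, lam_m):
        cols = [_sampled_component(lam_p, steps, delta_t),
                _sampled_component(lam_m, steps, delta_t)]
        if noise_basis is not None:
            cols.append(noise_basis)
        return np.column_stack(cols)

    def profiled_rss(log_lams):
        lam_p, lam_m = np.clip(np.exp(log_lams), 1e-8, 1e4)
        if lam_p <= lam_m:
            lam_p, lam_m = lam_m, lam_p
        X = design(lam_p, lam_m)
        amps, _ = optimize.nnls(X, vac_f)
        resid = vac_f - X @ amps
        return float(resid @ resid), (lam_p, lam_m, amps)

    grid = np.geomspace(1.0 / (5.0 * max(lags_f.max(), delta_t)),
                        2.0 / delta_t, 12)
    best_rss, best_state = np.inf, None
    for i, lm in enumerate(grid):
        for lp in grid[i + 1:]:
            rss, state = profiled_rss(np.log([lp, lm]))
            if rss < best_rss:
                best_rss, best_state = rss, state

    res = optimize.minimize(lambda x: profiled_rss(x)[0],
                            np.log([best_state[0], best_state[1]]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-18,
                                     "maxiter": 4000})
    rss, (lam_p, lam_m, amps) = profiled_rss(res.x)
    sigma_x = math.sqrt(max(amps[2], 0.0)) if with_positional_noise else 0.0
    params = _params_from_modes(lam_p, lam_m, amps[0], amps[1], sigma_x)

    # Final polish in native parameter space (log-transform keeps positivity).
    def native_resid(z):
        a, b, g, s = np.exp(z[:4])
        sx = math.sqrt(np.exp(z[4])) if with_positional_noise else 0.0
        try:
            p = GLEParams(a, b, g, s, sx)
        except ValueError:
            return np.full(len(vac_f), 1e6)
        curve = analytic_vac(p, delta_t, int(steps.max()))
        return curve[steps] - vac_f

    z0 = np.log([max(params.alpha, 1e-8), params.beta, params.gamma,
                 max(params.sigma, 1e-8)])
    if with_positional_noise:
        z0 = np.append(z0, math.log(max(params.sigma_x ** 2, 1e-12)))
    ls = optimize.least_squares(native_resid, z0, method="lm",
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if float(ls.cost) * 2.0 <= rss:
        a, b, g, s = np.exp(ls.x[:4])
        sx = math.sqrt(math.exp(ls.x[4])) if with_positional_noise else 0.0
        params = GLEParams(a, b, g, s, sx)
        rss = float(ls.cost) * 2.0
    return GLEFitResult(params=params, eigen=eigen_decompose(params),
                        mse=rss / len(vac_f), n_obs=len(vac_f),
                        converged=True)


# ---------------------------------------------------------------------------
# Model / results interface
# ---------------------------------------------------------------------------

class GLEModel:
    """GLE fitted to an empirical velocity-autocorrelation curve.

    Parameters
    ----------
    vac : array-like
        VAC values at lags ``0, delta_t, 2*delta_t, ...`` (um^2/s^2), or at
        the explicit ``lags`` given.
    delta_t : float
        Sampling interval of the underlying trajectories (s).
    lags : array-like, optional
        Lag times in seconds; defaults to ``arange(len(vac)) * delta_t``.
    tau_min : float
        Smallest lag entering the objective (s).
    positional_noise : bool
        Co-fit the positional measurement noise sigma_x (then typically
        ``tau_min = 0``).
    """

    def __init__(self, vac, delta_t: float = 1.0, lags=None,
                 tau_min: float = 2.0, positional_noise: bool = False):
        self.endog = np.asarray(vac, dtype=float)
        self.delta_t = float(delta_t)
        self.lags = (np.arange(len(self.endog)) * self.delta_t
                     if lags is None else np.asarray(lags, dtype=float))
        self.tau_min = float(tau_min)
        self.positional_noise = bool(positional_noise)

    def fit(self) -> "GLEResults":
        fr = fit_gle_to_vac(self.lags, self.endog, delta_t=self.delta_t,
                            tau_min=self.tau_min,
                            with_positional_noise=self.positional_noise)
        return GLEResults(self, fr)


@dataclass
class GLEResults:
    """Fit results: parameter estimates, eigen-structure and diagnostics."""

    model: GLEModel
    fit_result: GLEFitResult
    params: GLEParams = field(init=False)
    eigen: GLEEigen = field(init=False)

    def __post_init__(self) -> None:
        self.params = self.fit_result.params
        self.eigen = self.fit_result.eigen

    @property
    def mse(self) -> float:
        return self.fit_result.mse

    def predict(self, max_lag_steps: int | None = None) -> np.ndarray:
        if max_lag_steps is None:
            max_lag_steps = int(round(self.model.lags.max() / self.model.delta_t))
        return analytic_vac(self.params, self.model.delta_t, max_lag_steps)

    def simulate(self, n_traj: int, duration: float, seed: int | None = None,
                 dt_internal: float = 0.002,
                 sample_interval: float | None = None) -> list[Trajectory]:
        if sample_interval is None:
            sample_interval = self.model.delta_t
        return simulate_gle(self.params, n_traj, duration,
                            dt_internal=dt_internal,
                            sample_interval=sample_interval, seed=seed)

    def summary(self) -> str:
        p, e = self.params, self.eigen
        lines = [
            "Generalized Langevin equation fit (VAC least squares)",
            "=" * 56,
            f"  n lags used          {self.fit_result.n_obs:10d}",
            f"  MSE                  {self.mse:10.3e}  (um^2/s^2)^2",
            f"  positional noise     {'yes' if self.model.positional_noise else 'no'}",
            "-" * 56,
            f"  alpha   {p.alpha:10.4g} 1/s     beta    {p.beta:10.4g} 1/s",
            f"  gamma   {p.gamma:10.4g} 1/s     sigma   {p.sigma:10.4g} um s^-3/2",
            f"  sigma_x {p.sigma_x:10.4g} um",
            "-" * 56,
            f"  T1 = 1/lambda+ {e.decay_times[0]:8.3g} s   "
            f"T2 = 1/lambda- {e.decay_times[1]:8.3g} s",
            f"  phi+ {e.phi_plus:8.3g} um^2/s^2       "
            f"phi- {e.phi_minus:8.3g} um^2/s^2",
            "=" * 56,
        ]
        return "\n".join(lines)


class ExponentialVACModel:
    """Sum-of-exponentials VAC model; ``fit()`` returns a VACExponentialFit."""

    def __init__(self, vac, lags=None, delta_t: float = 1.0,
                 n_components: int = 2):
        self.endog = np.asarray(vac, dtype=float)
        self.lags = (np.arange(len(self.endog)) * float(delta_t)
                     if lags is None else np.asarray(lags, dtype=float))
        self.n_components = int(n_components)

    def fit(self) -> VACExponentialFit:
        return fit_two_exponentials(self.lags, self.endog, self.n_components)
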