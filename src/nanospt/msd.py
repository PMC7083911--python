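"""Mean-square displacement, diffusion fitting and hydrodynamic sizing.

The sizing chain is: time-averaged MSD -> linear fit MSD = 4*D*lag over a
bounded lag window -> Stokes-Einstein radius R = k_B*T/(6*pi*eta*D) ->
anisotropy-corrected hydrodynamic radius R_hydro = A*R.  For thin
disc-like sheets diffusing in a viscous medium the sphere-equivalent
radius underestimates the lateral extent; the multiplicative correction
A (default 1.49, from a spheroid hydrodynamic model) converts it into a
hydrodynamic radius comparable with the sheet diameter scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthdata import K_BOLTZMANN
from .tracking import Trajectory, trajectory_max_mass

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "HydroResult",
    "SizeBrightnessTable",
    "compute_msd",
    "fit_diffusion",
    "glycerol_viscosity",
    "stokes_radius",
    "oblate_friction_ratio",
    "size_brightness_correlation",
]

logger = logging.getLogger(__name__)

DEFAULT_A_CORRECTION = 1.49
DEFAULT_MAX_LAG_S = 25.0


@dataclass
class MSDCurve:
    """Lag-resolved mean-square displacement of one trajectory."""

    lag_s: np.ndarray
    msd_um2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.lag_s) > 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd_um2 < 0):
            raise ValueError("MSD values must be nonnegative")


@dataclass
class DiffusionFit:
    D_um2_s: float
    intercept_um2: float
    max_lag_s: float
    r_squared: float
    degenerate: bool = False  # set when the raw fit gave D <= 0 (clipped)


@dataclass
class HydroResult:
    R_stokes_nm: float
    A_correction: float
    R_hydro_nm: float
    T_K: float
    eta_Pa_s: float


@dataclass
class SizeBrightnessTable:
    """Per-particle hydrodynamic size and brightness, plus power-law fit."""

    particle_id: np.ndarray
    D_um2_s: np.ndarray
    R_stokes_nm: np.ndarray
    R_hydro_nm: np.ndarray
    max_mass: np.ndarray
    n_points: np.ndarray
    prefactor: float
    exponent: float
    exponent_ci: tuple[float, float]
    n_excluded: int


def compute_msd(
    traj: Trajectory,
    max_lag_s: float | None = None,
    estimator: str = "time_averaged",
) -> MSDCurve:
    """Mean-square displacement of one uniformly sampled trajectory.

    ``time_averaged`` (default) averages squared displacements over all
    overlapping start points at every integer lag up to ``max_lag_s``,
    giving the full MSD curve used for diffusion fitting.  ``single_step``
    averages only consecutive single-step displacements and returns one
    value at lag = frame interval.
    """
    if len(traj) < 2:
        raise ValueError("trajectory must contain at least 2 points")
    dt = traj.frame_interval_s  # raises on non-uniform sampling
    x, y = traj.x_um, traj.y_um
    n = len(traj)

    if estimator == "single_step":
        sq = np.diff(x) ** 2 + np.diff(y) ** 2
        return MSDCurve(
            lag_s=np.array([dt]),
            msd_um2=np.array([sq.mean()]),
            n_pairs=np.array([n - 1]),
        )
    if estimator != "time_averaged":
        raise ValueError(f"unknown estimator {estimator!r}")

    if max_lag_s is None:
        max_lag = n - 1
    else:
        max_lag = min(int(np.floor(max_lag_s / dt + 1e-9)), n - 1)
    if max_lag < 1:
        raise ValueError("max_lag_s shorter than one frame interval")
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(max_lag)
    npairs = np.empty(max_lag, dtype=int)
    for k in lags:
        dxk = x[k:] - x[:-k]
        dyk = y[k:] - y[:-k]
        msd[k - 1] = np.mean(dxk**2 + dyk**2)
        npairs[k - 1] = n - k
    return MSDCurve(lag_s=lags * dt, msd_um2=msd, n_pairs=npairs)


def fit_diffusion(
    msd: MSDCurve,
    max_lag_s: float = DEFAULT_MAX_LAG_S,
    with_intercept: bool = False,
) -> DiffusionFit:
    """Weighted least-squares fit of MSD = 4*D*lag (+ optional intercept).

    Weights are the pair counts at each lag.  The fit uses only lags up
    to ``max_lag_s``.  The optional intercept absorbs the static
    localization-noise offset (4*sigma_loc^2); by default the line is
    forced through the origin.  A negative fitted D is clipped to 0 and
    flagged degenerate.
    """
    sel = msd.lag_s <= max_lag_s + 1e-12
    lag = msd.lag_s[sel]
    y = msd.msd_um2[sel]
    w = msd.n_pairs[sel].astype(float)
    if len(lag) < (2 if with_intercept else 1):
        raise ValueError("not enough lags inside the fit window")

    if with_intercept:
        X = np.column_stack([4.0 * lag, np.ones_like(lag)])
        wsq = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * wsq[:, None], y * wsq, rcond=None)
        d, intercept = float(coef[0]), float(coef[1])
        yhat = X @ coef
    else:
        d = float(np.sum(w * lag * y) / (4.0 * np.sum(w * lag**2)))
        intercept = 0.0
        yhat = 4.0 * d * lag
    ybar = np.average(y, weights=w)
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    degenerate = d <= 0 or np.all(y == 0)
    return DiffusionFit(
        D_um2_s=max(d, 0.0),
        intercept_um2=intercept,
        max_lag_s=max_lag_s,
        r_squared=r2,
        degenerate=bool(degenerate),
    )


def glycerol_viscosity(T_K: float, glycerol_mass_fraction: float = 1.0) -> float:
    """Dynamic viscosity of a glycerol-water mixture, in Pa*s.

    Implements the Cheng (2008) exponent-mixing correlation, valid for
    0-100 C and the full composition range: the mixture viscosity is
    mu_w**alpha * mu_g**(1-alpha) with a composition- and temperature-
    dependent weighting alpha.  Pure-water and pure-glycerol limits match
    standard tables to a few percent.
    """
    if not (273.0 < T_K < 373.0):
        raise ValueError("temperature must be within (273, 373) K")
    c = glycerol_mass_fraction
    if not (0.0 <= c <= 1.0):
        raise ValueError("glycerol_mass_fraction must be in [0, 1]")
    t = T_K - 273.15  # Celsius
    mu_w = 1.790 * np.exp((-1230.0 - t) * t / (36100.0 + 360.0 * t))  # mPa*s
    mu_g = 12100.0 * np.exp((-1233.0 + t) * t / (9900.0 + 70.0 * t))  # mPa*s
    a = 0.705 - 0.0017 * t
    b = (4.9 + 0.036 * t) * a**2.5
    alpha = 1.0 - c + (a * b * c * (1.0 - c)) / (a * c + b * (1.0 - c))
    mu = mu_w**alpha * mu_g ** (1.0 - alpha)
    return float(mu) * 1e-3


def stokes_radius(
    D_um2_s: float,
    T_K: float,
    eta_Pa_s: float,
    A_correction: float = DEFAULT_A_CORRECTION,
) -> HydroResult:
    """Stokes-Einstein radius and anisotropy-corrected hydrodynamic radius.

    R_stokes = k_B*T / (6*pi*eta*D); R_hydro = A * R_stokes.
    """
    if D_um2_s <= 0:
        raise ValueError("D must be > 0")
    if T_K <= 0 or eta_Pa_s <= 0:
        raise ValueError("temperature and viscosity must be > 0")
    d_m2_s = D_um2_s * 1e-12
    r_m = K_BOLTZMANN * T_K / (6.0 * np.pi * eta_Pa_s * d_m2_s)
    r_nm = r_m * 1e9
    return HydroResult(
        R_stokes_nm=r_nm,
        A_correction=A_correction,
        R_hydro_nm=A_correction * r_nm,
        T_K=T_K,
        eta_Pa_s=eta_Pa_s,
    )


def oblate_friction_ratio(aspect_ratio: float) -> float:
    """Perrin orientation-averaged friction of an oblate spheroid.

    Ratio of the translational friction of an oblate spheroid (polar/
    equatorial semi-axis ratio p = c/a < 1) to that of the sphere with the
    same volume.  Exploratory helper for reasoning about disc-like
    particles; the default sizing correction A = 1.49 is an independent
    constant and is NOT derived from this formula.
    """
    p = aspect_ratio
    if not (0 < p < 1):
        raise ValueError("aspect_ratio must be in (0, 1) for an oblate spheroid")
    xi = np.sqrt(1.0 - p**2)
    # Perrin S-factor for an oblate spheroid, normalized by equal-volume sphere
    s = 2.0 * np.arctan(xi / p) / xi  # times 1/a
    f_ratio = 2.0 * p ** (-1.0 / 3.0) / s
    return float(f_ratio)


def size_brightness_correlation(
    trajs: list[Trajectory],
    T_K: float,
    eta_Pa_s: float,
    A_correction: float = DEFAULT_A_CORRECTION,
    fit_max_lag_s: float = DEFAULT_MAX_LAG_S,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> SizeBrightnessTable:
    """Correlate per-particle brightness with hydrodynamic size.

    For every trajectory the maximum blob mass and the corrected
    hydrodynamic radius are computed; a power law
    mass = prefactor * (2*R_hydro)**exponent is fitted by least squares
    in log-log space, with a seeded bootstrap (over particles) confidence
    interval on the exponent.  Trajectories whose diffusion fit is
    degenerate (D <= 0) are excluded with a logged reason.
    """
    if len(trajs) < 3:
        raise ValueError("need at least 3 trajectories")
    rows = []
    n_excluded = 0
    for traj in trajs:
        msd = compute_msd(traj, max_lag_s=fit_max_lag_s)
        fit = fit_diffusion(msd, max_lag_s=fit_max_lag_s)
        if fit.degenerate:
            logger.info(
                "particle %s excluded: degenerate diffusion fit (D=%g)",
                traj.particle_id,
                fit.D_um2_s,
            )
            n_excluded += 1
            continue
        hydro = stokes_radius(fit.D_um2_s, T_K, eta_Pa_s, A_correction)
        rows.append(
            (
                traj.particle_id,
                fit.D_um2_s,
                hydro.R_stokes_nm,
                hydro.R_hydro_nm,
                trajectory_max_mass(traj),
                len(traj),
            )
        )
    if len(rows) < 3:
        raise ValueError("fewer than 3 trajectories with a valid size")
    pid, d, r_st, r_hy, mass, npts = (np.asarray(c) for c in zip(*rows))

    log_d = np.log(2.0 * r_hy)  # hydrodynamic diameter on the size axis
    log_m = np.log(mass)
    exponent, log_pref = np.polyfit(log_d, log_m, 1)

    rng = np.random.default_rng(seed)
    n = len(log_d)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if np.ptp(log_d[idx]) == 0:
            boot[b] = np.nan
            continue
        boot[b] = np.polyfit(log_d[idx], log_m[idx], 1)[0]
    ci = tuple(np.nanpercentile(boot, [2.5, 97.5]))
    return SizeBrightnessTable(
        particle_id=pid,
        D_um2_s=d.astype(float),
        R_stokes_nm=r_st.astype(float),
        R_hydro_nm=r_hy.astype(float),
        max_mass=mass.astype(float),
        n_points=npts.astype(int),
        prefactor=float(np.exp(log_pref)),
        exponent=float(exponent),
        exponent_ci=(float(ci[0]), float(ci[1])),
        n_excluded=n_excluded,
    )


def spearman_size_truth(recovered_nm: np.ndarray, true_nm: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation between recovered and true sizes."""
    rho, p = stats.spearmanr(recovered_nm, true_nm)
    return float(rho), float(p)
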