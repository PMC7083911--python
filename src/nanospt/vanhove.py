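"""In-vivo microrheology: velocities, proximity partitioning, Van Hove analysis.

The self part of the Van Hove function is the probability distribution of
particle displacements at a fixed lag time.  Purely thermal (Brownian)
motion gives a Gaussian of variance 2*D*tau per axis; active processes
(flows, motor-driven contractions) add rare large displacements that show
up as heavy tails exceeding the Gaussian fitted to the small-displacement
core.  Trajectories can additionally be partitioned by the distance of
each point to the nearest nucleus boundary, to compare the local
environment near and far from nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit
from shapely.geometry import Point

from .synthdata import NucleusMap
from .tracking import Trajectory

__all__ = [
    "DisplacementSet",
    "VanHoveResult",
    "ProximityComparison",
    "instantaneous_velocity",
    "distance_to_nuclei",
    "pooled_displacements",
    "compute_van_hove",
    "partition_by_proximity",
]

DEFAULT_LAG_S = 0.1
DEFAULT_BIN_WIDTH_UM = 0.005
DEFAULT_GAUSS_WINDOW_UM = 0.03


@dataclass
class DisplacementSet:
    """Pooled per-axis displacements at one lag, with proximity labels."""

    lag_s: float
    displacements_um: np.ndarray
    proximity_um: np.ndarray | None = None  # start-point distance to nucleus border
    group: str = "all"  # near / far / all

    def __post_init__(self) -> None:
        self.displacements_um = np.asarray(self.displacements_um, dtype=float)
        if not np.all(np.isfinite(self.displacements_um)):
            raise ValueError("displacements must be finite")
        if self.proximity_um is not None:
            self.proximity_um = np.asarray(self.proximity_um, dtype=float)
            if np.any(self.proximity_um < 0):
                raise ValueError("proximity distances must be >= 0")

    def __len__(self) -> int:
        return len(self.displacements_um)


@dataclass
class VanHoveResult:
    """Displacement histogram with Gaussian-core fit and tail metrics."""

    bin_edges_um: np.ndarray
    probability: np.ndarray
    gaussian_amplitude: float
    gaussian_sigma_um: float
    window_um: float
    tail_excess: float
    tail_excess_se: float
    excess_kurtosis: float
    active_processes_detected: bool
    n_displacements: int

    def __post_init__(self) -> None:
        if abs(self.probability.sum() - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must sum to 1")
        if self.gaussian_sigma_um <= 0:
            raise ValueError("fitted sigma must be > 0")


@dataclass
class ProximityComparison:
    near: VanHoveResult | None
    far: VanHoveResult | None
    threshold_um: float
    rank_sum_statistic: float | None
    rank_sum_p: float | None
    variance_ratio: float | None  # var(near) / var(far)
    underpowered: bool
    n_near: int
    n_far: int


def _lag_frames(traj: Trajectory, lag_s: float) -> int:
    dt = traj.frame_interval_s
    k = lag_s / dt
    if abs(k - round(k)) > 1e-6:
        raise ValueError(
            f"lag {lag_s} s is not an integer multiple of the frame interval {dt} s"
        )
    k = int(round(k))
    if k < 1:
        raise ValueError("lag must be at least one frame interval")
    return k


def instantaneous_velocity(traj: Trajectory, lag_s: float = DEFAULT_LAG_S) -> np.ndarray:
    """Per-point speeds |r(t + lag) - r(t)| / lag, in um/s."""
    k = _lag_frames(traj, lag_s)
    if len(traj) <= k:
        raise ValueError("trajectory too short for the requested lag")
    dx = traj.x_um[k:] - traj.x_um[:-k]
    dy = traj.y_um[k:] - traj.y_um[:-k]
    return np.sqrt(dx**2 + dy**2) / lag_s


def distance_to_nuclei(point: tuple[float, float], nucleus_map: NucleusMap) -> float:
    """Minimum Euclidean distance from a point to any nucleus boundary.

    The distance is to the border (polygon exterior ring), unsigned:
    a point inside a nucleus gets its distance to the ring, not zero.
    """
    if not nucleus_map.polygons:
        raise ValueError("nucleus map is empty")
    p = Point(point)
    return float(min(poly.exterior.distance(p) for poly in nucleus_map.shapely_polygons()))


def pooled_displacements(
    trajs: list[Trajectory],
    lag_s: float = DEFAULT_LAG_S,
    nucleus_map: NucleusMap | None = None,
) -> DisplacementSet:
    """Pool per-axis (x and y) displacements at one lag across trajectories.

    If a nucleus map is given, each displacement carries the distance of
    its starting point to the nearest nucleus border (the same value for
    the x- and the y-component of one step).
    """
    disp: list[np.ndarray] = []
    prox: list[np.ndarray] = []
    for traj in trajs:
        try:
            k = _lag_frames(traj, lag_s)
        except ValueError:
            raise
        if len(traj) <= k:
            continue
        dx = traj.x_um[k:] - traj.x_um[:-k]
        dy = traj.y_um[k:] - traj.y_um[:-k]
        disp.append(dx)
        disp.append(dy)
        if nucleus_map is not None:
            d0 = np.array(
                [
                    distance_to_nuclei((x, y), nucleus_map)
                    for x, y in zip(traj.x_um[:-k], traj.y_um[:-k])
                ]
            )
            prox.append(d0)
            prox.append(d0)
    if not disp:
        raise ValueError("no trajectory provides displacements at this lag")
    return DisplacementSet(
        lag_s=lag_s,
        displacements_um=np.concatenate(disp),
        proximity_um=np.concatenate(prox) if prox else None,
    )


def _gauss(x: np.ndarray, amplitude: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-(x**2) / (2.0 * sigma**2))


def _van_hove_core(
    displacements: np.ndarray,
    bin_width_um: float,
    window_um: float,
) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Histogram + core Gaussian fit + tail excess for one displacement pool."""
    dmax = max(np.abs(displacements).max(), window_um) + bin_width_um
    n_half = int(np.ceil(dmax / bin_width_um))
    edges = np.arange(-n_half, n_half + 1) * bin_width_um  # symmetric, 0-centred bins
    counts, _ = np.histogram(displacements, bins=edges)
    prob = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    core = np.abs(centers) <= window_um + 1e-12
    if core.sum() < 3:
        raise ValueError("Gaussian window contains fewer than 3 bins")
    sigma0 = max(np.std(displacements[np.abs(displacements) <= window_um]), bin_width_um / 10)
    popt, _ = curve_fit(
        _gauss,
        centers[core],
        prob[core],
        p0=(prob[core].max(), sigma0),
        maxfev=10000,
    )
    amplitude, sigma = float(popt[0]), float(abs(popt[1]))

    outside = ~core
    tail_mass = float(prob[outside].sum())
    gauss_tail = float(_gauss(centers[outside], amplitude, sigma).sum())
    tail_excess = max(tail_mass - gauss_tail, 0.0)
    return edges, prob, amplitude, sigma, tail_excess


def compute_van_hove(
    trajs: list[Trajectory] | DisplacementSet,
    lag_s: float = DEFAULT_LAG_S,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    gaussian_window_um: float = DEFAULT_GAUSS_WINDOW_UM,
    active_threshold_se: float = 3.0,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> VanHoveResult:
    """Van Hove displacement distribution with Gaussian-core fit.

    Per-axis displacements at the lag are pooled across trajectories into
    a symmetric histogram; a Gaussian is least-squares fitted to the bins
    inside ``[-gaussian_window_um, +gaussian_window_um]``.  ``tail_excess``
    is the probability mass outside the window in excess of the fitted
    Gaussian's prediction there (floored at 0); its standard error comes
    from a seeded bootstrap over displacements.  The active-processes
    flag is raised when the excess exceeds ``active_threshold_se`` times
    that standard error.
    """
    if isinstance(trajs, DisplacementSet):
        dset = trajs
    else:
        dset = pooled_displacements(trajs, lag_s=lag_s)
    disp = dset.displacements_um
    if len(disp) < 10:
        raise ValueError("need at least 10 displacements")

    edges, prob, amplitude, sigma, tail_excess = _van_hove_core(
        disp, bin_width_um, gaussian_window_um
    )

    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sample = rng.choice(disp, size=len(disp), replace=True)
        try:
            boot[b] = _van_hove_core(sample, bin_width_um, gaussian_window_um)[4]
        except (ValueError, RuntimeError):
            boot[b] = np.nan
    se = float(np.nanstd(boot))

    kurt = float(stats.kurtosis(disp, fisher=True, bias=True))
    active = bool(tail_excess > active_threshold_se * se) if se > 0 else bool(tail_excess > 0)
    return VanHoveResult(
        bin_edges_um=edges,
        probability=prob,
        gaussian_amplitude=amplitude,
        gaussian_sigma_um=sigma,
        window_um=gaussian_window_um,
        tail_excess=tail_excess,
        tail_excess_se=se,
        excess_kurtosis=kurt,
        active_processes_detected=active,
        n_displacements=len(disp),
    )


def partition_by_proximity(
    trajs: list[Trajectory],
    nucleus_map: NucleusMap,
    threshold_um: float | None = None,
    lag_s: float = DEFAULT_LAG_S,
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
    gaussian_window_um: float = DEFAULT_GAUSS_WINDOW_UM,
    min_group_size: int = 50,
    seed: int = 0,
) -> ProximityComparison:
    """Split displacements into near-/far-from-nucleus groups and compare.

    Each displacement is assigned by the proximity of its starting point.
    The default threshold is the median distance over all points (always
    reported in the result).  The comparison is a two-sided Mann-Whitney
    rank-sum test on displacement magnitudes plus the near/far variance
    ratio; groups below ``min_group_size`` displacements mark the
    comparison underpowered instead of silently computing it.
    """
    if threshold_um is not None and threshold_um <= 0:
        raise ValueError("threshold_um must be > 0")
    dset = pooled_displacements(trajs, lag_s=lag_s, nucleus_map=nucleus_map)
    assert dset.proximity_um is not None
    if threshold_um is None:
        threshold_um = float(np.median(dset.proximity_um))
    near_mask = dset.proximity_um <= threshold_um
    near = dset.displacements_um[near_mask]
    far = dset.displacements_um[~near_mask]

    underpowered = len(near) < min_group_size or len(far) < min_group_size

    def _vh(d: np.ndarray, group: str) -> VanHoveResult | None:
        if len(d) < 10:
            return None
        return compute_van_hove(
            DisplacementSet(lag_s=lag_s, displacements_um=d, group=group),
            bin_width_um=bin_width_um,
            gaussian_window_um=gaussian_window_um,
            seed=seed,
        )

    near_vh = _vh(near, "near")
    far_vh = _vh(far, "far")

    if underpowered or len(near) == 0 or len(far) == 0:
        stat = p = vr = None
    else:
        u = stats.mannwhitneyu(np.abs(near), np.abs(far), alternative="two-sided")
        stat, p = float(u.statistic), float(u.pvalue)
        vr = float(np.var(near) / np.var(far)) if np.var(far) > 0 else None
    return ProximityComparison(
        near=near_vh,
        far=far_vh,
        threshold_um=threshold_um,
        rank_sum_statistic=stat,
        rank_sum_p=p,
        variance_ratio=vr,
        underpowered=underpowered,
        n_near=int(len(near)),
        n_far=int(len(far)),
    )
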