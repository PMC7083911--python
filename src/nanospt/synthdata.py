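"""Synthetic-data generators with known ground truth.

Everything the analysis pipeline consumes can be generated here: nanosheet
populations with correlated diameter/height, 2-D Brownian trajectories of
spheroidal particles (optionally with sparse active-displacement bursts),
diffraction-limited fluorescence movies rendered from those trajectories,
excitation-power saturation sweeps with shot noise, and regular arrays of
nucleus polygons emulating a syncytial embryo.  All generators take an
explicit seed and are bit-reproducible.

Internal units: micrometres, seconds, kelvin.  Pixels appear only at the
rendering / IO boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special
from shapely.geometry import Polygon

from .tracking import Trajectory

__all__ = [
    "K_BOLTZMANN",
    "SIGMA_CU_PER_NM2",
    "MONOLAYER_NM",
    "SheetPopulation",
    "MotionParams",
    "SyntheticMovie",
    "SaturationCurve",
    "NucleusMap",
    "generate_sheet_population",
    "diffusion_coefficient",
    "simulate_trajectory",
    "render_movie",
    "simulate_saturation_sweep",
    "generate_nucleus_map",
]

K_BOLTZMANN = 1.380649e-23  # J/K (exact, SI)
SIGMA_CU_PER_NM2 = 3.8  # Cu2+ areal density of a single silicate layer
MONOLAYER_NM = 1.0  # monolayer height


@dataclass
class SheetPopulation:
    """A synthetic nanosheet cohort with geometric ground truth.

    ``n_cu`` counts Cu2+ luminescent centres assuming a disc of the given
    diameter per layer at the crystallographic areal density.
    """

    diameter_nm: np.ndarray
    height_nm: np.ndarray
    n_layers: np.ndarray
    n_cu: np.ndarray
    true_brightness: np.ndarray
    seed: int
    monolayer_nm: float = MONOLAYER_NM
    sigma_cu_per_nm2: float = SIGMA_CU_PER_NM2

    def __len__(self) -> int:
        return len(self.diameter_nm)


@dataclass(frozen=True)
class MotionParams:
    """Physical and sampling parameters for one simulated trajectory."""

    stokes_radius_nm: float
    temperature_K: float = 295.0
    viscosity_Pa_s: float = 1.0
    frame_interval_s: float = 0.125  # 8 fps glycerol protocol
    n_frames: int = 1000
    localization_sigma_um: float = 0.0
    active_burst: tuple[float, float] | None = None  # (rate per frame, scale um)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stokes_radius_nm <= 0 and not np.isinf(self.viscosity_Pa_s):
            raise ValueError("stokes_radius_nm must be > 0")
        if self.temperature_K <= 0 or self.frame_interval_s <= 0:
            raise ValueError("temperature and frame interval must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.localization_sigma_um < 0:
            raise ValueError("localization_sigma_um must be >= 0")


@dataclass
class SyntheticMovie:
    """Rendered image stack with its generating ground truth.

    ``frames`` has shape (n_frames, height_px, width_px).
    """

    frames: np.ndarray
    pixel_size_um: float
    psf_sigma_px: float
    background_level: float
    noise_model: str
    ground_truth: list[Trajectory]
    frame_interval_s: float
    clipped: bool = False
    seed: int = 0


@dataclass
class SaturationCurve:
    """An excitation-power sweep of detected photon counts."""

    P_exc_uW: np.ndarray
    detected_counts_per_s: np.ndarray
    integration_s: float
    direction: np.ndarray  # 'up' / 'down' per point
    true_I_sat_per_s: float | None = None
    true_P_sat_uW: float | None = None
    efficiency: float = 1.0
    seed: int = 0


@dataclass
class NucleusMap:
    """Closed nucleus-boundary polygons in a shared micrometre frame."""

    polygons: list[np.ndarray] = field(default_factory=list)  # (n_vertices, 2), closed rings
    seed: int = 0

    def __post_init__(self) -> None:
        for ring in self.polygons:
            if ring.shape[0] < 4 or not np.allclose(ring[0], ring[-1]):
                raise ValueError("each polygon must be a closed ring with >= 3 distinct vertices")

    def shapely_polygons(self) -> list[Polygon]:
        return [Polygon(ring[:-1]) for ring in self.polygons]


def generate_sheet_population(
    n: int,
    diameter_range_nm: tuple[float, float] = (20.0, 300.0),
    height_slope: float = 13.0 / 300.0,
    brightness_exponent: float = 0.5,
    noise_cv: float = 0.2,
    seed: int = 0,
    height_scatter_sigma: float = 0.15,
    monolayer_nm: float = MONOLAYER_NM,
    sigma_cu_per_nm2: float = SIGMA_CU_PER_NM2,
) -> SheetPopulation:
    """Draw a nanosheet cohort with linearly correlated diameter and height.

    Diameters are log-uniform over ``diameter_range_nm``; heights follow
    ``height_slope * diameter`` with multiplicative lognormal scatter
    (``height_scatter_sigma`` in log-space), floored at one monolayer.
    ``true_brightness`` is proportional to diameter**brightness_exponent
    with multiplicative lognormal noise of coefficient of variation
    ``noise_cv``.

    Defaults emulate a 6 h tip-sonicated cohort: 20-300 nm diameters,
    ~1-13 nm heights, square-root brightness scaling with 20% scatter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = diameter_range_nm
    if not (0 < lo < hi <= 1000):
        raise ValueError("diameter_range_nm must satisfy 0 < lo < hi <= 1000")
    if brightness_exponent < 0 or noise_cv < 0:
        raise ValueError("brightness_exponent and noise_cv must be >= 0")

    rng = np.random.default_rng(seed)
    diameter = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    scatter = (
        rng.lognormal(mean=0.0, sigma=height_scatter_sigma, size=n)
        if height_scatter_sigma > 0
        else np.ones(n)
    )
    height = np.maximum(height_slope * diameter * scatter, monolayer_nm)
    n_layers = np.maximum(np.rint(height / monolayer_nm).astype(int), 1)
    area = np.pi * (diameter / 2.0) ** 2  # disc model for the lateral face
    n_cu = np.rint(sigma_cu_per_nm2 * area * n_layers).astype(np.int64)
    if noise_cv > 0:
        log_sigma = np.sqrt(np.log1p(noise_cv**2))
        bnoise = rng.lognormal(mean=-0.5 * log_sigma**2, sigma=log_sigma, size=n)
    else:
        bnoise = np.ones(n)
    brightness = diameter**brightness_exponent * bnoise
    return SheetPopulation(
        diameter_nm=diameter,
        height_nm=height,
        n_layers=n_layers,
        n_cu=n_cu,
        true_brightness=brightness,
        seed=seed,
        monolayer_nm=monolayer_nm,
        sigma_cu_per_nm2=sigma_cu_per_nm2,
    )


def diffusion_coefficient(params: MotionParams) -> float:
    """Stokes-Einstein D = k_B T / (6 pi eta R), in um^2/s."""
    if np.isinf(params.viscosity_Pa_s):
        return 0.0
    r_m = params.stokes_radius_nm * 1e-9
    d_m2_s = K_BOLTZMANN * params.temperature_K / (
        6.0 * np.pi * params.viscosity_Pa_s * r_m
    )
    return d_m2_s * 1e12


def simulate_trajectory(params: MotionParams) -> Trajectory:
    """Simulate one 2-D Brownian trajectory.

    Positions are cumulative sums of i.i.d. Gaussian steps of per-axis
    variance 2*D*dt, plus i.i.d. localization noise, plus optional sparse
    active bursts: at each frame, with probability ``rate``, a Laplace-
    distributed extra displacement of the given scale is added to that
    step (per axis).  Constant unit mass is attached; rendering assigns
    real amplitudes.
    """
    rng = np.random.default_rng(params.seed)
    d = diffusion_coefficient(params)
    n = params.n_frames
    dt = params.frame_interval_s
    step_sigma = np.sqrt(2.0 * d * dt)
    steps = rng.normal(0.0, step_sigma, size=(n - 1, 2)) if n > 1 else np.zeros((0, 2))
    if params.active_burst is not None and n > 1:
        rate, scale = params.active_burst
        mask = rng.random(n - 1) < rate
        bursts = rng.laplace(0.0, scale, size=(n - 1, 2))
        steps = steps + bursts * mask[:, None]
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    if params.localization_sigma_um > 0:
        pos = pos + rng.normal(0.0, params.localization_sigma_um, size=pos.shape)
    t = np.arange(n) * dt
    return Trajectory(
        particle_id=0,
        t_s=t,
        x_um=pos[:, 0],
        y_um=pos[:, 1],
        mass=np.ones(n),
        pixel_size_um=1.0,
    )


def _integrated_gaussian_1d(centers: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Integral of a unit-peak Gaussian over unit pixels centred at `centers`."""
    s = sigma * np.sqrt(2.0)
    upper = special.erf((centers + 0.5 - mu) / s)
    lower = special.erf((centers - 0.5 - mu) / s)
    return sigma * np.sqrt(np.pi / 2.0) * (upper - lower)


def render_movie(
    trajectories: list[Trajectory],
    shape_px: tuple[int, int],
    pixel_size_um: float,
    psf_sigma_px: float = 2.0,
    amplitudes: np.ndarray | None = None,
    background: float = 0.0,
    noise_model: str = "none",
    gaussian_sigma: float = 0.0,
    frame_interval_s: float | None = None,
    seed: int = 0,
) -> SyntheticMovie:
    """Render trajectories into a diffraction-limited movie.

    Every spot is an integrated symmetric Gaussian (peak ``amplitude``,
    width ``psf_sigma_px``) at the trajectory position converted to
    pixels; the total intensity contributed by an unclipped spot is
    2*pi*amplitude*sigma^2.  A spot whose centre falls outside the frame
    is clipped to the image and the movie's ``clipped`` flag is raised
    (never silently dropped).  ``noise_model`` is one of ``none``,
    ``poisson`` or ``gaussian`` (with ``gaussian_sigma``).
    """
    if not trajectories:
        raise ValueError("at least one trajectory required")
    n_frames = len(trajectories[0])
    times = trajectories[0].t_s
    for tr in trajectories[1:]:
        if len(tr) != n_frames or not np.allclose(tr.t_s, times):
            raise ValueError("trajectories must share a common time base")
    if amplitudes is None:
        amplitudes = np.array([float(np.max(tr.mass)) for tr in trajectories])
    amplitudes = np.asarray(amplitudes, dtype=float)
    if len(amplitudes) != len(trajectories):
        raise ValueError("amplitudes must be length-matched to trajectories")
    if noise_model not in ("none", "poisson", "gaussian"):
        raise ValueError(f"unknown noise_model {noise_model!r}")

    h, w = shape_px
    frames = np.full((n_frames, h, w), float(background))
    cols = np.arange(w)
    rows = np.arange(h)
    clipped = False
    for tr, amp in zip(trajectories, amplitudes):
        xs_px = tr.x_um / pixel_size_um
        ys_px = tr.y_um / pixel_size_um
        if np.any(xs_px < 0) or np.any(xs_px > w - 1) or np.any(ys_px < 0) or np.any(ys_px > h - 1):
            clipped = True
            xs_px = np.clip(xs_px, 0, w - 1)
            ys_px = np.clip(ys_px, 0, h - 1)
        for i in range(n_frames):
            gx = _integrated_gaussian_1d(cols, xs_px[i], psf_sigma_px)
            gy = _integrated_gaussian_1d(rows, ys_px[i], psf_sigma_px)
            frames[i] += amp * np.outer(gy, gx)
    rng = np.random.default_rng(seed)
    if noise_model == "poisson":
        frames = rng.poisson(np.clip(frames, 0, None)).astype(float)
    elif noise_model == "gaussian":
        frames = frames + rng.normal(0.0, gaussian_sigma, size=frames.shape)
    if frame_interval_s is None:
        frame_interval_s = trajectories[0].frame_interval_s if n_frames > 1 else 1.0
    return SyntheticMovie(
        frames=frames,
        pixel_size_um=pixel_size_um,
        psf_sigma_px=psf_sigma_px,
        background_level=background,
        noise_model=noise_model,
        ground_truth=trajectories,
        frame_interval_s=frame_interval_s,
        clipped=clipped,
        seed=seed,
    )


def simulate_saturation_sweep(
    I_sat_per_s: float,
    P_sat_uW: float,
    powers_uW: np.ndarray,
    integration_s: float = 1.0,
    efficiency: float = 1.0,
    noise: str = "poisson",
    both_directions: bool = True,
    seed: int = 0,
) -> SaturationCurve:
    """Simulate an excitation-power sweep of a saturating emitter.

    Expected detected counts follow the two-level saturation law
    I_sat * P / (P + P_sat), scaled by the detection efficiency and the
    integration time, with optional Poisson shot noise.  When
    ``both_directions`` is set the sweep is stepped up and then back
    down, as in a hysteresis-checking protocol.
    """
    if I_sat_per_s <= 0 or P_sat_uW <= 0:
        raise ValueError("I_sat_per_s and P_sat_uW must be > 0")
    powers_uW = np.asarray(powers_uW, dtype=float)
    if np.any(powers_uW < 0):
        raise ValueError("powers must be nonnegative")
    if both_directions:
        powers = np.concatenate([powers_uW, powers_uW[::-1]])
        direction = np.array(["up"] * len(powers_uW) + ["down"] * len(powers_uW))
    else:
        powers = powers_uW
        direction = np.array(["up"] * len(powers_uW))
    expected = efficiency * I_sat_per_s * powers / (powers + P_sat_uW) * integration_s
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    elif noise == "none":
        counts = expected
    else:
        raise ValueError(f"unknown noise {noise!r}")
    return SaturationCurve(
        P_exc_uW=powers,
        detected_counts_per_s=counts / integration_s,
        integration_s=integration_s,
        direction=direction,
        true_I_sat_per_s=I_sat_per_s,
        true_P_sat_uW=P_sat_uW,
        efficiency=efficiency,
        seed=seed,
    )


def _circle_ring(cx: float, cy: float, radius: float, n_vertices: int = 24) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ring = np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
    return np.vstack([ring, ring[:1]])


def generate_nucleus_map(
    n_rows: int,
    n_cols: int,
    nucleus_radius_um: float = 2.5,
    spacing_um: float = 7.0,
    jitter_um: float = 0.5,
    seed: int = 0,
    max_retries: int = 20,
) -> NucleusMap:
    """Nuclei as 24-gon circles on a jittered hexagonal grid.

    Emulates the regular 2-D nuclear array of a syncytial blastoderm.
    Jitter draws are retried (bounded) until no two polygons overlap.
    """
    if spacing_um <= 2.0 * nucleus_radius_um:
        raise ValueError("spacing_um must exceed twice the nucleus radius")
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid must be at least 1x1")
    rng = np.random.default_rng(seed)
    row_pitch = spacing_um * np.sqrt(3.0) / 2.0
    centers = []
    for r in range(n_rows):
        for c in range(n_cols):
            centers.append((c * spacing_um + (r % 2) * spacing_um / 2.0, r * row_pitch))
    centers = np.asarray(centers, dtype=float)
    for _ in range(max_retries):
        jittered = centers + rng.normal(0.0, jitter_um, size=centers.shape) if jitter_um > 0 else centers
        rings = [_circle_ring(cx, cy, nucleus_radius_um) for cx, cy in jittered]
        polys = [Polygon(r[:-1]) for r in rings]
        ok = True
        for i in range(len(polys)):
            for j in range(i + 1, len(polys)):
                if polys[i].distance(polys[j]) <= 0:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return NucleusMap(polygons=rings, seed=seed)
        if jitter_um == 0:
            break
    raise RuntimeError("could not place non-overlapping nuclei within the retry budget")
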