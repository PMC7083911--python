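"""Spot detection and trajectory linking for diffraction-limited emitters.

Detection is a classic band-pass / local-maximum / centroid-refinement
chain; linking is greedy nearest-neighbour with gap closing ("memory").
The per-frame background-subtracted integrated brightness of a blob is
called its *mass*, and the maximum mass along a trajectory is used
downstream as the particle's fluorescence intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Spot",
    "LinkParams",
    "Trajectory",
    "bin2x2",
    "detect_spots",
    "link_spots",
    "trajectory_max_mass",
]


@dataclass(frozen=True)
class Spot:
    """A single detected blob in one frame."""

    frame: int
    x_px: float
    y_px: float
    mass: float
    size_px: float  # radius-of-gyration proxy

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"spot mass must be >= 0, got {self.mass}")


@dataclass(frozen=True)
class LinkParams:
    """Linking parameters (defaults follow the glycerol tracking protocol)."""

    search_range_px: float = 9.0
    memory_frames: int = 300
    min_length: int = 300
    blob_diameter_px: int = 11

    def __post_init__(self) -> None:
        if self.blob_diameter_px % 2 == 0:
            raise ValueError("blob_diameter_px must be odd")
        if self.search_range_px <= 0:
            raise ValueError("search_range_px must be > 0")
        if self.memory_frames < 0 or self.min_length < 1:
            raise ValueError("memory_frames >= 0 and min_length >= 1 required")


@dataclass
class Trajectory:
    """Time-ordered 2-D positions of one particle with per-frame mass.

    Positions are in micrometres and times in seconds; ``pixel_size_um``
    records the conversion that produced them (1.0 when positions were
    generated directly in physical units).
    """

    particle_id: int
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    mass: np.ndarray
    pixel_size_um: float = 1.0
    clipped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        n = len(self.t_s)
        if not (len(self.x_um) == len(self.y_um) == len(self.mass) == n) or n < 1:
            raise ValueError("t_s, x_um, y_um, mass must share a common length >= 1")
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def frame_interval_s(self) -> float:
        if len(self) < 2:
            raise ValueError("frame interval undefined for a single-point trajectory")
        dts = np.diff(self.t_s)
        if not np.allclose(dts, dts[0], rtol=1e-6):
            raise ValueError("trajectory is not uniformly sampled")
        return float(dts[0])


def bin2x2(frame: np.ndarray) -> np.ndarray:
    """Sum-bin an image 2x2 (pre-processing used for embryo movies).

    Odd trailing rows/columns are dropped.
    """
    h, w = frame.shape[0] // 2 * 2, frame.shape[1] // 2 * 2
    f = frame[:h, :w]
    return f[0::2, 0::2] + f[1::2, 0::2] + f[0::2, 1::2] + f[1::2, 1::2]


def _bandpass(image: np.ndarray, blob_diameter_px: int) -> np.ndarray:
    """Gaussian smoothing minus a boxcar background estimate, clipped at 0."""
    img = np.asarray(image, dtype=float)
    noise_sigma = 1.0
    smoothed = ndimage.gaussian_filter(img, noise_sigma, mode="nearest")
    background = ndimage.uniform_filter(img, blob_diameter_px, mode="nearest")
    bp = np.clip(smoothed - background, 0.0, None)
    # kill float-rounding ripple of a flat background (~1e-13 of the signal)
    floor = max(1e-9, 1e-6 * float(bp.max()))
    bp[bp < floor] = 0.0
    return bp


def detect_spots(
    frame: np.ndarray,
    blob_diameter_px: int = 11,
    min_mass: float = 0.0,
    percentile_threshold: float = 64.0,
    frame_index: int = 0,
) -> list[Spot]:
    """Detect diffraction-limited spots in a single image.

    The image is band-pass filtered (Gaussian denoising minus a boxcar
    background of the blob size), local maxima above the brightness
    percentile of non-zero filtered pixels are taken as candidates, and
    each candidate is refined to sub-pixel accuracy by an iterated
    centre-of-mass within a circular window of the blob radius.

    Parameters
    ----------
    frame:
        2-D nonnegative image.
    blob_diameter_px:
        Odd integer window for background estimation, local-maximum
        suppression and centroid refinement.
    min_mass:
        Candidates with background-subtracted integrated mass below this
        are discarded (default 0: keep everything).
    percentile_threshold:
        Percentile (of the positive band-passed pixels) a local maximum
        must exceed.
    """
    if blob_diameter_px % 2 == 0:
        raise ValueError("blob_diameter_px must be odd")
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("frame must be a 2-D image")

    bp = _bandpass(img, blob_diameter_px)
    positive = bp[bp > 0]
    if positive.size == 0:
        return []
    threshold = np.percentile(positive, percentile_threshold)

    footprint = np.ones((blob_diameter_px, blob_diameter_px), dtype=bool)
    maxima = (bp == ndimage.maximum_filter(bp, footprint=footprint, mode="nearest")) & (
        bp > threshold
    )
    ys, xs = np.nonzero(maxima)

    radius = blob_diameter_px // 2
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    mask = (xx**2 + yy**2) <= radius**2

    h, w = img.shape
    # robust background level for mass integration (spots are sparse)
    background_level = float(np.median(img))
    spots: list[Spot] = []
    seen: set[tuple[int, int]] = set()
    for y0, x0 in zip(ys.tolist(), xs.tolist()):
        cy, cx = float(y0), float(x0)
        # iterated centre of mass: re-centre the window until the shift
        # is sub-threshold (symmetric spots converge in a couple of steps)
        for _ in range(10):
            iy, ix = int(round(cy)), int(round(cx))
            if not (radius <= iy < h - radius and radius <= ix < w - radius):
                iy = min(max(iy, radius), h - radius - 1)
                ix = min(max(ix, radius), w - radius - 1)
            window = bp[iy - radius : iy + radius + 1, ix - radius : ix + radius + 1]
            wmasked = window * mask
            total = wmasked.sum()
            if total <= 0:
                break
            ny = iy + (wmasked * yy).sum() / total
            nx = ix + (wmasked * xx).sum() / total
            shift = max(abs(ny - cy), abs(nx - cx))
            cy, cx = ny, nx
            if shift < 0.005:
                break
        if total <= 0:
            continue
        key = (int(round(cy * 10)), int(round(cx * 10)))
        if key in seen:  # two maxima collapsed onto the same refined centre
            continue
        seen.add(key)
        rg2 = (wmasked * (xx**2 + yy**2)).sum() / total
        # mass: background-subtracted raw-image sum over the square window
        raw_window = img[iy - radius : iy + radius + 1, ix - radius : ix + radius + 1]
        mass = float(raw_window.sum() - background_level * raw_window.size)
        if mass < min_mass:
            continue
        spots.append(
            Spot(
                frame=frame_index,
                x_px=float(cx),
                y_px=float(cy),
                mass=max(mass, 0.0),
                size_px=float(np.sqrt(max(rg2, 0.0))),
            )
        )
    spots.sort(key=lambda s: (s.y_px, s.x_px))
    return spots


def detect_stack(
    stack: np.ndarray,
    blob_diameter_px: int = 11,
    min_mass: float = 0.0,
    percentile_threshold: float = 64.0,
) -> list[list[Spot]]:
    """Run :func:`detect_spots` on every frame of an image stack."""
    return [
        detect_spots(
            stack[i],
            blob_diameter_px=blob_diameter_px,
            min_mass=min_mass,
            percentile_threshold=percentile_threshold,
            frame_index=i,
        )
        for i in range(stack.shape[0])
    ]


class _Track:
    __slots__ = ("frames", "xs", "ys", "masses", "last_frame")

    def __init__(self) -> None:
        self.frames: list[int] = []
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.masses: list[float] = []
        self.last_frame = -1

    def add(self, spot: Spot) -> None:
        self.frames.append(spot.frame)
        self.xs.append(spot.x_px)
        self.ys.append(spot.y_px)
        self.masses.append(spot.mass)
        self.last_frame = spot.frame


def link_spots(
    spots_by_frame: list[list[Spot]],
    params: LinkParams,
    pixel_size_um: float,
    frame_interval_s: float,
) -> list[Trajectory]:
    """Link per-frame spot lists into trajectories.

    Frame-to-frame assignment is greedy on squared displacement: candidate
    (track, spot) pairs within ``search_range_px`` are sorted by distance
    and consumed in order, with deterministic lexicographic tie-breaking
    on (frame, x, y).  A track that finds no match survives for up to
    ``memory_frames`` further frames before it is closed.  Tracks shorter
    than ``min_length`` points are discarded.  Output positions are in
    micrometres and times in seconds.
    """
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValueError("pixel_size_um and frame_interval_s must be > 0")
    active: list[_Track] = []
    closed: list[_Track] = []
    r2max = params.search_range_px**2

    for frame_idx, spots in enumerate(spots_by_frame):
        # deterministic candidate order regardless of input spot order
        spots = sorted(spots, key=lambda s: (s.y_px, s.x_px))
        candidates = []
        for ti, track in enumerate(active):
            tx, ty = track.xs[-1], track.ys[-1]
            for si, spot in enumerate(spots):
                d2 = (spot.x_px - tx) ** 2 + (spot.y_px - ty) ** 2
                if d2 <= r2max:
                    candidates.append((d2, spot.frame, spot.x_px, spot.y_px, ti, si))
        candidates.sort()
        used_tracks: set[int] = set()
        used_spots: set[int] = set()
        for d2, _, _, _, ti, si in candidates:
            if ti in used_tracks or si in used_spots:
                continue
            active[ti].add(spots[si])
            used_tracks.add(ti)
            used_spots.add(si)
        for si, spot in enumerate(spots):
            if si not in used_spots:
                t = _Track()
                t.add(spot)
                active.append(t)
        still_active = []
        for track in active:
            if frame_idx - track.last_frame > params.memory_frames:
                closed.append(track)
            else:
                still_active.append(track)
        active = still_active
    closed.extend(active)

    trajectories: list[Trajectory] = []
    pid = 0
    for track in closed:
        if len(track.frames) < params.min_length:
            continue
        frames = np.asarray(track.frames)
        trajectories.append(
            Trajectory(
                particle_id=pid,
                t_s=frames * frame_interval_s,
                x_um=np.asarray(track.xs) * pixel_size_um,
                y_um=np.asarray(track.ys) * pixel_size_um,
                mass=np.asarray(track.masses),
                pixel_size_um=pixel_size_um,
            )
        )
        pid += 1
    return trajectories


def trajectory_max_mass(traj: Trajectory) -> float:
    """Maximum per-frame integrated brightness along a trajectory.

    Used as the particle's fluorescence intensity: the maximum is robust
    against frames where the particle drifted out of focus or rotated.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    return float(np.max(traj.mass))
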