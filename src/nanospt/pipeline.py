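"""End-to-end scenario runner and pipeline configuration.

Three scenarios tie the stages together:

* ``glycerol`` — render (or load) a movie of nanosheets diffusing in a
  viscous glycerol solution, detect and link spots, compute MSDs and
  spheroid-corrected hydrodynamic radii, and correlate size with
  brightness.
* ``embryo`` — trajectories of injected nanosheets in a syncytial
  embryo: instantaneous velocities, nucleus-proximity partitioning and
  Van Hove tail analysis.
* ``photophysics`` — fit saturation sweeps and count luminescent
  centres via the photon budget.

Every run writes a JSON summary recording the seed, the resolved
parameters and whether each was a default or user-set, so any result can
be reproduced from its summary alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from . import msd as nmsd
from . import photophysics as nphot
from . import synthdata as nsyn
from . import tracking as ntrk
from . import vanhove as nvh

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_SCENARIOS = ("glycerol", "embryo", "photophysics")


@dataclass
class PipelineConfig:
    """All stage parameters with field defaults equal to the protocol values."""

    scenario: str = "glycerol"
    seed: int = 0
    # acquisition
    frame_interval_s: float = 0.125  # 8 fps glycerol; embryo uses 0.1 (10 fps)
    n_frames: int = 1000
    pixel_size_um: float = 0.1  # camera pixel size: required, no protocol default
    # tracking
    blob_diameter_px: int = 11
    search_range_px: float = 9.0
    memory_frames: int = 300
    min_length: int = 300  # 200 for the embryo scenario
    min_mass: float = 0.0
    percentile_threshold: float = 64.0
    bin_2x2: bool = False
    # sizing
    temperature_K: float = 295.0
    glycerol_mass_fraction: float = 1.0
    viscosity_Pa_s: float | None = None  # None -> glycerol_viscosity(T, fraction)
    A_correction: float = 1.49
    max_lag_s: float = 25.0
    # photophysics
    lifetime_s: float = 1.0e-4
    quantum_yield: float = 0.1
    sigma_cu_per_nm2: float = 3.8
    collection: float = 0.70
    optics_transmission: float = 0.50
    detector_qe: float = 0.05
    # van hove
    vh_lag_s: float = 0.1
    vh_bin_width_um: float = 0.005
    vh_window_um: float = 0.03
    proximity_threshold_um: float | None = None  # None -> median distance

    user_set: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}, got {self.scenario!r}")
        if self.scenario == "embryo" and "frame_interval_s" not in self.user_set:
            self.frame_interval_s = 0.1
        if self.scenario == "embryo" and "min_length" not in self.user_set:
            self.min_length = 200
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")

    def resolved_viscosity(self) -> float:
        if self.viscosity_Pa_s is not None:
            return self.viscosity_Pa_s
        return nmsd.glycerol_viscosity(self.temperature_K, self.glycerol_mass_fraction)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("user_set")
        return d

    def provenance(self) -> dict:
        return {
            name: ("user" if name in self.user_set else "default")
            for name in self.to_dict()
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; keys present in the file are marked user-set."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw, user_set=set(raw))


def _track_movie(stack: np.ndarray, cfg: PipelineConfig) -> list[ntrk.Trajectory]:
    frames = stack
    pixel_size = cfg.pixel_size_um
    if cfg.bin_2x2:
        frames = np.stack([ntrk.bin2x2(f) for f in frames])
        pixel_size = 2.0 * pixel_size
    spots = ntrk.detect_stack(
        frames,
        blob_diameter_px=cfg.blob_diameter_px,
        min_mass=cfg.min_mass,
        percentile_threshold=cfg.percentile_threshold,
    )
    params = ntrk.LinkParams(
        search_range_px=cfg.search_range_px,
        memory_frames=cfg.memory_frames,
        min_length=cfg.min_length,
        blob_diameter_px=cfg.blob_diameter_px,
    )
    return ntrk.link_spots(spots, params, pixel_size, cfg.frame_interval_s)


def _summary_base(cfg: PipelineConfig) -> dict:
    import nanospt

    return {
        "nanospt_version": nanospt.__version__,
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "parameter_provenance": cfg.provenance(),
    }


def _run_glycerol(cfg: PipelineConfig, inputs: dict, outdir: Path) -> dict:
    if "movie_tiff" in inputs:
        stack, meta = nio.read_movie_tiff(inputs["movie_tiff"])
        if "pixel_size_um" in meta and "pixel_size_um" not in cfg.user_set:
            cfg.pixel_size_um = float(meta["pixel_size_um"])
        if "frame_interval_s" in meta and "frame_interval_s" not in cfg.user_set:
            cfg.frame_interval_s = float(meta["frame_interval_s"])
        trajs = _track_movie(stack, cfg)
    elif "trajectories_csv" in inputs:
        trajs = nio.read_trajectories_csv(inputs["trajectories_csv"], cfg.pixel_size_um)
    else:
        raise ValueError("glycerol scenario needs 'movie_tiff' or 'trajectories_csv'")
    if not trajs:
        raise ValueError("no trajectories survived tracking")
    nio.write_trajectories_csv(outdir / "trajectories.csv", trajs)

    eta = cfg.resolved_viscosity()
    table = nmsd.size_brightness_correlation(
        trajs,
        T_K=cfg.temperature_K,
        eta_Pa_s=eta,
        A_correction=cfg.A_correction,
        fit_max_lag_s=cfg.max_lag_s,
        seed=cfg.seed,
    )
    rows = "particle_id,D_um2_s,R_stokes_nm,R_hydro_nm,max_mass\n" + "".join(
        f"{p},{d:.8g},{rs:.8g},{rh:.8g},{m:.8g}\n"
        for p, d, rs, rh, m in zip(
            table.particle_id, table.D_um2_s, table.R_stokes_nm, table.R_hydro_nm, table.max_mass
        )
    )
    nio.atomic_write_text(outdir / "size_brightness.csv", rows)
    rho, p = nmsd.spearman_size_truth(table.R_hydro_nm, table.max_mass)
    summary = _summary_base(cfg)
    summary.update(
        {
            "viscosity_Pa_s": eta,
            "n_trajectories": len(trajs),
            "n_sized": int(len(table.particle_id)),
            "n_excluded": table.n_excluded,
            "power_law": {
                "prefactor": table.prefactor,
                "exponent": table.exponent,
                "exponent_ci95": list(table.exponent_ci),
            },
            "size_brightness_spearman": {"rho": rho, "p": p},
        }
    )
    return summary


def _run_embryo(cfg: PipelineConfig, inputs: dict, outdir: Path) -> dict:
    if "trajectories_csv" in inputs:
        trajs = nio.read_trajectories_csv(inputs["trajectories_csv"], cfg.pixel_size_um)
    elif "movie_tiff" in inputs:
        stack, _ = nio.read_movie_tiff(inputs["movie_tiff"])
        trajs = _track_movie(stack, cfg)
    else:
        raise ValueError("embryo scenario needs 'trajectories_csv' or 'movie_tiff'")
    if not trajs:
        raise ValueError("no trajectories available")

    speeds = {
        int(tr.particle_id): nvh.instantaneous_velocity(tr, cfg.vh_lag_s).tolist()
        for tr in trajs
        if len(tr) > 1
    }
    vh = nvh.compute_van_hove(
        trajs,
        lag_s=cfg.vh_lag_s,
        bin_width_um=cfg.vh_bin_width_um,
        gaussian_window_um=cfg.vh_window_um,
        seed=cfg.seed,
    )
    hist_csv = "bin_center_um,probability\n" + "".join(
        f"{c:.8g},{p:.8g}\n"
        for c, p in zip(
            0.5 * (vh.bin_edges_um[:-1] + vh.bin_edges_um[1:]), vh.probability
        )
    )
    nio.atomic_write_text(outdir / "van_hove.csv", hist_csv)

    summary = _summary_base(cfg)
    summary.update(
        {
            "n_trajectories": len(trajs),
            "mean_instantaneous_speed_um_s": float(
                np.mean([s for v in speeds.values() for s in v])
            ),
            "van_hove": {
                "gaussian_sigma_um": vh.gaussian_sigma_um,
                "tail_excess": vh.tail_excess,
                "tail_excess_se": vh.tail_excess_se,
                "excess_kurtosis": vh.excess_kurtosis,
                "active_processes_detected": vh.active_processes_detected,
                "n_displacements": vh.n_displacements,
            },
        }
    )
    if "nuclei_csv" in inputs:
        nmap = nio.read_nucleus_map_csv(inputs["nuclei_csv"])
        cmp_res = nvh.partition_by_proximity(
            trajs,
            nmap,
            threshold_um=cfg.proximity_threshold_um,
            lag_s=cfg.vh_lag_s,
            bin_width_um=cfg.vh_bin_width_um,
            gaussian_window_um=cfg.vh_window_um,
            seed=cfg.seed,
        )
        summary["proximity"] = {
            "threshold_um": cmp_res.threshold_um,
            "n_near": cmp_res.n_near,
            "n_far": cmp_res.n_far,
            "underpowered": cmp_res.underpowered,
            "rank_sum_p": cmp_res.rank_sum_p,
            "variance_ratio": cmp_res.variance_ratio,
            "near_sigma_um": cmp_res.near.gaussian_sigma_um if cmp_res.near else None,
            "far_sigma_um": cmp_res.far.gaussian_sigma_um if cmp_res.far else None,
        }
    return summary


def _run_photophysics(cfg: PipelineConfig, inputs: dict, outdir: Path) -> dict:
    if "saturation_csv" not in inputs:
        raise ValueError("photophysics scenario needs 'saturation_csv'")
    curve = nio.read_saturation_csv(inputs["saturation_csv"])
    eff = nphot.DetectionEfficiency(
        collection=cfg.collection,
        optics_transmission=cfg.optics_transmission,
        detector_qe=cfg.detector_qe,
    )
    fit = nphot.fit_saturation(curve, eff)
    est = nphot.count_luminescent_centers(
        fit,
        lifetime_s=cfg.lifetime_s,
        quantum_yield=cfg.quantum_yield,
        sigma_cu_per_nm2=cfg.sigma_cu_per_nm2,
    )
    summary = _summary_base(cfg)
    summary.update(
        {
            "efficiency_overall": eff.overall,
            "fit": {
                "I_sat_per_s": fit.I_sat_per_s,
                "P_sat_uW": fit.P_sat_uW,
                "plateau_reached": fit.plateau_reached,
                "hysteresis": fit.hysteresis,
            },
            "N_centers": est.N_centers,
            "monolayer_side_nm": est.monolayer_side_nm,
            "monolayer_side_nm_rounded": est.monolayer_side_nm_rounded,
        }
    )
    return summary


def run_pipeline(config: PipelineConfig, inputs: dict, outdir: str | Path) -> dict:
    """Run one scenario end to end; returns and writes the JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r} does not exist: {path}")
    runner = {
        "glycerol": _run_glycerol,
        "embryo": _run_embryo,
        "photophysics": _run_photophysics,
    }[config.scenario]
    logger.info("running %s scenario (seed=%d)", config.scenario, config.seed)
    summary = runner(config, inputs, outdir)
    nio.write_json(outdir / "summary.json", summary)
    return summary
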