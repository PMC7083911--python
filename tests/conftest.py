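import numpy as np
import pytest

from nanospt import synthdata as syn


def viscosity_for_D(D_um2_s: float, T_K: float = 295.0, R_nm: float = 1.0) -> float:
    """Viscosity that makes a particle of radius R_nm diffuse at D (um^2/s)."""
    return syn.K_BOLTZMANN * T_K / (6.0 * np.pi * R_nm * 1e-9 * D_um2_s * 1e-12)


def brownian_trajectories(
    n_traj: int,
    D_um2_s: float,
    frame_interval_s: float,
    n_frames: int,
    seed0: int,
    active_burst=None,
):
    """A cohort of Brownian trajectories at a prescribed diffusivity."""
    eta = viscosity_for_D(D_um2_s)
    trajs = []
    for i in range(n_traj):
        params = syn.MotionParams(
            stokes_radius_nm=1.0,
            temperature_K=295.0,
            viscosity_Pa_s=eta,
            frame_interval_s=frame_interval_s,
            n_frames=n_frames,
            active_burst=active_burst,
            seed=seed0 + i,
        )
        tr = syn.simulate_trajectory(params)
        tr.particle_id = i
        trajs.append(tr)
    return trajs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
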