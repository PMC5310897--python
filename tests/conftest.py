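"""Shared fixtures: small simulated cohorts and a rendered image stack.

Everything is generated programmatically with fixed seeds; the rendered
fixture is session-scoped because the entropy filter dominates test time.
"""

import numpy as np
import pytest

from flowtaxis.render import RenderParams, render_stack
from flowtaxis.simulate import SimParams, simulate_trackset
from flowtaxis.tracks import Track, TrackSet

# rendered-fixture geometry: cells in the lower-right 2x2 grid so the
# top-left 60x60 px region holds only debris (the drift template)
FIXTURE_ORIGINS = np.array([[100.0, 100.0], [180.0, 100.0],
                            [100.0, 180.0], [180.0, 180.0]])
FIXTURE_TEMPLATE_BOX = (5, 5, 60, 60)
# rendered cell components are ~300-500 px^2 at radius 6; debris plus its
# entropy halo stays under ~160 px^2, so this cleanly separates the two
FIXTURE_MIN_AREA = 200


def straight_track(n_steps: int, step=(1.0, 0.0), dt: float = 1.0,
                   cell_id=0) -> Track:
    """A track taking identical steps; handy exact-value fixture."""
    t = np.arange(n_steps + 1) * dt
    xy = np.outer(np.arange(n_steps + 1), np.asarray(step, dtype=float))
    return Track(cell_id, t, xy)


def track_from_steps(steps, dt: float = 1.0, cell_id=0) -> Track:
    steps = np.asarray(steps, dtype=float)
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return Track(cell_id, np.arange(len(xy)) * dt, xy)


@pytest.fixture(scope="session")
def rendered_fixture():
    """4 motile cells rendered over 15 frames with a known drift schedule."""
    rng = np.random.default_rng(5)
    params = SimParams(n_cells=4, n_frames=15, base_speed=0.8, speed_sd=0.1,
                       p_pause=0.0, p_resume=1.0)
    ts = simulate_trackset(params, rng)
    drift = np.zeros((15, 2), dtype=int)
    drift[5] = (3, -2)
    drift[6:] = (1, 2)
    rp = RenderParams(image_shape=(260, 260), cell_radius=6, noise_sd=0.01,
                      drift_schedule=drift)
    stack, truth, drift_out = render_stack(ts, rp, rng, origins=FIXTURE_ORIGINS)
    return {"trackset": ts, "params": rp, "stack": stack, "truth": truth,
            "drift": drift_out}


@pytest.fixture()
def two_state_params():
    """Two-state walk whose arrest statistics have a closed-form oracle."""
    return SimParams(n_cells=300, n_frames=121, base_speed=0.5, speed_sd=0.05,
                     p_pause=0.1, p_resume=0.1, pause_speed=0.05,
                     persistence_sigma=1.0)


@pytest.fixture()
def small_trackset():
    rng = np.random.default_rng(11)
    params = SimParams(n_cells=6, n_frames=31, base_speed=0.5, speed_sd=0.1,
                       p_pause=0.05, p_resume=0.3, pause_speed=0.05)
    return simulate_trackset(params, rng)
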