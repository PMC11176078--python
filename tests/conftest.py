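import numpy as np
import pytest

from swimstates import kinematics, synthetic


@pytest.fixture(scope="session")
def control_session():
    """A 240-s control session plus its ground-truth bout table."""
    config = synthetic.SessionConfig(session_duration_s=240.0, seed=10)
    pose, truth = synthetic.simulate_session(
        config, synthetic.condition("control"))
    return config, pose, truth


@pytest.fixture(scope="session")
def control_bouts(control_session):
    """Detected bouts with parameters for the control session, with the
    generating state attached (detection recovers one bout per truth row)."""
    config, pose, truth = control_session
    bouts = kinematics.analyze_session(pose, config)
    assert len(bouts) == len(truth)
    bouts = bouts.copy()
    bouts["state"] = truth["state"].to_numpy()
    return config, bouts, truth


@pytest.fixture(scope="session")
def rendered_benchmark():
    """100 rendered frames at peak-SNR 10 with known subpixel positions."""
    rng = np.random.default_rng(11)
    config = synthetic.SessionConfig(arena_diameter_mm=16.0)
    positions_mm = rng.uniform(5.0, 11.0, size=(100, 2))
    template = synthetic.GaussianFishTemplate(sigma_px=4.0, depth=150.0)
    stack, truth_px = synthetic.render_frames(
        positions_mm, config, template, noise_sd=15.0, seed=12)
    return config, stack, positions_mm, truth_px
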