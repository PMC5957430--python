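import numpy as np
import pytest

import meiotrack as mt


@pytest.fixture(scope="session")
def control_cell():
    """One simulated control M I cell with its ground truth."""
    bundle, gt = mt.simulate_cell(mt.make_preset("control"), seed=4)
    return bundle, gt


@pytest.fixture(scope="session")
def control_result(control_cell):
    bundle, gt = control_cell
    return mt.analyze_cell(bundle, ground_truth=gt)


@pytest.fixture(scope="session")
def control_cohort():
    """Twenty seeded control cells with blind analyses."""
    out = []
    for seed in range(20):
        bundle, gt = mt.simulate_cell(mt.make_preset("control"), seed)
        out.append((bundle, gt, mt.analyze_cell(bundle, ground_truth=gt)))
    return out


@pytest.fixture(scope="session")
def optics():
    return mt.OpticsConfig()


@pytest.fixture(scope="session")
def rendered_frame(control_cell, optics):
    """An early-prometaphase rendered frame plus the true positions."""
    from meiotrack.render import default_origin, render_movie
    bundle, gt = control_cell
    frame = 10
    series = render_movie(bundle, optics, seed=1, frames=[frame])
    origin = np.array(default_origin(optics))  # (z, y, x)
    true_xyz = gt.true_positions[:, frame] - origin[::-1]
    return series.frame(0, 0), true_xyz
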