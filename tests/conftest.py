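import numpy as np
import pytest

from xenoresp.trajectory import Trajectory


@pytest.fixture
def make_traj():
    """Factory for quick trajectories: make_traj(volumes, days=None, ...)."""

    def _make(volumes, days=None, treatment_end_day=7.0, **kw):
        volumes = np.asarray(volumes, dtype=float)
        if days is None:
            days = np.arange(len(volumes)) * 7.0
        return Trajectory(model_id=kw.get("model_id", "M1"),
                          animal_id=kw.get("animal_id", "a1"),
                          arm=kw.get("arm", "arm"),
                          days=days, volumes=volumes,
                          treatment_end_day=treatment_end_day)

    return _make
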