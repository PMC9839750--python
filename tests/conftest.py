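import numpy as np
import pytest

from dualflit import simulate as sim


@pytest.fixture(scope="session")
def pge2() -> sim.ConditionPreset:
    return sim.preset_library()["pge2"]


@pytest.fixture(scope="session")
def rendered_clone(pge2) -> sim.SimulatedClone:
    """One full-length clone with traces, rendered stacks and truth masks."""
    clone = sim.simulate_lineage(pge2, 72.0, seed=11)
    sim.simulate_traces(clone, sim.ReporterDynamics(), seed=12)
    sim.render_sequence(clone, sim.RenderConfig(seed=5))
    return clone


@pytest.fixture(scope="session")
def sparse_rendered_clone(pge2) -> sim.SimulatedClone:
    """A shorter, sparser rendered clone where cells stay well separated."""
    clone = sim.simulate_lineage(pge2, 40.0, seed=3)
    sim.simulate_traces(clone, seed=4)
    sim.render_sequence(clone, sim.RenderConfig(duration_h=40.0, seed=6))
    return clone


@pytest.fixture(scope="session")
def small_cohort(pge2) -> list[sim.SimulatedClone]:
    """50 clones with ground-truth traces (no rendering)."""
    return sim.simulate_cohort(pge2, 50, 72.0, seed=7)


def make_trace(values, missing=None, first_frame=0, track_id=1, channel="myog"):
    """Build a Trace directly from raw values (test helper)."""
    from dualflit.fluorsig import Trace

    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros(values.size, dtype=bool)
    return Trace(track_id, channel, first_frame, values,
                 np.asarray(missing, dtype=bool))
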