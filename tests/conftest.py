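import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def overnight_recording():
    """A 12-h overnight recording (20:00 start, 60 Hz) with one low- and one
    high-amplitude B-wave train and pulse-amplitude coupling, plus its
    ground truth.  Shared across tests: simulation is the expensive part."""
    from datetime import datetime

    from icpwaves.synthetic_data import BWaveTrainSpec, SimulationSpec, simulate_icp_recording

    spec = SimulationSpec(
        duration_s=12 * 3600,
        sampling_rate=60,
        baseline_icp=12.0,
        noise_sd=0.2,
        amp_coupling=2.0,
        b_wave_trains=(
            BWaveTrainSpec(start_s=3 * 3600, duration_s=2 * 3600, freq_per_min=1.0, amplitude=6.0),
            BWaveTrainSpec(start_s=6 * 3600, duration_s=1.5 * 3600, freq_per_min=1.5, amplitude=14.0),
        ),
        seed=11,
        start_clock=datetime(2000, 1, 1, 20, 0, 0),
    )
    return simulate_icp_recording(spec) + (spec,)


@pytest.fixture(scope="session")
def overnight_results(overnight_recording):
    from icpwaves import RecordingAnalysis

    signal, truth, spec = overnight_recording
    return RecordingAnalysis(signal).fit(), truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
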