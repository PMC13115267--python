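import numpy as np
import pytest

from gaitcorridor import AnalysisConfig, CohortSpec, GaitTemplate


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def template() -> GaitTemplate:
    return GaitTemplate()


@pytest.fixture
def quiet_spec() -> CohortSpec:
    """A deterministic, low-noise single-group spec for recovery tests."""
    return CohortSpec(
        seed=7,
        n_subjects=3,
        cycles_per_subject=8,
        cycle_noise_sd=0.5,
        interlimb_lag_pct=0.0,
        interlimb_lag_sd_pct=0.0,
        decoupling_pct=0.0,
        between_subject_sd=2.0,
    )


def make_template_series(
    durations_ms,
    fs: float = 120.0,
    template: GaitTemplate | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    subject_id: str = "S",
    side: str = "left",
):
    """Sample the two-bump template over cycles of the given durations."""
    from gaitcorridor import AngleSeries, template_waveform

    template = template or GaitTemplate()
    durations = np.asarray(durations_ms, float)
    edges = np.concatenate([[0.0], np.cumsum(durations)])
    t = np.arange(0.0, edges[-1], 1000.0 / fs)
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(durations) - 1)
    phase = (t - edges[idx]) / durations[idx] * 100.0
    angle = template_waveform(template, phase)
    if noise_sd > 0:
        angle = angle + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return AngleSeries(subject_id, side, t, angle, fs=fs)
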