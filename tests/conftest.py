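"""Shared fixtures and synthetic-recording builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dyadsync import constants, signal_synthesis as ss, task_model as tm

@pytest.fixture(scope="session")
def delayed_session() -> tm.DyadSession:
    return tm.simulate_session("dyad001", "delayed", seed=11)


@pytest.fixture(scope="session")
def default_timeline() -> pd.DataFrame:
    return ss.make_timeline(ss.AcquisitionConfig())


@pytest.fixture(scope="session")
def intensity_recording(delayed_session) -> ss.HyperscanRecording:
    """One raw recording with strong coupling at channel 19, no artifacts."""
    return ss.synthesize_dyad_recording(
        delayed_session,
        coupling=ss.CouplingSpec(strength_by_strategy={"delayed": 5.0}),
        seed=101,
    )


def make_hb_noise_recording(
    seed: int,
    n_channels: int = constants.N_CHANNELS,
    strength: float = 0.0,
    coupled_channel: int = 19,
    lag: float = 0.0,
    active_segments=constants.TASK_SEGMENTS,
    dyad_id: str = "dyad",
    strategy: str = "delayed",
    noise: ss.NoiseSpec | None = None,
) -> ss.HyperscanRecording:
    """Build an hb-stage recording directly (physiological noise plus an
    optional shared narrowband component), skipping the optical forward and
    inverse steps.  Used for Monte-Carlo work where only the concentration
    series matter."""
    noise = noise or ss.NoiseSpec()
    acq = ss.AcquisitionConfig()
    rng = np.random.default_rng(seed)
    timeline = ss.make_timeline(acq)
    n = int(round(acq.total_duration * acq.fs))
    times = np.arange(n) / acq.fs
    shared = ss._narrowband_noise(n, acq.fs, 6.4, 0.5, rng)
    gate = ss._segment_gate(times, timeline, active_segments)
    lag_samples = int(round(lag * acq.fs))
    shared_lagged = np.roll(shared, lag_samples)

    data = np.empty((2, n_channels, 2, n))
    for p in range(2):
        src = shared if p == 0 else shared_lagged
        for c in range(n_channels):
            x = ss._channel_noise(n, acq.fs, noise, rng)
            if strength > 0 and (c + 1) == coupled_channel:
                x = x + strength * x.std() * src * gate
            data[p, c, 0] = x
            data[p, c, 1] = -x / 3.0
    return ss.HyperscanRecording(
        dyad_id=dyad_id,
        stage="hb",
        data=data,
        fs=acq.fs,
        timeline=timeline,
        strategy=strategy,
    )
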