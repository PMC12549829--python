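import numpy as np
import pytest

import lfpbeta as lb


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_noise():
    """Background-only noise model (no mains interference)."""
    return lb.NoiseSpec(
        pink_exponent=1.0, pink_scale=10.0, white_scale=1.0,
        line_harmonic_amplitudes=(0.0,),
    )


@pytest.fixture
def silence():
    """Fully silent noise model."""
    return lb.NoiseSpec(
        pink_exponent=1.0, pink_scale=0.0, white_scale=0.0,
        line_harmonic_amplitudes=(0.0,),
    )


def sinusoid_recording(freq, fs, duration_s, amplitude=1.0, n_channels=1):
    t = np.arange(int(round(duration_s * fs))) / fs
    x = amplitude * np.sin(2 * np.pi * freq * t)
    return lb.Recording(
        np.tile(x, (n_channels, 1)), fs, [f"ch{i+1}" for i in range(n_channels)]
    )


def brute_force_bursts(env, fs, percentile=80.0, min_duration_s=0.1, threshold=None):
    """Independent run-length enumeration oracle for burst detection.

    Walks the envelope sample by sample, collecting maximal strictly-above-
    threshold runs, discarding boundary-touching runs and runs shorter than
    the minimum duration.  Returns (start, stop) sample index pairs.
    """
    env = np.asarray(env, float).ravel()
    if threshold is None:
        threshold = np.percentile(env, percentile)
    runs = []
    start = None
    for i, v in enumerate(env):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(env)))
    out = []
    for a, b in runs:
        if a == 0 or b == len(env):
            continue
        if (b - a) / fs >= min_duration_s:
            out.append((a, b))
    return out
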