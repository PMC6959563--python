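import numpy as np
import pytest

from rhythmpencil import OscillationComponent, SyntheticSpec, simulate_cohort
from rhythmpencil.preprocess import average_replicates


@pytest.fixture
def timepoints():
    """The canonical sampling grid: 48 h at 2-h steps."""
    return np.arange(0.0, 48.0, 2.0)


@pytest.fixture
def pure_12h(timepoints):
    """Noiseless sustained 12-h cosine, amplitude 3, peak at 0 h."""
    return 3.0 * np.cos(2 * np.pi * timepoints / 12.0)


@pytest.fixture
def mixed_24_12(timepoints):
    """Damped 24-h plus growing 12-h component (known parameters)."""
    t = timepoints
    return (
        2.0 * 0.9 ** (t / 24.0) * np.cos(2 * np.pi * t / 24.0 - np.pi / 2)
        + 1.0 * 1.1 ** (t / 12.0) * np.cos(2 * np.pi * t / 12.0)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Averaged noiseless 150-gene cohort with its ground truth."""
    spec = SyntheticSpec(n_genes=150, noise_sd=0.0, seed=77)
    matrix, truth = simulate_cohort(spec)
    return average_replicates(matrix), truth


def random_components(rng, n, period_range=(6.0, 30.0), min_separation=1.2,
                      decay_range=(0.85, 1.15), amp_log10_range=(-1.0, 1.0)):
    """Random well-separated damped-sinusoid parameter sets."""
    while True:
        periods = np.sort(rng.uniform(*period_range, n))[::-1]
        if all(periods[i] / periods[i + 1] >= min_separation for i in range(n - 1)):
            break
    amps = 10.0 ** rng.uniform(*amp_log10_range, n)
    if amps.max() / amps.min() > 100:
        amps = np.clip(amps, amps.max() / 100, None)
    decays = rng.uniform(*decay_range, n)
    peaks = rng.uniform(0, periods)
    return [
        OscillationComponent.from_peak_time(T, d, A, p)
        for T, d, A, p in zip(periods, decays, amps, peaks)
    ]
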