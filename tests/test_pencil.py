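"""Matrix-pencil decomposition: parameter recovery and invariances."""

import numpy as np
import pytest

from rhythmpencil import (
    OscillationComponent,
    biological_phase,
    decompose,
    reconstruct,
    remove_components,
)
from conftest import random_components


def assert_component_close(got, want, rtol=1e-6):
    assert got.period == pytest.approx(want.period, rel=rtol)
    assert got.decay == pytest.approx(want.decay, rel=rtol)
    assert got.amplitude == pytest.approx(want.amplitude, rel=rtol)
    # peak time compared on the circle
    delta = abs(got.peak_time - want.peak_time)
    delta = min(delta, want.period - delta)
    assert delta <= rtol * want.period


class TestDecompose:
    def test_constant_series_has_no_components(self, timepoints):
        dec = decompose(np.full(24, 5.0), dt=2.0)
        assert dec.mean == pytest.approx(5.0)
        assert dec.components == ()
        assert dec.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_pure_cosine_recovered_exactly(self, timepoints, pure_12h):
        dec = decompose(pure_12h, dt=2.0)
        assert len(dec.components) == 1
        c = dec.components[0]
        assert c.period == pytest.approx(12.0, abs=1e-6)
        assert c.decay == pytest.approx(1.0, abs=1e-6)
        assert c.amplitude == pytest.approx(3.0, abs=1e-6)
        assert min(c.peak_time, 12.0 - c.peak_time) == pytest.approx(0.0, abs=1e-6)

    def test_two_component_mixture_recovered(self, timepoints, mixed_24_12):
        dec = decompose(mixed_24_12, dt=2.0)
        assert len(dec.components) == 2
        by_period = sorted(dec.components, key=lambda c: -c.period)
        want = [
            OscillationComponent.from_peak_time(24.0, 0.9, 2.0, 6.0),
            OscillationComponent.from_peak_time(12.0, 1.1, 1.0, 0.0),
        ]
        for got, exp in zip(by_period, want):
            assert_component_close(got, exp)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            decompose(np.arange(10.0), dt=2.0, k=3)

    def test_nonfinite_rejected(self):
        x = np.ones(24)
        x[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            decompose(x, dt=2.0)

    def test_components_ranked_by_amplitude(self, timepoints):
        t = timepoints
        x = 1.0 * np.cos(2 * np.pi * t / 24) + 4.0 * np.cos(2 * np.pi * t / 12)
        dec = decompose(x, dt=2.0)
        amps = [c.amplitude for c in dec.components]
        assert amps == sorted(amps, reverse=True)
        assert dec.components[0].period == pytest.approx(12.0, abs=1e-6)

    @pytest.mark.parametrize("n_comp", [1, 2, 3])
    def test_random_signal_oracle(self, timepoints, n_comp):
        """Forward-simulated random signals are recovered to 1e-6 relative."""
        rng = np.random.default_rng(1000 + n_comp)
        for _ in range(60):
            comps = random_components(rng, n_comp)
            x = rng.uniform(0, 10) + sum(c.evaluate(timepoints) for c in comps)
            dec = decompose(x, dt=2.0)
            assert len(dec.components) == n_comp
            got = sorted(dec.components, key=lambda c: -c.period)
            for g, w in zip(got, comps):
                assert_component_close(g, w)

    def test_scale_equivariance(self, timepoints, mixed_24_12):
        base = decompose(mixed_24_12, dt=2.0)
        scaled = decompose(3.5 * mixed_24_12, dt=2.0)
        for b, s in zip(base.components, scaled.components):
            assert s.amplitude == pytest.approx(3.5 * b.amplitude, rel=1e-8)
            assert s.period == pytest.approx(b.period, rel=1e-8)
            assert s.decay == pytest.approx(b.decay, rel=1e-8)
            delta = abs(s.peak_time - b.peak_time)
            assert min(delta, b.period - delta) == pytest.approx(0.0, abs=1e-6)

    def test_time_shift_rotates_phase(self, timepoints):
        """Dropping the first sample rotates phi by 2*pi*dt/T and keeps T, d."""
        t = timepoints
        x = 2.0 * np.cos(2 * np.pi * t / 12 + 0.7)
        full = decompose(x, dt=2.0).components[0]
        shifted = decompose(x[1:], dt=2.0).components[0]
        assert shifted.period == pytest.approx(full.period, rel=1e-8)
        assert shifted.decay == pytest.approx(full.decay, rel=1e-8)
        expected_phase = (full.phase + 2 * np.pi * 2.0 / 12.0) % (2 * np.pi)
        assert shifted.phase == pytest.approx(expected_phase, rel=1e-6)

    def test_noisy_12h_period_within_half_hour(self, timepoints):
        """At amplitude-to-noise 5, period error stays within 0.5 h mostly."""
        rng = np.random.default_rng(5)
        hits = total = 0
        for _ in range(200):
            x = 5.0 + 2.0 * np.cos(2 * np.pi * (timepoints - rng.uniform(0, 12)) / 12)
            x = x + rng.normal(0, 0.4, timepoints.size)
            dec = decompose(x, dt=2.0)
            near = [c for c in dec.components if abs(c.period - 12) < 3]
            total += 1
            if near and abs(max(near, key=lambda c: c.amplitude).period - 12) <= 0.5:
                hits += 1
        assert hits / total >= 0.9


class TestReconstruct:
    def test_empty_include_gives_constant_mean(self, timepoints, mixed_24_12):
        dec = decompose(mixed_24_12, dt=2.0)
        out = reconstruct(dec, timepoints, include=[])
        assert np.allclose(out, dec.mean)

    def test_round_trip(self, timepoints, mixed_24_12):
        dec = decompose(mixed_24_12, dt=2.0)
        assert np.allclose(reconstruct(dec, timepoints), mixed_24_12, atol=1e-8)

    def test_unknown_component_index_rejected(self, timepoints, pure_12h):
        dec = decompose(pure_12h, dt=2.0)
        with pytest.raises(IndexError, match="unknown component"):
            reconstruct(dec, timepoints, include=[5])

    def test_single_component_peak_value(self, timepoints):
        c = OscillationComponent.from_peak_time(12.0, 0.95, 2.0, 3.0)
        x = 4.0 + c.evaluate(timepoints)
        dec = decompose(x, dt=2.0)
        got = reconstruct(dec, np.array([c.peak_time]), include=[0])[0]
        assert got == pytest.approx(4.0 + 2.0 * 0.95 ** (3.0 / 12.0), rel=1e-6)


class TestRemoveComponents:
    def test_pure_12h_unchanged_when_removing_circadian(self, timepoints, pure_12h):
        dec = decompose(pure_12h, dt=2.0)
        out = remove_components(pure_12h, dec, (21.0, 25.0), timepoints)
        assert np.allclose(out, pure_12h, atol=1e-8)

    def test_removing_circadian_leaves_12h_part(self, timepoints, mixed_24_12):
        dec = decompose(mixed_24_12, dt=2.0)
        out = remove_components(mixed_24_12, dec, (21.0, 25.0), timepoints)
        want = 1.1 ** (timepoints / 12.0) * np.cos(2 * np.pi * timepoints / 12.0)
        assert np.allclose(out, want, atol=1e-6)

    def test_remove_everything_leaves_mean_plus_residual(self, timepoints, mixed_24_12):
        dec = decompose(mixed_24_12, dt=2.0)
        out = remove_components(mixed_24_12, dec, (0.0, np.inf), timepoints)
        assert np.allclose(out, dec.mean, atol=1e-8)

    def test_inverted_window_rejected(self, timepoints, pure_12h):
        dec = decompose(pure_12h, dt=2.0)
        with pytest.raises(ValueError, match="inverted"):
            remove_components(pure_12h, dec, (25.0, 21.0), timepoints)


@pytest.mark.parametrize(
    "phase,period,expected",
    [(0.0, 12.0, 0.0), (np.pi, 12.0, 6.0), (np.pi / 2, 12.0, 9.0)],
)
def test_biological_phase(phase, period, expected):
    c = OscillationComponent(period=period, decay=1.0, amplitude=1.0, phase=phase)
    assert biological_phase(c) == pytest.approx(expected)
    assert 0 <= c.peak_time < period
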