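"""Synthetic-cohort generator: forward model, truth bookkeeping, effects."""

import numpy as np
import pytest

from rhythmpencil import (
    EffectModel,
    OscillationComponent,
    SyntheticSpec,
    decompose,
    simulate_cohort,
    simulate_coverage_profile,
    simulate_series,
    simulate_two_conditions,
)
from rhythmpencil.synthetic import TWELVE_H_BAND


class TestSimulateSeries:
    def test_no_components_gives_constant(self, timepoints):
        out = simulate_series([], 5.0, 0.0, timepoints, replicates=2)
        assert out.shape == (24, 2)
        assert np.allclose(out, 5.0)

    def test_cosine_extrema(self, timepoints):
        c = OscillationComponent.from_peak_time(12.0, 1.0, 3.0, 0.0)
        out = simulate_series([c], 0.0, 0.0, timepoints)[:, 0]
        assert out[0] == pytest.approx(3.0)   # t=0 peak
        assert out[3] == pytest.approx(-3.0)  # t=6 trough

    def test_same_seed_identical(self, timepoints):
        c = OscillationComponent.from_peak_time(24.0, 1.0, 1.0, 3.0)
        a = simulate_series([c], 2.0, 0.5, timepoints, 2, seed=9)
        b = simulate_series([c], 2.0, 0.5, timepoints, 2, seed=9)
        assert np.array_equal(a, b)

    def test_nonuniform_timepoints_rejected_naming_gap(self):
        with pytest.raises(ValueError, match="gap"):
            simulate_series([], 1.0, 0.0, [0.0, 2.0, 5.0])

    def test_decompose_inverts_forward_model(self, timepoints):
        """The generator and the estimator agree on the signal model."""
        c = OscillationComponent.from_peak_time(12.0, 0.95, 2.0, 4.0)
        x = simulate_series([c], 6.0, 0.0, timepoints)[:, 0]
        dec = decompose(x, dt=2.0)
        assert dec.components[0].period == pytest.approx(12.0, rel=1e-8)
        assert dec.components[0].peak_time == pytest.approx(4.0, rel=1e-6)


class TestSimulateCohort:
    def test_all_null_has_no_components(self):
        spec = SyntheticSpec(
            n_genes=100, class_fractions={"null": 1.0}, seed=1
        )
        _, truth = simulate_cohort(spec)
        assert all(g.components == () for g in truth)

    def test_twelvehour_only_periods_in_band(self):
        spec = SyntheticSpec(
            n_genes=50, class_fractions={"twelvehour": 1.0}, seed=2
        )
        _, truth = simulate_cohort(spec)
        lo, hi = TWELVE_H_BAND
        for g in truth:
            assert len(g.components) == 1
            assert lo <= g.components[0].period <= hi

    def test_subthreshold_means_below_background(self):
        spec = SyntheticSpec(
            n_genes=40, class_fractions={"subthreshold": 1.0}, seed=3
        )
        _, truth = simulate_cohort(spec)
        assert all(g.mean < 0.1 for g in truth)

    def test_fixed_seed_reproducible(self):
        spec = SyntheticSpec(n_genes=30, seed=11)
        m1, _ = simulate_cohort(spec)
        m2, _ = simulate_cohort(SyntheticSpec(n_genes=30, seed=11))
        assert np.array_equal(m1.values, m2.values)

    def test_class_fractions_within_binomial_error(self):
        spec = SyntheticSpec(n_genes=3000, seed=4)
        _, truth = simulate_cohort(spec)
        counts = {}
        for g in truth:
            counts[g.class_label] = counts.get(g.class_label, 0) + 1
        for cls, frac in spec.class_fractions.items():
            n = counts.get(cls, 0)
            sd = np.sqrt(3000 * frac * (1 - frac))
            assert abs(n - 3000 * frac) <= 4 * sd, cls

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SyntheticSpec(n_genes=0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticSpec(n_genes=10, class_fractions={"null": 0.7})


class TestSimulateTwoConditions:
    def test_default_effect_proportions_sum_to_one(self):
        model = EffectModel(abolished=0.545, dampened=0.316, increased=0.139)
        assert model.abolished + model.dampened + model.increased == pytest.approx(1.0)

    def test_dampening_factor_must_shrink(self):
        with pytest.raises(ValueError, match="dampening factor"):
            EffectModel(dampen_factor=1.0)

    def test_abolished_zeroes_the_12h_amplitude(self):
        spec = SyntheticSpec(
            n_genes=60, class_fractions={"mixed": 1.0}, seed=5
        )
        _, _, truth = simulate_two_conditions(spec)
        lo, hi = TWELVE_H_BAND
        for g in truth:
            twelve_b = [c for c in g.components_b if lo <= c.period <= hi]
            if g.effect == "abolished":
                assert all(c.amplitude == 0.0 for c in twelve_b)
            elif g.effect == "dampened":
                twelve_a = [c for c in g.components if lo <= c.period <= hi]
                assert twelve_b[0].amplitude == pytest.approx(
                    0.5 * twelve_a[0].amplitude
                )

    def test_effect_labels_partition_exactly(self):
        spec = SyntheticSpec(
            n_genes=1000, class_fractions={"twelvehour": 1.0}, seed=6
        )
        _, _, truth = simulate_two_conditions(spec)
        counts = {}
        for g in truth:
            counts[g.effect] = counts.get(g.effect, 0) + 1
        assert counts["abolished"] == 545
        assert counts["dampened"] == 316
        assert counts["increased"] == 139

    def test_non_12h_components_identical_between_conditions(self):
        spec = SyntheticSpec(
            n_genes=40, class_fractions={"mixed": 1.0}, seed=7
        )
        _, _, truth = simulate_two_conditions(spec)
        lo, hi = TWELVE_H_BAND
        for g in truth:
            for a, b in zip(g.components, g.components_b):
                if not lo <= a.period <= hi:
                    assert a == b

    def test_unchanged_genes_differ_only_by_noise(self):
        spec = SyntheticSpec(
            n_genes=30, class_fractions={"twelvehour": 1.0},
            noise_sd=0.0, seed=8,
        )
        spec.effect_model = EffectModel(
            abolished=0.0, dampened=0.0, increased=0.0, unchanged=1.0,
            dampen_factor=0.5,
        )
        mat_a, mat_b, _ = simulate_two_conditions(spec)
        assert np.allclose(mat_a.values, mat_b.values)


class TestSimulateCoverageProfile:
    def test_two_plateaus_no_noise(self):
        p = simulate_coverage_profile(2.0, 1.0, 50, 100, noise_sd=0.0)
        assert len(p) == 150
        assert p.boundary == 50
        assert set(np.unique(p.density)) == {1.0, 2.0}

    def test_same_seed_identical(self):
        a = simulate_coverage_profile(2.0, 1.0, 50, 100, noise_sd=0.3, seed=1)
        b = simulate_coverage_profile(2.0, 1.0, 50, 100, noise_sd=0.3, seed=1)
        assert np.array_equal(a.density, b.density)

    def test_zero_body_length_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            simulate_coverage_profile(2.0, 1.0, 50, 0)

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            simulate_coverage_profile(-1.0, 1.0, 50, 100)
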