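"""Sample entropy, quadratic sample entropy and tolerance resolution."""

import math

import numpy as np
import pytest

from conftest import sampen_bruteforce
from gmse import (EntropyParams, quadratic_sample_entropy, resolve_r,
                  sample_entropy)


class TestResolveR:
    def test_percent_of_sd(self):
        ref = np.array([0.7, 0.8, 0.9, 0.85, 0.75])
        params = resolve_r(ref, EntropyParams(r_mode="percent_of_sd",
                                              r_value=0.5))
        assert params.resolved_r == pytest.approx(
            0.005 * np.std(ref, ddof=1), rel=1e-12)

    def test_fixed_absolute(self):
        params = resolve_r([], EntropyParams(r_mode="fixed_absolute",
                                             r_value=0.0002))
        assert params.resolved_r == 0.0002

    def test_reference_series_mode(self, rng):
        ref = rng.standard_normal(100)
        params = resolve_r(ref, EntropyParams(
            r_mode="percent_of_reference_series", r_value=20.0))
        assert params.resolved_r == pytest.approx(
            0.2 * np.std(ref, ddof=1), rel=1e-12)

    def test_constant_reference_errors(self):
        with pytest.raises(ValueError, match="zero"):
            resolve_r(np.full(50, 0.8), EntropyParams(r_value=0.5))

    def test_inputs_not_mutated(self):
        p = EntropyParams(r_value=0.5)
        resolve_r([0.0, 1.0], p)
        assert p.resolved_r is None

    @pytest.mark.parametrize("kwargs", [dict(m=0), dict(m=-1),
                                        dict(r_value=0.0),
                                        dict(r_mode="percent_of_variance")])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            EntropyParams(**kwargs)


class TestSampleEntropy:
    def test_constant_series_zero(self):
        est = sample_entropy(np.full(50, 3.3), m=2, r=0.1)
        assert est.value == 0.0
        assert est.matches_m == est.matches_m1 > 0

    def test_period_two_signal_zero(self):
        x = np.tile([0.5, 1.0], 25)
        est = sample_entropy(x, m=2, r=0.3)
        assert est.value == 0.0

    def test_equals_bruteforce_exactly(self, rng):
        for _ in range(25):
            n = int(rng.integers(30, 120))
            x = rng.standard_normal(n)
            m = int(rng.integers(1, 4))
            r = float(rng.uniform(0.05, 0.8))
            b, a, v = sampen_bruteforce(x, m, r)
            est = sample_entropy(x, m=m, r=r)
            assert (est.matches_m, est.matches_m1) == (b, a)
            assert est.n_templates == n - m
            if est.defined:
                assert est.value == pytest.approx(v, rel=1e-12)

    def test_nonincreasing_in_r(self, rng):
        x = rng.standard_normal(400)
        values = [sample_entropy(x, 2, r).value
                  for r in (0.1, 0.2, 0.4, 0.8, 1.6)]
        assert all(u >= w - 1e-12 for u, w in zip(values, values[1:]))

    def test_shift_invariance(self, rng):
        x = rng.standard_normal(300)
        e1 = sample_entropy(x, 2, 0.25)
        e2 = sample_entropy(x + 17.3, 2, 0.25)
        assert (e1.matches_m, e1.matches_m1) == (e2.matches_m, e2.matches_m1)

    def test_joint_scale_invariance(self, rng):
        x = rng.standard_normal(300)
        c = 4.2
        e1 = sample_entropy(x, 2, 0.25)
        e2 = sample_entropy(c * x, 2, c * 0.25)
        assert (e1.matches_m, e1.matches_m1) == (e2.matches_m, e2.matches_m1)

    def test_undefined_flagged_not_raised(self, rng):
        x = rng.standard_normal(50)
        est = sample_entropy(x, 2, 1e-12)
        assert not est.defined
        assert math.isnan(est.value)

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="too short"):
            sample_entropy(np.arange(3.0), m=2, r=0.1)

    def test_nonfinite_errors(self):
        with pytest.raises(ValueError, match="non-finite"):
            sample_entropy(np.array([1.0, np.nan, 2.0, 3.0, 4.0]), 2, 0.1)

    @pytest.mark.parametrize("m, r", [(0, 0.1), (2, 0.0), (2, -1.0)])
    def test_invalid_arguments(self, m, r):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(20.0), m=m, r=r)

    def test_strict_inequality_at_exact_ties(self):
        # distances exactly equal to r must NOT match under "< r"
        x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        tie = sample_entropy(x, 1, 1.0)       # all cross-level d == 1.0
        above = sample_entropy(x, 1, 1.0 + 1e-9)
        assert tie.matches_m < above.matches_m


class TestQuadraticSampleEntropy:
    def test_constant_series_with_half_tolerance(self):
        est = quadratic_sample_entropy(np.full(40, 1.0), m=2, r=0.5)
        assert est.value == 0.0  # SampEn 0 + ln(2*0.5)

    def test_definitional_offset(self, rng):
        x = rng.standard_normal(200)
        se = sample_entropy(x, 2, 0.1)
        qse = quadratic_sample_entropy(x, 2, 0.1)
        assert qse.value == pytest.approx(se.value + math.log(0.2), rel=1e-12)
        assert (qse.matches_m, qse.matches_m1) == (se.matches_m, se.matches_m1)

    def test_undefined_propagates(self, rng):
        x = rng.standard_normal(40)
        est = quadratic_sample_entropy(x, 2, 1e-12)
        assert not est.defined
        assert math.isnan(est.value)
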