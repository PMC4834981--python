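"""Multiscale-entropy orchestration and the complexity index."""

import numpy as np
import pytest

from gmse import (ComplexityIndex, EntropyEstimate, EntropyParams, MSECurve,
                  coarse_grain, complexity_index, mse_curve, resolve_r,
                  sample_entropy)
from gmse.synth import white_gaussian


def make_curve(values, start=10):
    entries = {
        start + i: EntropyEstimate(
            value=float("nan") if v is None else float(v), m=2, r=0.01,
            n_templates=100, matches_m=0 if v is None else 50,
            matches_m1=0 if v is None else 20)
        for i, v in enumerate(values)
    }
    return MSECurve("variance", entries, EntropyParams(resolved_r=0.01))


class TestMSECurve:
    def test_composition_adds_nothing(self):
        """The orchestration must equal independent step-by-step
        coarse-grain + entropy calls sharing one resolved tolerance."""
        x = white_gaussian(50_000, seed=3)
        params = EntropyParams(m=2, r_mode="percent_of_sd", r_value=0.5)
        curve = mse_curve(x, "variance", range(10, 101), params)
        resolved = resolve_r(x, params)
        for tau in (10, 37, 64, 100):
            cg = coarse_grain(x, tau, "variance").values
            est = sample_entropy(cg, m=2, r=resolved.resolved_r)
            got = curve.entries[tau]
            assert (got.matches_m, got.matches_m1) == (est.matches_m,
                                                       est.matches_m1)
            np.testing.assert_array_equal(got.value, est.value)  # NaN-aware
            assert got.r == resolved.resolved_r

    def test_constant_series_variance_curve_is_zero(self):
        x = np.full(3000, 0.8)
        params = EntropyParams(m=2, r_mode="fixed_absolute", r_value=0.0002)
        curve = mse_curve(x, "variance", range(2, 21), params)
        assert all(e.defined and e.value == 0.0 for e in curve.entries.values())

    def test_variance_at_scale_one_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            mse_curve(white_gaussian(1000, seed=0), "variance", [1, 2, 3],
                      EntropyParams(r_value=0.5))

    def test_infeasible_scale_names_maximum(self):
        x = white_gaussian(400, seed=1)
        with pytest.raises(ValueError, match="scale <= 100"):
            mse_curve(x, "variance", range(10, 201),
                      EntropyParams(m=2, r_value=0.5))

    def test_additive_shift_invariance(self):
        """Both coarse-graining moments and the SD-based tolerance are
        location-free, so the curve is unchanged by a constant offset."""
        x = white_gaussian(4000, seed=6)
        for moment in ("mean", "variance"):
            p = EntropyParams(m=2, r_value=15.0 if moment == "mean" else 0.5)
            c1 = mse_curve(x, moment, range(2, 11), p)
            c2 = mse_curve(x + 123.4, moment, range(2, 11), p)
            for tau in c1.scales:
                a, b = c1.entries[tau], c2.entries[tau]
                assert (a.matches_m, a.matches_m1) == (b.matches_m, b.matches_m1)

    def test_single_resolved_r_used_at_every_scale(self):
        x = white_gaussian(4000, seed=2)
        curve = mse_curve(x, "variance", range(2, 12),
                          EntropyParams(m=2, r_value=0.5))
        rs = {e.r for e in curve.entries.values()}
        assert rs == {curve.params.resolved_r}

    def test_r_per_scale_variant_records_own_r(self):
        x = white_gaussian(4000, seed=2)
        curve = mse_curve(x, "variance", range(2, 12),
                          EntropyParams(m=2, r_value=0.5), r_per_scale=True)
        for tau, e in curve.entries.items():
            cg = coarse_grain(x, tau, "variance").values
            assert e.r == pytest.approx(0.005 * np.std(cg, ddof=1), rel=1e-12)

    def test_reference_mode_requires_prior_resolution(self):
        x = white_gaussian(2000, seed=0)
        with pytest.raises(ValueError, match="reference"):
            mse_curve(x, "variance", range(2, 6),
                      EntropyParams(r_mode="percent_of_reference_series",
                                    r_value=10.0))

    def test_short_series_warning(self):
        x = white_gaussian(500, seed=4)
        with pytest.warns(UserWarning, match="coarse-grained points"):
            mse_curve(x, "variance", range(2, 11),
                      EntropyParams(m=2, r_value=0.5))

    def test_scales_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            mse_curve(white_gaussian(1000, seed=0), "variance", [10, 10, 11],
                      EntropyParams(r_value=0.5))


class TestComplexityIndex:
    def test_sum_of_zeros(self):
        ci = complexity_index(make_curve([0.0] * 91), 10, 100)
        assert ci.value == 0.0
        assert ci.n_defined == 91

    def test_91_inclusive_scales(self):
        ci = complexity_index(make_curve([1.0] * 91), 10, 100)
        assert ci.value == 91.0
        assert ci.scale_max - ci.scale_min + 1 == 91

    def test_strict_names_missing_scale(self):
        values = [1.0] * 91
        values[57 - 10] = None
        with pytest.raises(ValueError, match="57"):
            complexity_index(make_curve(values), 10, 100, policy="strict")

    def test_skip_undefined_accounting(self):
        values = [1.0] * 91
        values[57 - 10] = None
        ci = complexity_index(make_curve(values), 10, 100,
                              policy="skip_undefined")
        assert ci.value == 90.0
        assert ci.undefined_scales == (57,)
        assert ci.n_defined + len(ci.undefined_scales) == 91

    def test_additivity_over_adjacent_ranges(self, rng):
        curve = make_curve(rng.standard_normal(91))
        whole = complexity_index(curve, 10, 100).value
        left = complexity_index(curve, 10, 54).value
        right = complexity_index(curve, 55, 100).value
        assert whole == pytest.approx(left + right, abs=1e-12)

    def test_uncovered_range_errors(self):
        with pytest.raises(ValueError, match="cover"):
            complexity_index(make_curve([1.0] * 5), 10, 30)

    def test_inverted_range_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            complexity_index(make_curve([1.0] * 5), 14, 10)

    def test_unknown_policy(self):
        with pytest.raises(ValueError, match="policy"):
            complexity_index(make_curve([1.0] * 5), 10, 14, policy="drop")

    def test_consistency_invariant_enforced(self):
        with pytest.raises(ValueError):
            ComplexityIndex(value=1.0, scale_min=10, scale_max=12,
                            n_defined=1, undefined_scales=())
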