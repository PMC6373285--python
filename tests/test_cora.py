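import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from headfsi.cora import (
    CoraConfig,
    RatingComponents,
    aggregate_cases,
    classify_biofidelity,
    combine_components,
    corridor_rating,
    phase_rating,
    rate_pair,
    shape_rating,
    size_rating,
)
from headfsi.signals import SignalCurve
from headfsi.synthetic import PerturbationSpec, perturb_curve

from conftest import random_pair
from cora_oracle import brute_corridor, brute_phase, brute_shape, brute_size


def shift_curve(ref: SignalCurve, delay: float) -> SignalCurve:
    """Delayed copy on the reference grid (edge-clamped)."""
    vals = np.interp(ref.times - delay, ref.times, ref.values)
    return SignalCurve(ref.times, vals)


class TestCorridor:
    def test_identical_scores_ten(self, haversine_ref, cora_config):
        assert corridor_rating(haversine_ref, haversine_ref, cora_config) == 10.0

    def test_far_outside_scores_zero(self, haversine_ref, cora_config):
        y = np.max(np.abs(haversine_ref.values))
        off = SignalCurve(haversine_ref.times,
                          haversine_ref.values + 2 * cora_config.b0 * y)
        assert corridor_rating(haversine_ref, off, cora_config) == 0.0

    def test_mid_band_offset_scores_analytically(self, haversine_ref, cora_config):
        # every sample sits exactly mid-way between the corridors:
        # score = 10 * 0.5**k_c = 2.5 for k_c = 2
        y = np.max(np.abs(haversine_ref.values))
        di, do = cora_config.a0 * y, cora_config.b0 * y
        test = SignalCurve(haversine_ref.times,
                           haversine_ref.values + di + 0.5 * (do - di))
        c1 = corridor_rating(haversine_ref, test, cora_config)
        assert c1 == pytest.approx(2.5, abs=1e-9)

    def test_flat_zero_reference_rejected(self, cora_config):
        flat = SignalCurve([0, 0.1, 0.2], [0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate reference"):
            corridor_rating(flat, flat, cora_config)


class TestPhase:
    def test_identical_zero_shift_full_score(self, haversine_ref, cora_config):
        shift, p = phase_rating(haversine_ref, haversine_ref, cora_config)
        assert shift == 0.0
        assert p == 10.0

    def test_outer_band_delay_scores_zero(self, haversine_ref, cora_config):
        delay = cora_config.d_max * haversine_ref.duration
        shift, p = phase_rating(haversine_ref, shift_curve(haversine_ref, delay),
                                cora_config)
        assert p == 0.0

    def test_mid_band_delay_scores_five(self, haversine_ref, cora_config):
        delay = 0.5 * (cora_config.d_min + cora_config.d_max) * haversine_ref.duration
        _, p = phase_rating(haversine_ref, shift_curve(haversine_ref, delay),
                            cora_config)
        # one-sample quantization band around the exact value
        dt = haversine_ref.sample_interval
        quant = 10.0 * dt / ((cora_config.d_max - cora_config.d_min)
                             * haversine_ref.duration)
        assert p == pytest.approx(5.0, abs=quant)

    def test_short_window_rejected(self, cora_config):
        tiny = SignalCurve([0.0, 0.1], [1.0, 2.0])
        with pytest.raises(ValueError):
            phase_rating(tiny, tiny, cora_config)


class TestShapeAndSize:
    def test_identical_and_negated(self, haversine_ref, cora_config):
        assert shape_rating(haversine_ref, haversine_ref, 0.0, cora_config) == 10.0
        neg = SignalCurve(haversine_ref.times, -haversine_ref.values)
        assert shape_rating(haversine_ref, neg, 0.0, cora_config) == 0.0

    def test_shape_is_scale_invariant(self, haversine_ref, cora_config):
        tripled = SignalCurve(haversine_ref.times, 3 * haversine_ref.values)
        assert shape_rating(haversine_ref, tripled, 0.0, cora_config) == pytest.approx(10.0)

    def test_size_doubling_gives_quarter_ratio(self, haversine_ref, cora_config):
        doubled = SignalCurve(haversine_ref.times, 2 * haversine_ref.values)
        assert size_rating(haversine_ref, doubled, 0.0, cora_config) == pytest.approx(2.5)

    def test_size_near_unity(self, haversine_ref, cora_config):
        near = SignalCurve(haversine_ref.times, 0.999 * haversine_ref.values)
        assert size_rating(haversine_ref, near, 0.0, cora_config) > 9.9


class TestCombineAndAggregate:
    @pytest.mark.parametrize("comps, expected", [
        ((8.0, 8.0, 8.0, 8.0), 8.0),
        ((10.0, 10.0, 10.0, 10.0), 10.0),
        ((7.24, 4.99, 6.51, 3.65), 5.5975),  # printed per-case components
    ])
    def test_equal_weight_mean(self, comps, expected):
        assert combine_components(*comps) == pytest.approx(expected)

    def test_aggregate_matches_published_averages(self):
        # FSI-model per-case B and V rows of the relative-displacement table
        cases_b = [5.30, 5.60, 6.27]
        cases_v = [6.43, 7.24, 7.85]
        rcs = [RatingComponents(V=v, G=5, P=5, C1=5, B=b)
               for v, b in zip(cases_v, cases_b)]
        avg = aggregate_cases(rcs).rounded()
        assert avg.B == pytest.approx(5.72)
        assert avg.V == pytest.approx(7.17)

    def test_aggregate_single_case_identity(self):
        rc = RatingComponents(1.0, 2.0, 3.0, 4.0, 2.5)
        assert aggregate_cases([rc]) == rc

    def test_aggregate_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_cases([])


class TestClassification:
    @pytest.mark.parametrize("b, label", [
        (9.43, "Excellent"),
        (8.6, "Excellent"),
        (5.72, "Fair"),
        (6.5, "Good"),
        (4.5, "Fair"),
        (2.6, "Marginal"),
        (0.0, "Unacceptable"),
        (10.0, "Excellent"),
    ])
    def test_bins(self, b, label):
        assert classify_biofidelity(b) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_biofidelity(10.5)


class TestFullRatingProperties:
    def test_self_rating_is_perfect(self, haversine_ref):
        rc = rate_pair(haversine_ref, haversine_ref)
        assert (rc.V, rc.G, rc.P, rc.C1, rc.B) == (10.0, 10.0, 10.0, 10.0, 10.0)

    def test_pure_scaling_hits_size_not_shape(self, haversine_ref):
        scaled = perturb_curve(haversine_ref, PerturbationSpec(amplitude_scale=2.0))
        rc = rate_pair(haversine_ref, scaled)
        assert rc.V == pytest.approx(10.0)
        assert rc.P == pytest.approx(10.0)  # shift 0
        assert rc.G == pytest.approx(2.5)
        assert rc.C1 < 10.0

    def test_pure_shift_degrades_phase_monotonically(self, haversine_ref, cora_config):
        t_len = haversine_ref.duration
        delays = [0.02, 0.05, 0.08, 0.11]
        scores = []
        for frac in delays:
            rc = rate_pair(haversine_ref, shift_curve(haversine_ref, frac * t_len),
                           cora_config)
            scores.append(rc.P)
            assert rc.V == pytest.approx(10.0, abs=0.15)  # one-sample quantization
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_scores_bounded_for_random_pairs(self, rng):
        for _ in range(20):
            ref, test = random_pair(rng)
            rc = rate_pair(ref, test)
            for v in (rc.V, rc.G, rc.P, rc.C1, rc.B):
                assert 0.0 <= v <= 10.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_component_scores_match_brute_force(self, seed):
        """Vectorised ratings agree with literal per-sample loops to 1e-9."""
        rng = np.random.default_rng(seed)
        ref, test = random_pair(rng)
        cfg = CoraConfig()
        dt = ref.sample_interval
        r, t = ref.values.tolist(), test.values.tolist()

        assert corridor_rating(ref, test, cfg) == pytest.approx(
            brute_corridor(r, t, cfg), abs=1e-9)
        shift, p = phase_rating(ref, test, cfg)
        bshift, bp = brute_phase(r, t, cfg, dt)
        assert shift == pytest.approx(bshift, abs=1e-12)
        assert p == pytest.approx(bp, abs=1e-9)
        assert shape_rating(ref, test, shift, cfg) == pytest.approx(
            brute_shape(r, t, shift, cfg, dt), abs=1e-9)
        assert size_rating(ref, test, shift, cfg) == pytest.approx(
            brute_size(r, t, shift, cfg, dt), abs=1e-9)
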