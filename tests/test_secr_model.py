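"""Encounter model, likelihoods and the exact-enumeration oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import camsecr as cs
from camsecr.captures import CaptureArray
from camsecr.secr_model import LatentState, _loglik_one


def _params(lambda0=0.029, sigma=1.69, b1=1.10, psi=0.5):
    return cs.ModelParams(lambda0, sigma, b1, psi)


class TestEncounterFunction:
    def test_baseline_rate_at_zero_distance(self):
        assert cs.encounter_rate(_params(), 0.0, 0) == pytest.approx(0.029)

    def test_rate_vanishes_far_away(self):
        assert cs.encounter_rate(_params(), 1e3, 0) == pytest.approx(0.0, abs=1e-12)

    def test_no_behavioural_effect_when_b1_zero(self):
        p = _params(b1=0.0)
        assert cs.encounter_rate(p, 0.7, 0) == cs.encounter_rate(p, 0.7, 1)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            cs.encounter_rate(_params(), -0.1, 0)

    def test_pre_encounter_probability_three_sf(self):
        p1 = cs.encounter_probability(_params(), 0.0, 0)
        assert float(f"{p1:.3g}") == 0.0286

    def test_post_encounter_probability_direct_evaluation(self):
        p2 = cs.encounter_probability(_params(), 0.0, 1)
        assert p2 == pytest.approx(1 - math.exp(-0.029 * math.e ** 1.10), abs=1e-12)
        assert p2 == pytest.approx(0.0834, abs=5e-4)

    def test_zero_rate_gives_zero_probability(self):
        assert cs.encounter_probability(cs.ModelParams(0.0, 1.0), 2.0, 0) == 0.0

    @given(st.floats(0, 5), st.floats(0.01, 5), st.floats(0.1, 3))
    def test_probability_monotone_in_distance(self, d, dd, sigma):
        p = _params(sigma=sigma)
        assert cs.encounter_probability(p, d, 0) >= cs.encounter_probability(p, d + dd, 0)

    @given(st.floats(0.001, 1), st.floats(0.001, 1), st.floats(0, 3))
    def test_probability_monotone_in_rate_and_behaviour(self, l0, dl, b1):
        assert cs.encounter_probability(_params(l0 + dl, b1=b1), 1.0, 0) >= \
            cs.encounter_probability(_params(l0, b1=b1), 1.0, 0)
        assert cs.encounter_probability(_params(l0, b1=b1), 1.0, 1) >= \
            cs.encounter_probability(_params(l0, b1=0.0), 1.0, 1)


class TestSigmaConversions:
    def test_roundtrip(self):
        assert cs.b_to_sigma(cs.sigma_to_b(1.69)) == pytest.approx(1.69)

    def test_conventions_differ(self):
        # the printed convention sigma = 1/|b| vs conventional sqrt(1/(2b))
        assert cs.sigma_from_printed_b(2.0) == pytest.approx(0.5)
        assert cs.b_to_sigma(2.0) == pytest.approx(0.5)
        assert cs.sigma_from_printed_b(0.5) != pytest.approx(cs.b_to_sigma(0.5))


def _tiny_arr(y, traps):
    n, J, K = y.shape
    return CaptureArray(
        y, [f"A{i}" for i in range(n)], [f"T{j}" for j in range(J)], K,
        trap_xy=np.asarray(traps, float), effort=np.ones((J, K), np.int8),
    )


class TestCompleteDataLoglik:
    def test_all_excluded_empty_history_is_zero(self, two_trap_instance):
        _, ss, arr = two_trap_instance
        # no observed individuals at all: M=2 augmented, both excluded
        y = np.zeros((0, 2, 4), np.uint8)
        empty = CaptureArray(y, [], ["T1", "T2"], 4,
                             trap_xy=arr.trap_xy, effort=arr.effort)
        lat = LatentState(np.zeros(2), np.zeros(2))
        ll = cs.complete_data_loglik(_params(), lat, empty,
                                     cs.BehaviouralIndicator(y.copy()), ss)
        assert ll == 0.0

    def test_single_capture_is_log_p(self):
        y = np.ones((1, 1, 1), np.uint8)
        arr = _tiny_arr(y, [[0.0, 0.0]])
        ss = cs.StateSpace(np.array([[0.0, 0.0]]), np.array([True]), 1.0, 1.0)
        lat = LatentState([1], [0])
        C = cs.BehaviouralIndicator(np.zeros_like(y))
        params = _params(0.5, 1.0, 0.0)
        ll = cs.complete_data_loglik(params, lat, arr, C, ss)
        assert ll == pytest.approx(math.log(cs.encounter_probability(params, 0.0, 0)))

    def test_observed_excluded_is_signalled(self, two_trap_instance):
        _, ss, arr = two_trap_instance
        lat = LatentState([0], [0])
        with pytest.raises(ValueError, match="z = 0"):
            cs.complete_data_loglik(_params(), lat, arr,
                                    cs.prior_capture_indicator(arr), ss)

    def test_matches_elementwise_bruteforce(self, two_trap_instance):
        _, ss, arr = two_trap_instance
        rng = np.random.default_rng(5)
        params = _params(0.4, 0.9, 0.6)
        C = cs.prior_capture_indicator(arr)
        M = 3
        lat = LatentState([1, 1, 0], rng.integers(0, ss.suitable.sum(), 3))
        ll = cs.complete_data_loglik(params, lat, arr, C, ss)
        # independent brute force: explicit product over every cell
        total = 0.0
        pts = ss.suitable_points
        ys = [arr.y[0], np.zeros((2, 4), np.uint8)]
        Cs = [C.C[0], np.zeros((2, 4), np.uint8)]
        for ind, (yy, cc) in enumerate(zip(ys, Cs)):
            centre = pts[lat.centres[ind]]
            for j in range(2):
                d = math.hypot(centre[0] - arr.trap_xy[j, 0], centre[1] - arr.trap_xy[j, 1])
                for k in range(4):
                    p = cs.encounter_probability(params, d, int(cc[j, k]))
                    total += math.log(p if yy[j, k] else 1 - p)
        assert ll == pytest.approx(total, abs=1e-10)

    def test_invariant_under_relabelling(self):
        rng = np.random.default_rng(8)
        y = (rng.random((3, 3, 4)) < 0.3).astype(np.uint8)
        y[:, 0, 0] = 1
        traps = rng.uniform(0, 3, (3, 2))
        arr = _tiny_arr(y, traps)
        ss = cs.build_statespace(
            [cs.TrapStation(f"T{j}", *traps[j], np.ones(4, np.int8)) for j in range(3)],
            2.0, 1.0,
        )
        params = _params(0.3, 1.2, 0.4)
        C = cs.prior_capture_indicator(arr)
        lat = LatentState([1, 1, 1], rng.integers(0, ss.suitable.sum(), 3))
        ll = cs.complete_data_loglik(params, lat, arr, C, ss)
        perm = [2, 0, 1]
        arr2 = _tiny_arr(y[perm], traps)
        C2 = cs.prior_capture_indicator(arr2)
        lat2 = LatentState([1, 1, 1], lat.centres[perm])
        ll2 = cs.complete_data_loglik(params, lat2, arr2, C2, ss)
        assert ll == pytest.approx(ll2, rel=1e-12)


class TestMarginalBruteforce:
    def test_single_point_closed_form(self):
        y = np.ones((1, 1, 1), np.uint8)
        arr = _tiny_arr(y, [[0.0, 0.0]])
        ss = cs.StateSpace(np.array([[0.0, 0.0]]), np.array([True]), 1.0, 1.0)
        params = _params(0.5, 1.0, 0.0, psi=0.7)
        ml = cs.marginal_loglik_bruteforce(params, arr, ss, M=1)
        p = cs.encounter_probability(params, 0.0, 0)
        assert ml == pytest.approx(math.log(0.7 * p))

    def test_psi_one_single_point_equals_complete_data(self):
        y = np.zeros((1, 1, 3), np.uint8)
        y[0, 0, 1] = 1
        arr = _tiny_arr(y, [[0.0, 0.0]])
        ss = cs.StateSpace(np.array([[0.0, 0.0]]), np.array([True]), 1.0, 1.0)
        params = _params(0.5, 1.0, 0.4, psi=1 - 1e-12)
        ml = cs.marginal_loglik_bruteforce(params, arr, ss, M=1)
        lat = LatentState([1], [0])
        cd = cs.complete_data_loglik(params, lat, arr,
                                     cs.prior_capture_indicator(arr), ss)
        assert ml == pytest.approx(cd, abs=1e-9)

    def test_matches_nested_loop_oracle(self, two_trap_instance):
        _, ss, arr = two_trap_instance
        params = _params(0.6, 0.8, 0.5, psi=0.4)
        M = 2
        ml = cs.marginal_loglik_bruteforce(params, arr, ss, M=M)
        # independent nested loops over every (z, centres) configuration
        pts = ss.suitable_points
        C = cs.prior_capture_indicator(arr).C
        P = len(pts)

        def hist_lik(yy, cc, centre):
            lik = 1.0
            for j in range(2):
                d = math.hypot(centre[0] - arr.trap_xy[j, 0],
                               centre[1] - arr.trap_xy[j, 1])
                for k in range(4):
                    p = cs.encounter_probability(params, d, int(cc[j, k]))
                    lik *= p if yy[j, k] else 1 - p
            return lik

        zero = np.zeros((2, 4), np.uint8)
        total = 0.0
        for z2 in (0, 1):  # augmented individual; observed forced z=1
            for c1 in range(P):
                for c2 in range(P):
                    w = params.psi * (1 / P) * hist_lik(arr.y[0], C[0], pts[c1])
                    w *= (1 / P) * (
                        params.psi * hist_lik(zero, zero, pts[c2])
                        if z2 else (1 - params.psi)
                    )
                    total += w
        assert ml == pytest.approx(math.log(total), abs=1e-9)

    def test_refuses_large_instances(self, two_trap_instance):
        _, ss, arr = two_trap_instance
        with pytest.raises(ValueError, match="too large"):
            cs.marginal_loglik_bruteforce(_params(), arr, ss, M=50)

    def test_approaches_complete_data_as_psi_to_one(self):
        y = np.ones((1, 1, 2), np.uint8)
        arr = _tiny_arr(y, [[0.0, 0.0]])
        ss = cs.StateSpace(np.array([[0.0, 0.0]]), np.array([True]), 1.0, 1.0)
        lat = LatentState([1], [0])
        cd = cs.complete_data_loglik(_params(0.5, 1.0, 0.0), lat, arr,
                                     cs.BehaviouralIndicator(np.zeros_like(y)), ss)
        prev = -np.inf
        for psi in (0.5, 0.9, 0.99):
            ml = cs.marginal_loglik_bruteforce(_params(0.5, 1.0, 0.0, psi), arr, ss, 1)
            assert ml > prev
            prev = ml
        assert prev == pytest.approx(cd, abs=0.02)


class TestPosteriorNsBruteforce:
    def test_matches_numerical_psi_integration(self, two_trap_instance):
        """Enumeration with the analytic Beta weight equals a literal
        nested-loop + numerical quadrature over psi."""
        from scipy.integrate import quad

        _, ss, arr = two_trap_instance
        params = _params(0.6, 0.8, 0.5)
        M = 3
        exact = cs.posterior_ns_bruteforce(params, arr, ss, M=M)
        pts = ss.suitable_points
        P = len(pts)
        zero = np.zeros((2, 4), np.uint8)
        l0 = sum(
            math.exp(_loglik_one(params,
                                 np.hypot(*(p - arr.trap_xy).T), zero, zero))
            for p in pts
        ) / P

        def joint(psi, k):
            A = M - 1
            return (math.comb(A, k) * (psi * l0) ** k * (1 - psi) ** (A - k) * psi)

        num = den = 0.0
        for k in range(M):
            w = quad(lambda psi: joint(psi, k), 0, 1)[0]
            num += (1 + k) * w
            den += w
        assert exact == pytest.approx(num / den, rel=1e-7)
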