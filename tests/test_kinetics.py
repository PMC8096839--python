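"""Ergodicity, loading rate, contact-time pooling, MSD and mobility."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forcefret.kinetics import (add_forces, classify_mobility,
                                ergodicity_ratio, msd_fit,
                                pool_and_fit_loading_rate,
                                pool_by_contact_time,
                                smallest_enclosing_circle)
from forcefret.simulate import simulate_force_ramp_trace


def _brownian_tracks(n_tracks, n_frames, d_um2_s, dt, eps=0.03, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_tracks):
        steps = rng.normal(0, np.sqrt(2 * d_um2_s * dt), (n_frames, 2))
        xy = np.cumsum(steps, axis=0) + rng.normal(0, eps, (n_frames, 2))
        for k in range(n_frames):
            rows.append((pid, k, xy[k, 0], xy[k, 1]))
    return pd.DataFrame(rows, columns=["particle", "pair", "x_um", "y_um"])


class TestErgodicity:
    def test_constant_trajectories_ratio_near_zero(self, params):
        recs = []
        for pid, level in enumerate([0.2, 0.3, 0.4, 0.5]):
            recs.append(pd.DataFrame({"particle": pid,
                                      "E": np.full(20, level)}))
        recs = add_forces(pd.concat(recs, ignore_index=True), params)
        res = ergodicity_ratio(recs, 50)
        assert res.ratio < 0.05

    def test_iid_forces_ratio_near_one(self, params):
        rng = np.random.default_rng(1)
        recs = []
        for pid in range(40):
            e = np.clip(rng.normal(0.42, 0.2, 50), 0.02, 0.59)
            recs.append(pd.DataFrame({"particle": pid, "E": e}))
        recs = add_forces(pd.concat(recs, ignore_index=True), params)
        res = ergodicity_ratio(recs, 50)
        assert res.ratio == pytest.approx(1.0, abs=0.05)

    def test_slow_switching_ratio_grows_with_slower_sampling(self, params):
        # two-state force switching at ~0.5/s: fast frame rates see
        # frozen levels (low ratio), slow frame rates see transitions
        rng = np.random.default_rng(2)
        ratios = {}
        for frame_rate in (50.0, 1.0):
            recs = []
            for pid in range(60):
                n, dt = 50, 1.0 / frame_rate
                state = rng.integers(0, 2)
                e = np.empty(n)
                for k in range(n):
                    if rng.random() < 0.5 * dt:
                        state = 1 - state
                    e[k] = (0.25, 0.55)[state]
                recs.append(pd.DataFrame({
                    "particle": pid,
                    "E": np.clip(e + rng.normal(0, 0.02, n), 0.01, 0.59)}))
            recs = add_forces(pd.concat(recs, ignore_index=True), params)
            ratios[frame_rate] = ergodicity_ratio(recs, frame_rate).ratio
        assert ratios[1.0] > ratios[50.0] + 0.1

    def test_no_qualifying_trajectories_raises(self, params):
        recs = add_forces(pd.DataFrame({"particle": [0] * 3,
                                        "E": [0.9] * 3}), params)
        with pytest.raises(ValueError):
            ergodicity_ratio(recs, 50)


class TestLoadingRate:
    def test_recovers_study_rate_from_seven_ramps(self, params, dyn_range):
        rng = np.random.default_rng(3)
        traces = []
        for i in range(7):
            tr = simulate_force_ramp_trace(1.5, 3.75, 10, 0.05, params,
                                           dyn_range, tail_s=4.0,
                                           seed=int(rng.integers(2 ** 31)))
            traces.append(add_forces(tr, params))
        slope, mean_trace = pool_and_fit_loading_rate(traces)
        assert slope == pytest.approx(1.5, rel=0.10)
        assert {"t_s", "force_pn"} <= set(mean_trace.columns)

    def test_noiseless_single_ramp_plus_offset_invariance(self, params):
        tr = simulate_force_ramp_trace(2.0, 4.0, 20, 0.0, params, seed=4)
        tr = add_forces(tr, params)
        shifted = tr.copy()
        shifted["t_s"] += 11.0
        slope, _ = pool_and_fit_loading_rate([tr, shifted])
        assert slope == pytest.approx(2.0, rel=1e-3)

    def test_unbiased_over_repeats(self, params, dyn_range):
        slopes = []
        for rep in range(100):
            rng = np.random.default_rng(500 + rep)
            traces = [add_forces(simulate_force_ramp_trace(
                1.5, 3.75, 10, 0.05, params, dyn_range, tail_s=4.0,
                seed=int(rng.integers(2 ** 31))), params) for _ in range(7)]
            slopes.append(pool_and_fit_loading_rate(traces)[0])
        assert abs(np.mean(slopes) - 1.5) / 1.5 < 0.05

    def test_flat_traces_rejected(self, params):
        flat = pd.DataFrame({"t_s": np.arange(10) * 0.1,
                             "force_pn": np.zeros(10)})
        with pytest.raises(ValueError):
            pool_and_fit_loading_rate([flat, flat])


class TestContactPooling:
    def test_window_assignment_half_open(self):
        recs = pd.DataFrame({"movie": ["m"] * 3,
                             "t_s": [7 * 60.0, 5 * 60.0, 0.0]})
        out = pool_by_contact_time(recs, {"m": 0.0}, window_s=300.0)
        assert list(out["contact_window"]) == [1, 1, 0]

    def test_missing_annotation_goes_unknown(self):
        recs = pd.DataFrame({"movie": ["x"], "t_s": [10.0]})
        out = pool_by_contact_time(recs, {}, window_s=300.0)
        assert list(out["contact_window"]) == [-1]


class TestMSD:
    def test_fluid_phase_diffusion_recovered(self):
        dt = 0.02
        tracks = _brownian_tracks(300, 12, 0.72, dt, seed=5)
        res = msd_fit(tracks, dt, seed=0)
        assert res.D == pytest.approx(0.72, abs=2 * res.D_se)
        assert res.epsilon == pytest.approx(0.03, abs=0.03)

    def test_immobile_molecules_intercept(self):
        dt = 0.02
        tracks = _brownian_tracks(200, 12, 0.0, dt, eps=0.03, seed=6)
        res = msd_fit(tracks, dt, seed=0)
        assert abs(res.D) < 3 * res.D_se + 1e-3
        assert res.epsilon == pytest.approx(0.03, abs=0.01)

    def test_frame_interval_invariance(self):
        # halving the frame interval leaves the inferred D unchanged
        res = []
        for dt in (0.02, 0.01):
            tracks = _brownian_tracks(200, 12, 0.3, dt, seed=7)
            res.append(msd_fit(tracks, dt, seed=0))
        assert res[0].D == pytest.approx(res[1].D,
                                         abs=2 * (res[0].D_se + res[1].D_se))

    def test_unbiased_across_d_range(self):
        dt = 0.02
        for d in (1e-4, 0.01, 0.7):
            est = [msd_fit(_brownian_tracks(150, 12, d, dt, eps=0.005,
                                            seed=800 + i), dt,
                           n_boot=20, seed=0).D for i in range(5)]
            assert np.mean(est) == pytest.approx(d, abs=0.03 * 0.7 + 0.1 * d)


class TestSmallestEnclosingCircle:
    @staticmethod
    def _brute_force(pts):
        best = None
        for p, q in itertools.combinations(pts, 2):
            c = ((p[0] + q[0]) / 2, (p[1] + q[1]) / 2,
                 np.hypot(p[0] - q[0], p[1] - q[1]) / 2)
            if all(np.hypot(r[0] - c[0], r[1] - c[1]) <= c[2] + 1e-10
                   for r in pts):
                if best is None or c[2] < best[2]:
                    best = c
        from forcefret.kinetics import _circumcircle
        for p, q, r in itertools.combinations(pts, 3):
            c = _circumcircle(p, q, r)
            if c and all(np.hypot(s[0] - c[0], s[1] - c[1]) <= c[2] + 1e-10
                         for s in pts):
                if best is None or c[2] < best[2]:
                    best = c
        return best

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for n in range(2, 13):
            for _ in range(20):
                pts = [tuple(p) for p in rng.uniform(0, 10, (n, 2))]
                cx, cy, r = smallest_enclosing_circle(pts)
                bx, by, br = self._brute_force(pts)
                assert r == pytest.approx(br, abs=1e-9)
                assert all(np.hypot(p[0] - cx, p[1] - cy) <= r + 1e-9
                           for p in pts)

    def test_identical_points_zero_radius(self):
        assert smallest_enclosing_circle([(2.0, 3.0)] * 5)[2] == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=1, max_size=20))
    def test_contains_all_points(self, pts):
        cx, cy, r = smallest_enclosing_circle(pts)
        assert all(np.hypot(p[0] - cx, p[1] - cy) <= r + 1e-7 for p in pts)


class TestMobility:
    def test_stationary_molecule_immobilized(self):
        rng = np.random.default_rng(9)
        dt = 0.02
        for _ in range(50):
            xy = rng.normal(0, 0.03, (50, 2))
            tr = pd.DataFrame({"particle": 0, "pair": np.arange(50),
                               "x_um": xy[:, 0], "y_um": xy[:, 1]})
            stat = classify_mobility(tr, dt)
            assert not stat.mobile
            assert stat.statistic < 0.2

    def test_classifier_accuracy_on_mixture(self):
        rng = np.random.default_rng(10)
        dt = 0.02
        correct = 0
        n = 500
        for i in range(n):
            if i % 2:
                xy = np.cumsum(rng.normal(0, np.sqrt(2 * 0.72 * dt), (50, 2)),
                               axis=0) + rng.normal(0, 0.03, (50, 2))
                mobile_truth = True
            else:
                xy = rng.normal(0, 0.03, (50, 2))
                mobile_truth = False
            tr = pd.DataFrame({"particle": 0, "pair": np.arange(50),
                               "x_um": xy[:, 0], "y_um": xy[:, 1]})
            correct += classify_mobility(tr, dt).mobile == mobile_truth
        assert correct / n >= 0.95

    def test_needs_three_points(self):
        tr = pd.DataFrame({"particle": 0, "pair": [0, 1],
                           "x_um": [0, 1], "y_um": [0, 1]})
        with pytest.raises(ValueError):
            classify_mobility(tr, 0.02)
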