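"""Step detection and the trajectory quality-control filter chain."""

import numpy as np
import pandas as pd
import pytest

from forcefret.fret import CorrectionFactors
from forcefret.qc import (QCConfig, apply_qc_chain, bleach_filter,
                          detect_steps, filter_first_frame,
                          filter_laser_region, filter_overlap,
                          filter_stoichiometry, make_cell_mask,
                          select_in_mask)
from forcefret.simulate import sample_brightness_records


def _records(particle, pairs, x=50.0, y=50.0, overlap=False, s=0.5):
    return pd.DataFrame({
        "particle": particle, "pair": pairs,
        "x": x, "y": y, "f_dd": 500.0, "f_da": 500.0, "f_aa": 1000.0,
        "interpolated": False, "overlap": overlap, "S": s})


class TestDetectSteps:
    def test_constant_noisy_trace_no_steps(self):
        rng = np.random.default_rng(0)
        n_fp = sum(detect_steps(rng.normal(100, 10, 80)).n_steps > 0
                   for _ in range(200))
        assert n_fp / 200 < 0.02

    def test_five_sigma_single_step_found_reliably(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(500):
            y = np.r_[np.full(50, 100.0), np.full(50, 50.0)]
            y += rng.normal(0, 10, 100)
            res = detect_steps(y)
            hits += res.n_steps == 1 and abs(res.step_frames[0] - 50) <= 1
        assert hits / 500 >= 0.99

    def test_two_step_staircase(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.full(40, 200.0), np.full(30, 100.0), np.full(30, 0.0)]
        res = detect_steps(y + rng.normal(0, 8, 100))
        assert res.n_steps == 2
        assert abs(res.step_frames[0] - 40) <= 1
        assert abs(res.step_frames[1] - 70) <= 1
        assert all(a < 0 for a in res.step_amplitudes)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_steps([1.0, 2.0, 3.0])


class TestSimpleFilters:
    def test_laser_region(self):
        profile = np.ones((100, 100))
        profile[:, 60:] = 0.4
        recs = pd.concat([_records(0, range(5), x=30),
                          _records(1, range(5), x=80)], ignore_index=True)
        out = filter_laser_region(recs, profile, 0.5)
        assert set(out["particle"]) == {0}

    def test_laser_region_area_fraction(self):
        # retained fraction of uniformly spread records matches the
        # area above half maximum of a Gaussian illumination profile
        yy, xx = np.mgrid[0:200, 0:200]
        profile = np.exp(-((xx - 100) ** 2 + (yy - 100) ** 2) / (2 * 40 ** 2))
        rng = np.random.default_rng(3)
        recs = _records(0, range(20000))
        recs["x"] = rng.uniform(0, 200, 20000)
        recs["y"] = rng.uniform(0, 200, 20000)
        kept = len(filter_laser_region(recs, profile, 0.5)) / 20000
        area = (profile >= 0.5).mean()
        assert kept == pytest.approx(area, abs=0.02)

    def test_overlap_rule(self):
        # >25% overlapping records: whole trajectory dropped
        heavy = _records(0, range(10), overlap=[True] * 3 + [False] * 7)
        light = _records(1, range(10), overlap=[True] * 1 + [False] * 9)
        out = filter_overlap(pd.concat([heavy, light], ignore_index=True))
        assert set(out["particle"]) == {1}
        assert len(out) == 9   # the single overlapping record removed

    def test_first_frame_rule(self):
        a = _records(0, range(0, 10))
        b = _records(1, range(3, 13))
        out = filter_first_frame(pd.concat([a, b], ignore_index=True))
        assert set(out["particle"]) == {0}

    def test_stoichiometry_rule(self):
        good = _records(0, range(10), s=0.5)
        bad = _records(1, range(10), s=[0.7] * 3 + [0.5] * 7)
        out = filter_stoichiometry(pd.concat([good, bad], ignore_index=True))
        assert set(out["particle"]) == {0}
        borderline = _records(2, range(10), s=[0.7] * 2 + [0.5] * 8)
        assert set(filter_stoichiometry(borderline)["particle"]) == {2}


class TestBleachFilter:
    def _traj(self, pid, aa_bleach=None, donor_bleach=None, seed=0):
        rec = sample_brightness_records(
            100, 0.6, total_rate=1500.0, acceptor_bleach_pair=aa_bleach,
            donor_bleach_pair=donor_bleach, particle=pid, seed=seed)
        rec["pair"] = np.arange(100)
        return rec

    def test_clean_acceptor_bleach_truncates(self):
        rec = self._traj(0, aa_bleach=60)
        kept, report = bleach_filter(rec)
        assert report["accepted"].iloc[0]
        assert kept["pair"].max() <= 59

    def test_no_bleach_rejected(self):
        rec = self._traj(0)
        kept, report = bleach_filter(rec)
        assert not report["accepted"].iloc[0]
        assert kept.empty

    def test_double_acceptor_step_rejected(self):
        # two acceptor bleach steps: not a single emitter
        a = sample_brightness_records(100, 0.6, kind="double_acceptor",
                                      acceptor_bleach_pair=40, seed=1)
        b = sample_brightness_records(100, 0.6, acceptor_bleach_pair=75,
                                      seed=2)
        rec = a.copy()
        rec[["f_dd", "f_da", "f_aa"]] += b[["f_dd", "f_da", "f_aa"]]
        rec["pair"] = np.arange(100)
        _, report = bleach_filter(rec)
        assert not report["accepted"].iloc[0]

    def test_donor_bleach_before_acceptor_truncates_earlier(self):
        rec = self._traj(0, aa_bleach=80, donor_bleach=40, seed=3)
        kept, report = bleach_filter(rec)
        assert report["accepted"].iloc[0]
        assert kept["pair"].max() <= 40

    def test_truncation_matches_true_bleach_frame(self):
        hits = 0
        for i in range(40):
            bleach = 20 + i
            rec = self._traj(i, aa_bleach=bleach, seed=100 + i)
            _, report = bleach_filter(rec)
            if report["accepted"].iloc[0] and \
                    abs(report["truncation_index"].iloc[0] - bleach) <= 1:
                hits += 1
        assert hits / 40 >= 0.95


class TestCellMask:
    def test_uniform_image_empty_mask(self):
        mask = make_cell_mask(np.full((64, 64), 10.0))
        assert not mask.mask.any()

    def test_disc_recovered_with_high_iou(self):
        from forcefret.simulate import render_cell_image
        img, truth = render_cell_image([(64, 64, 31, 200)], shape=(128, 128),
                                       seed=1)
        # block larger than the cell diameter (62 px), as for ~10 um cells
        mask = make_cell_mask(img, block_size=101, min_size=64)
        inter = (mask.mask & truth).sum()
        union = (mask.mask | truth).sum()
        assert inter / union >= 0.9

    def test_select_in_mask(self):
        from forcefret.qc import CellMask
        m = np.zeros((100, 100), dtype=bool)
        m[40:60, 40:60] = True
        recs = pd.concat([_records(0, range(4), x=50, y=50),
                          _records(1, range(4), x=10, y=10)],
                         ignore_index=True)
        out = select_in_mask(recs, CellMask(m))
        assert set(out["particle"]) == {0}


class TestChain:
    def _movie_records(self, n_traj=12, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for pid in range(n_traj):
            bleach = int(rng.integers(30, 70))
            r = sample_brightness_records(100, 0.87, total_rate=1500.0,
                                          acceptor_bleach_pair=bleach,
                                          particle=pid, seed=1000 + pid)
            r["pair"] = np.arange(100)
            r["x"] = rng.uniform(20, 80)
            r["y"] = rng.uniform(20, 80)
            r["interpolated"] = False
            r["overlap"] = False
            recs.append(r)
        return pd.concat(recs, ignore_index=True)

    def test_intact_pairs_survive(self):
        recs = self._movie_records()
        out, report = apply_qc_chain(recs, CorrectionFactors())
        assert out["particle"].nunique() >= 0.95 * 12
        assert report.empty or (report["removed_by"] != "").all()

    def test_chain_idempotent(self):
        recs = self._movie_records(seed=1)
        once, _ = apply_qc_chain(recs, CorrectionFactors())
        # survivors pass the non-destructive filters again unchanged
        again = filter_overlap(filter_first_frame(
            filter_stoichiometry(once)))
        assert len(again) == len(once)
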