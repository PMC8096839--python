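"""Synthetic-movie generator: photon bookkeeping, determinism, truth."""

import numpy as np
import pandas as pd
import pytest

from forcefret.fret import CorrectionFactors
from forcefret.image_prep import counts_to_photons
from forcefret.simulate import (CameraParams, MoleculeSpec, TimingParams,
                                random_scene, render_cell_image,
                                render_fiducial_pair, render_movie,
                                sample_brightness_records, sample_es_mixture,
                                simulate_force_ramp_trace, write_movie)

CAM = CameraParams()


def _one_molecule_movie(e=0.87, n_pairs=100, bleach=np.inf, seed=5, **kw):
    spec = MoleculeSpec(x_um=3.2, y_um=3.2, e_schedule=[(0.0, e)],
                        total_rate=2000.0, acceptor_bleach_s=bleach)
    timing = TimingParams(n_frame_pairs=n_pairs)
    return render_movie([spec], CAM, timing, shape=(40, 40), seed=seed, **kw)


class TestRenderMovie:
    def test_empty_scene_is_pure_noise(self):
        movie = render_movie([], CAM, TimingParams(n_frame_pairs=5),
                             shape=(32, 32), background_photons=0.0, seed=1)
        for stack in movie.stacks.values():
            assert stack.mean() == pytest.approx(CAM.offset, abs=1.0)

    def test_photon_conservation_at_spot(self):
        # summed photons around an immobile pair match the configured
        # budget within shot-noise error over 100 frames
        movie = _one_molecule_movie(e=0.87, background_photons=2.0)
        photons = counts_to_photons(movie.stacks["DA"], CAM)
        cy = cx = int(round(3.2 / CAM.pixel_size_um))
        box = photons[:, cy - 5:cy + 6, cx - 5:cx + 6]
        per_frame = box.sum(axis=(1, 2)) - 2.0 * box.shape[1] * box.shape[2]
        expected = 2000.0 * 0.87          # f_DA = gamma*N*E with gamma=1
        sem = per_frame.std(ddof=1) / np.sqrt(len(per_frame))
        assert abs(per_frame.mean() - expected) < 3 * sem + 0.01 * expected

    def test_acceptor_bleach_steps_fa(self):
        timing = TimingParams(n_frame_pairs=100)
        t_bleach = 50 * timing.pair_interval_s
        movie = _one_molecule_movie(bleach=t_bleach)
        truth = movie.truth.records
        f_aa = truth.sort_values("pair")["f_aa"].to_numpy()
        assert np.all(f_aa[:50] > 0) and np.all(f_aa[50:] == 0)
        # donor brightness rises as FRET quenching disappears
        f_dd = truth.sort_values("pair")["f_dd"].to_numpy()
        assert f_dd[60] > f_dd[40]

    def test_seed_reproducibility_bit_identical(self):
        m1 = _one_molecule_movie(seed=7)
        m2 = _one_molecule_movie(seed=7)
        for c in ("DD", "DA", "AA"):
            assert np.array_equal(m1.stacks[c], m2.stacks[c])

    def test_truth_follows_schedule(self):
        spec = MoleculeSpec(x_um=3.0, y_um=3.0, total_rate=1000.0,
                            e_schedule=[(0.0, 0.87), (1.0, 0.42)])
        timing = TimingParams(n_frame_pairs=100)  # 20 ms doublets
        movie = render_movie([spec], CAM, timing, shape=(40, 40), seed=2)
        tr = movie.truth.records.sort_values("pair")
        switch = int(np.ceil(1.0 / timing.pair_interval_s))
        assert (tr["E_true"].to_numpy()[:switch] == 0.87).all()
        assert (tr["E_true"].to_numpy()[switch:] == 0.42).all()

    def test_correction_factor_bookkeeping(self):
        fac = CorrectionFactors(alpha=0.1, delta=0.05, gamma=0.9, beta=1.2)
        spec = MoleculeSpec(x_um=3.0, y_um=3.0, total_rate=1000.0,
                            e_schedule=[(0.0, 0.4)])
        movie = render_movie([spec], CAM, TimingParams(n_frame_pairs=2),
                             shape=(40, 40), factors=fac, seed=3)
        row = movie.truth.records.iloc[0]
        f_dd = 1000 * 0.6
        f_aa = 1.2 * 0.9 * 1000
        f_da = 0.9 * 1000 * 0.4 + 0.1 * f_dd + 0.05 * f_aa
        assert row["f_dd"] == pytest.approx(f_dd)
        assert row["f_aa"] == pytest.approx(f_aa)
        assert row["f_da"] == pytest.approx(f_da)
        assert row["S_true"] == pytest.approx(0.5)


class TestScenesAndSamples:
    def test_random_scene_state_counts_deterministic(self):
        scene = random_scene(50, state_fractions=(0.79, 0.21), seed=4)
        es = [s.e_schedule[0][1] for s in scene]
        assert es.count(0.42) in (10, 11)
        assert len(scene) == 50

    def test_random_scene_min_separation(self):
        scene = random_scene(30, min_separation_px=12.0, seed=5)
        pos = np.array([[s.x_um, s.y_um] for s in scene]) / CAM.pixel_size_um
        d = np.sqrt(((pos[None] - pos[:, None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 12.0

    def test_es_mixture_weights_and_determinism(self):
        comps = [(0.85, 0.87, 0.12, 0.5, 0.05), (0.15, 0.42, 0.12, 0.5, 0.05)]
        pts = sample_es_mixture(2300, comps, seed=6)
        frac_low = (pts["component"] == 1).mean()
        assert frac_low == pytest.approx(0.15, abs=3 * np.sqrt(0.15 * 0.85 / 2300))
        assert pts.equals(sample_es_mixture(2300, comps, seed=6))

    def test_es_mixture_degenerate_sd(self):
        pts = sample_es_mixture(50, [(1.0, 0.5, 0.0, 0.5, 0.0)], seed=0)
        assert (pts["E"] == 0.5).all() and (pts["S"] == 0.5).all()

    def test_mixture_weights_must_normalize(self):
        with pytest.raises(ValueError):
            sample_es_mixture(10, [(0.5, 0.5, 0.1, 0.5, 0.1)])


class TestForceRamp:
    def test_noiseless_ramp_inverts_exactly(self, params):
        from forcefret.calibration import fret_to_force
        tr = simulate_force_ramp_trace(1.5, 3.0, 10, 0.0, params, seed=1)
        back = np.asarray(fret_to_force(tr["E"].to_numpy(), params))
        assert np.allclose(back, tr["F_true"], atol=1e-6)

    def test_peak_beyond_range_rejected(self, params, dyn_range):
        with pytest.raises(ValueError):
            simulate_force_ramp_trace(1.5, 20.0, 10, 0.0, params, dyn_range)

    def test_trace_shape(self, params):
        tr = simulate_force_ramp_trace(1.5, 3.0, 10, 0.05, params,
                                       tail_s=1.0, seed=2)
        assert tr["F_true"].max() == pytest.approx(3.0, abs=0.16)
        assert (tr["F_true"].to_numpy()[-5:] == 0).all()


class TestBrightnessRecords:
    def test_pair_expectations(self):
        fac = CorrectionFactors(alpha=0.08, delta=0.05, gamma=0.9, beta=1.2)
        rec = sample_brightness_records(2000, 0.4, fac, total_rate=1000,
                                        measurement_noise_sd=0, seed=1)
        assert rec["f_dd"].mean() == pytest.approx(600, rel=0.02)
        assert rec["f_aa"].mean() == pytest.approx(1080, rel=0.02)
        assert rec["f_da"].mean() == pytest.approx(
            0.9 * 400 + 0.08 * 600 + 0.05 * 1080, rel=0.02)

    @pytest.mark.parametrize("kind,s_expected", [
        ("pair", 0.5), ("double_donor", 2 / 3), ("double_acceptor", 1 / 3)])
    def test_stoichiometry_classes(self, kind, s_expected):
        from forcefret.fret import compute_es
        rec = sample_brightness_records(500, 0.5, kind=kind, seed=2,
                                        measurement_noise_sd=0)
        es = compute_es(rec, CorrectionFactors())
        assert es["S"].mean() == pytest.approx(s_expected, abs=0.01)


class TestAuxImages:
    def test_fiducial_identity_affine_coincides(self):
        from forcefret.registration import AffineTransform
        _, _, dxy, axy = render_fiducial_pair(
            10, AffineTransform.identity(), seed=3)
        assert np.allclose(dxy, axy)

    def test_cell_image_empty_scene(self):
        img, mask = render_cell_image([], seed=4)
        assert not mask.any()
        assert img.shape == (128, 128)

    def test_cell_image_union_of_discs(self):
        _, mask = render_cell_image([(40, 40, 12, 100), (50, 40, 12, 100)],
                                    seed=5)
        assert mask[40, 40] and mask[40, 50]
        # single connected blob
        from scipy import ndimage
        _, n = ndimage.label(mask)
        assert n == 1


def test_write_movie_round_trip(tmp_path):
    from forcefret.image_prep import load_movie_dir
    movie = _one_molecule_movie(n_pairs=5)
    out = write_movie(movie, tmp_path / "mov")
    stacks = load_movie_dir(out)
    assert set(stacks) == {"DD", "DA", "AA"}
    assert stacks["AA"].frames.shape == (5, 40, 40)
    # photon conversion applied: offset-subtracted counts scaled
    raw = movie.stacks["AA"][0].astype(np.float32)
    expected = (raw - CAM.offset) * CAM.photons_per_count / CAM.em_gain
    assert np.allclose(stacks["AA"].frames[0], expected, atol=1e-4)
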