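"""Synthetic training sets and hyperspectral cubes."""

import hashlib

import numpy as np
import pytest

from vsfgorient.synth import (
    GenerationRanges,
    Sheet,
    SheetScene,
    TrainingSet,
    canonicalize,
    decode_targets,
    gen_cube,
    gen_test_set,
    gen_training_set,
    two_sheet_susceptibilities,
)
from vsfgorient.tensor import grouped_susceptibilities


def rhombus(cx, cy, d1=14.0, d2=8.0):
    return np.array([[cx + d1, cy], [cx, cy + d2], [cx - d1, cy], [cx, cy - d2]])


class TestCanonicalize:
    def test_folded_triple_preserves_susceptibilities(self, rng):
        for _ in range(200):
            g = rng.uniform(-1, 1, (1, 6))
            phi = rng.uniform(0, 2 * np.pi)
            theta = rng.uniform(0, np.pi)
            pf, tf, gf, ip, it_ = canonicalize(phi, theta, g)
            assert 0 <= pf[0] < np.pi and 0 <= tf[0] <= np.pi / 2
            assert ip[0] == float(phi >= np.pi) and it_[0] == float(theta >= np.pi / 2)
            chi0 = grouped_susceptibilities(g[0], phi, theta)
            chi1 = grouped_susceptibilities(gf[0], pf[0], tf[0])
            assert np.allclose(chi0, chi1, atol=1e-12)

    def test_canonical_input_unchanged(self):
        g = np.ones((1, 6))
        pf, tf, gf, ip, it_ = canonicalize(0.5, 0.7, g)
        assert pf[0] == 0.5 and tf[0] == 0.7 and ip[0] == 0.0 and it_[0] == 0.0
        assert np.array_equal(gf, g)


class TestTrainingSetGeneration:
    def test_benchmark_scale_shapes(self):
        ts = gen_training_set(100000, seed=5)
        assert ts.inputs.shape == (100000, 16)
        assert ts.outputs.shape == (100000, 11)
        # 16 + 11 = 27 values per row, as the training bookkeeping requires
        assert ts.inputs.shape[1] + ts.outputs.shape[1] == 27

    def test_same_seed_bitwise_identical(self):
        a = gen_training_set(500, seed=3)
        b = gen_training_set(500, seed=3)
        assert np.array_equal(a.inputs, b.inputs) and np.array_equal(a.outputs, b.outputs)

    def test_rows_are_forward_model_consistent(self):
        ts = gen_training_set(300, seed=8)
        g, phi, theta, n, _, _ = decode_targets(ts.outputs)
        x = two_sheet_susceptibilities(g, phi, theta, n, delta_phi_deg=60.0)
        assert np.abs(x - ts.inputs).max() < 1e-10

    def test_inputs_unit_normalized(self):
        ts = gen_training_set(200, seed=2)
        assert np.allclose(np.linalg.norm(ts.inputs, axis=1), 1.0, atol=1e-12)

    def test_angles_and_ratio_in_canonical_domains(self):
        ts = gen_training_set(2000, seed=9)
        g, phi, theta, n, ip, it_ = decode_targets(ts.outputs)
        assert np.all((phi >= 0) & (phi < np.pi))
        assert np.all((theta >= 0) & (theta <= np.pi / 2))
        assert np.all((n >= 0.2) & (n <= 5.0))
        assert np.allclose(np.linalg.norm(g, axis=1), 1.0)

    def test_test_set_shares_no_rows_with_training(self):
        tr = gen_training_set(5000, seed=21)
        te = gen_test_set(1000, seed=21)
        digest = lambda X: {hashlib.sha1(row.tobytes()).hexdigest() for row in X}
        assert digest(tr.inputs).isdisjoint(digest(te.inputs))

    @pytest.mark.parametrize("n", [0, -5])
    def test_empty_request_is_error(self, n):
        with pytest.raises(ValueError):
            gen_test_set(n, seed=0)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            gen_training_set(10, seed=0, ranges=GenerationRanges(beta_low=1.0, beta_high=-1.0))

    def test_save_load_round_trip(self, tmp_path):
        ts = gen_training_set(50, seed=4)
        ts.save(tmp_path / "train")
        back = TrainingSet.load(tmp_path / "train")
        assert np.array_equal(back.inputs, ts.inputs)
        assert back.seed == 4 and back.params["role"] == "train"


class TestCubeGeneration:
    def test_empty_scene_is_baseline_plus_noise(self):
        scene = SheetScene(sheets=[], shape=(24, 24), baseline=10.0)
        cube = gen_cube(scene, seed=0)
        assert cube.data.shape == (8, 24, 24, scene.wavenumber.size)
        assert abs(cube.data.mean() - 10.0) < 0.1

    def test_target_snr_hit_within_20_percent(self):
        scene = SheetScene(
            sheets=[Sheet(vertices=rhombus(24, 24), phi_deg=15.0, theta_deg=23.0)],
            shape=(48, 48),
            target_snr=56.0,
        )
        cube = gen_cube(scene, seed=1)
        mask = scene.sheets[0].mask(scene.shape)
        i2910 = int(np.argmin(np.abs(cube.wavenumber - 2910.0)))
        sigma = cube.meta["noise_sigma"]
        peak = cube.plane("SSS")[..., i2910] - scene.baseline
        measured = peak[mask].mean() / sigma
        assert 45.0 <= measured <= 67.0

    def test_overlap_pixels_sum_contributions(self):
        s1 = Sheet(vertices=rhombus(16, 20, 10, 6), phi_deg=0.0, theta_deg=23.0)
        s2 = Sheet(vertices=rhombus(22, 20, 10, 6), phi_deg=0.0, theta_deg=23.0)
        scene = SheetScene(sheets=[s1, s2], shape=(40, 40), target_snr=1e9)
        cube = gen_cube(scene, seed=0)
        m1, m2 = s1.mask(scene.shape), s2.mask(scene.shape)
        overlap = m1 & m2
        only1 = m1 & ~m2
        assert overlap.any() and only1.any()
        i2910 = int(np.argmin(np.abs(cube.wavenumber - 2910.0)))
        plane = cube.plane("SSS")[..., i2910] - scene.baseline
        assert plane[overlap].mean() == pytest.approx(2.0 * plane[only1].mean(), rel=1e-6)

    def test_sqrt_k_pixel_averaging_law(self):
        scene = SheetScene(
            sheets=[Sheet(vertices=rhombus(12, 12, 8, 6), phi_deg=30.0, theta_deg=23.0)],
            shape=(24, 24),
            target_snr=10.0,
        )
        k = 25
        i2910 = None
        sums_1, sums_k = [], []
        mask = scene.sheets[0].mask(scene.shape)
        ys, xs = np.nonzero(mask)
        for trial in range(100):
            cube = gen_cube(scene, seed=trial)
            if i2910 is None:
                i2910 = int(np.argmin(np.abs(cube.wavenumber - 2910.0)))
            plane = cube.plane("SSS")[..., i2910]
            sums_1.append(plane[ys[0], xs[0]])
            sums_k.append(plane[ys[:k], xs[:k]].mean())
        snr_1 = np.mean(sums_1) / np.std(sums_1)
        snr_k = np.mean(sums_k) / np.std(sums_k)
        assert snr_k / snr_1 == pytest.approx(np.sqrt(k), rel=0.25)

    def test_zero_tilt_sheet_indistinguishable_from_background(self):
        """Zero tilt annihilates the response, so the sheet region is noise."""
        from scipy.stats import ttest_ind

        scene = SheetScene(
            sheets=[Sheet(vertices=rhombus(12, 12, 8, 6), phi_deg=20.0, theta_deg=0.0)],
            shape=(24, 24),
            target_snr=56.0,
        )
        mask = scene.sheets[0].mask(scene.shape)
        rejections = 0
        for trial in range(50):
            cube = gen_cube(scene, seed=1000 + trial)
            i2910 = int(np.argmin(np.abs(cube.wavenumber - 2910.0)))
            plane = cube.plane("SSS")[..., i2910]
            p = ttest_ind(plane[mask], plane[~mask], equal_var=False).pvalue
            rejections += p < 0.01
        assert rejections <= 5

    def test_sheet_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            SheetScene(
                sheets=[Sheet(vertices=rhombus(2, 2), phi_deg=0.0, theta_deg=20.0)],
                shape=(16, 16),
            )

    def test_axis_must_cover_ch_window(self):
        with pytest.raises(ValueError, match="2800"):
            SheetScene(sheets=[], wavenumber=np.arange(2850.0, 2950.0, 2.0))

    def test_reproducible_given_seed(self):
        scene = SheetScene(
            sheets=[Sheet(vertices=rhombus(12, 12, 8, 6), phi_deg=10.0, theta_deg=23.0)],
            shape=(24, 24),
        )
        a = gen_cube(scene, seed=7)
        b = gen_cube(scene, seed=7)
        assert np.array_equal(a.data, b.data)
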