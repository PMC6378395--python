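"""Ground-truth matching, ROC/AUC, average-synapse imaging, counting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from quantos.postanalysis import (
    average_synapse,
    count_photoreceptors,
    likelihood_histogram_2d,
    match_ground_truth,
    radial_profile,
    roc_auc,
)


class TestMatching:
    def test_within_one_micron_is_positive(self):
        labels, claimed = match_ground_truth([[0.0, 0.9]], [[0.0, 0.0]], 1.0)
        assert labels[0] and claimed[0]

    def test_beyond_one_micron_is_negative(self):
        labels, claimed = match_ground_truth([[0.0, 1.1]], [[0.0, 0.0]], 1.0)
        assert not labels[0] and not claimed[0]

    def test_one_to_one_no_double_claims(self):
        # two detections near one truth: only the nearer matches
        labels, claimed = match_ground_truth([[0.0, 0.2], [0.0, 0.3]], [[0.0, 0.0]], 1.0)
        assert labels.tolist() == [True, False]
        assert claimed.sum() == 1

    def test_matches_exhaustive_oracle_on_small_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            det = rng.uniform(0, 6, (rng.integers(1, 20), 2))
            tru = rng.uniform(0, 6, (rng.integers(1, 20), 2))
            labels, claimed = match_ground_truth(det, tru, 1.0)
            # independent oracle: sort all admissible pairs by distance,
            # assign greedily
            pairs = []
            for i in range(len(det)):
                for j in range(len(tru)):
                    d = float(np.hypot(*(det[i] - tru[j])))
                    if d <= 1.0:
                        pairs.append((d, i, j))
            used_i, used_j = set(), set()
            for d, i, j in sorted(pairs):
                if i not in used_i and j not in used_j:
                    used_i.add(i)
                    used_j.add(j)
            assert set(np.nonzero(labels)[0]) == used_i
            assert set(np.nonzero(claimed)[0]) == used_j


class TestRoc:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        r = roc_auc(scores, labels)
        assert r.auc == 1.0
        assert r.ci_low <= r.auc <= r.ci_high

    def test_permuted_scores_near_half(self):
        rng = np.random.default_rng(13)
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(14)
        scores = rng.random(50)
        labels = rng.random(50) < 0.4
        if labels.all() or not labels.any():
            labels[:5] = True
            labels[5:] = False
        r = roc_auc(scores, labels)
        u = mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert r.auc == pytest.approx(u / (labels.sum() * (~labels).sum()), rel=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [True, True])

    def test_curve_monotone(self, benchmark_all):
        roc, _ = benchmark_all
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert 0 <= roc.auc <= 1

    def test_bootstrap_ci_available(self):
        rng = np.random.default_rng(15)
        scores = np.r_[rng.normal(0, 1, 100), rng.normal(1.5, 1, 100)]
        labels = np.r_[np.zeros(100, bool), np.ones(100, bool)]
        r = roc_auc(scores, labels, ci_method="bootstrap", n_boot=300)
        assert r.ci_low < r.auc < r.ci_high


def _stamp(img, x, y, peak, sigma):
    yy, xx = np.indices(img.shape)
    img += peak * np.exp(-(((yy + 0.5) - y) ** 2 + ((xx + 0.5) - x) ** 2) / (2 * sigma**2))


class TestAverageSynapse:
    px = 0.1

    def _images(self, angle_deg):
        """One synthetic synapse at the given pre->post orientation.

        The midpoint sits exactly on the center of pixel (100, 100), i.e. at
        continuous coordinate 100.5 px, so an integer crop is well defined.
        """
        pre = np.zeros((200, 200))
        post = np.zeros((200, 200))
        cx = cy = 100.5
        d = 0.5 / self.px / 2.0  # half the pair distance, px
        rad = np.radians(angle_deg)
        _stamp(pre, cx - d * np.cos(rad), cy - d * np.sin(rad), 100, 2.0)
        _stamp(post, cx + d * np.cos(rad), cy + d * np.sin(rad), 80, 1.5)
        syn = pd.DataFrame({"x_um": [cx * self.px], "y_um": [cy * self.px],
                            "pair_angle": [angle_deg]})
        return {"pre": pre, "post": post}, syn

    def test_single_vertical_synapse_equals_own_crop(self):
        images, syn = self._images(90.0)
        avg = average_synapse(images, syn, self.px)
        side = avg.side_px
        half = (side - 1) // 2
        # rotation angle is zero and the grid is integer: the mean equals
        # the plain crop pixel for pixel
        crop = images["pre"][100 - half : 100 + half + 1, 100 - half : 100 + half + 1]
        assert avg.n == 1
        assert avg.images["pre"].shape == (side, side)
        assert np.allclose(avg.images["pre"], crop, atol=1e-9)

    def test_rotation_aligns_orientations(self):
        imgs_v, syn_v = self._images(90.0)
        imgs_h, syn_h = self._images(0.0)
        avg_v = average_synapse(imgs_v, syn_v, self.px)
        avg_h = average_synapse(imgs_h, syn_h, self.px)
        for ch in ("pre", "post"):
            a, b = avg_v.images[ch], avg_h.images[ch]
            rms = np.sqrt(np.mean((a - b) ** 2))
            assert rms < 0.05 * a.max()

    def test_identical_synapses_average_to_one_crop(self):
        images, syn = self._images(90.0)
        syn3 = pd.concat([syn] * 3, ignore_index=True)
        a1 = average_synapse(images, syn, self.px)
        a3 = average_synapse(images, syn3, self.px)
        assert a3.n == 3
        assert np.allclose(a1.images["pre"], a3.images["pre"])

    def test_border_synapse_skipped_and_empty_errors(self):
        images, _ = self._images(90.0)
        border = pd.DataFrame({"x_um": [0.3], "y_um": [0.3], "pair_angle": [90.0]})
        with pytest.raises(ValueError, match="no usable"):
            average_synapse(images, border, self.px)


class TestRadialProfile:
    def test_gaussian_spot_profile(self):
        img = np.zeros((61, 61))
        _stamp(img, 30.5, 30.5, 100, 3.0)
        from quantos.postanalysis import AverageSynapse

        avg = AverageSynapse(images={"pre": img}, n=1, crop_um=6.1,
                             pixel_size=0.1, skipped_border=0)
        prof = radial_profile(avg, "pre")
        vals = prof["mean_intensity"].to_numpy()
        assert np.nanargmax(vals) == 0
        sl = vals[: int(3 * 3)]
        assert np.all(np.diff(sl) < 0)

    def test_flat_image_errors(self):
        from quantos.postanalysis import AverageSynapse

        avg = AverageSynapse(images={"pre": np.full((21, 21), 5.0)}, n=1,
                             crop_um=2.1, pixel_size=0.1, skipped_border=0)
        with pytest.raises(ValueError, match="flat"):
            radial_profile(avg, "pre")

    def test_matches_bruteforce_binning(self):
        rng = np.random.default_rng(16)
        img = rng.random((41, 41)) + 5.0
        img[20, 20] = 50.0  # unambiguous center
        from quantos.postanalysis import AverageSynapse

        avg = AverageSynapse(images={"pre": img}, n=1, crop_um=4.1,
                             pixel_size=0.1, skipped_border=0)
        prof = radial_profile(avg, "pre")
        for r in range(5):
            acc, cnt = 0.0, 0
            for i in range(41):
                for j in range(41):
                    rr = np.hypot(i - 20, j - 20)
                    if r <= rr < r + 1:
                        acc += img[i, j]
                        cnt += 1
            assert prof.loc[r, "mean_intensity"] == pytest.approx(acc / cnt, rel=1e-9)


class TestCounting:
    @pytest.fixture(scope="class")
    def nuclei_scene(self):
        from quantos.imaging import z_project_mean
        from quantos.synthetic import SceneConfig, generate_scene

        cfg = SceneConfig(seed=17, n_pairs=0, n_clustered_noise=0,
                          n_uniform_noise=0, n_nuclei=50)
        scene = generate_scene(cfg)
        return cfg, scene, z_project_mean(scene.stacks["dapi"])

    def test_masked_count_matches_truth(self, nuclei_scene):
        cfg, scene, img = nuclei_scene
        mask = np.zeros(img.shape, bool)
        mask[:, : img.shape[1] // 2] = True  # left half
        truth_in = (scene.nuclei["x"] < cfg.side_um / 2).sum()
        out = count_photoreceptors(img, mask, pixel_size=cfg.pixel_size)
        assert abs(out["count"] - truth_in) <= 2

    def test_empty_mask_zero(self, nuclei_scene):
        _, _, img = nuclei_scene
        out = count_photoreceptors(img, np.zeros(img.shape, bool))
        assert out["count"] == 0

    def test_full_mask_equals_unmasked(self, nuclei_scene):
        from quantos.imaging import extract_rois_dapi

        _, _, img = nuclei_scene
        out = count_photoreceptors(img, np.ones(img.shape, bool))
        assert out["count"] == len(extract_rois_dapi(img))

    def test_synapses_per_photoreceptor(self, nuclei_scene):
        cfg, scene, img = nuclei_scene
        mask = np.ones(img.shape, bool)
        syn = scene.nuclei[["x", "y"]].to_numpy()[:10]  # any coordinates
        out = count_photoreceptors(img, mask, synapses_um=syn,
                                   pixel_size=cfg.pixel_size)
        assert out["n_synapses_in_mask"] == 10
        assert out["synapses_per_photoreceptor"] == pytest.approx(10 / out["count"])


def test_likelihood_histogram_deterministic(benchmark_all):
    _, tab = benchmark_all
    h1 = likelihood_histogram_2d(tab, "log_likelihood_synapse", "log_likelihood_noise")
    h2 = likelihood_histogram_2d(tab, "log_likelihood_synapse", "log_likelihood_noise")
    assert np.array_equal(h1["counts"], h2["counts"])
    assert h1["counts"].sum() == len(tab)
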