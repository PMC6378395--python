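"""Spatial prior, candidate pairing, posterior arithmetic, synapse calling."""

import numpy as np
import pandas as pd
import pytest

from quantos.classifier import (
    ClassModel,
    PriorModel,
    build_class_model,
    build_maturity_model,
    calibrate_random_factor,
    call_synapses,
    classify_scene,
    estimate_prior,
    pair_candidates,
    score_candidates,
    score_maturity,
)
from quantos.densities import ParameterDensity, uniform_density
from quantos.synthetic import SceneConfig, generate_scene


def _features(xy_um, pixel_size=0.1):
    xy = np.asarray(xy_um, dtype=float) / pixel_size
    return pd.DataFrame({"xm": xy[:, 0], "ym": xy[:, 1]})


def _const_density(height, lo=-1e6, hi=1e6):
    grid = np.linspace(lo, hi, 8)
    return ParameterDensity(kind="uniform", grid=grid,
                            values=np.full(8, height), support=(lo, hi),
                            n_samples=0)


def _toy_model(ls: float, ln: float) -> ClassModel:
    """Distance-only model whose class likelihoods are the constants ls/ln."""
    empty = {"pre": {}, "post": {}}
    return ClassModel(
        role="synapse_noise",
        classes=("synapse", "noise"),
        marker_densities={"synapse": dict(empty), "noise": dict(empty)},
        pair_densities={
            "synapse": {"distance": _const_density(ls), "angle": uniform_density(-180, 180)},
            "noise": {"distance": _const_density(ln), "angle": uniform_density(-180, 180)},
        },
        max_dist=1.2,
    )


class TestRandomFactorCalibration:
    def test_slope_matches_pi_d_squared(self, prior_model):
        assert prior_model.random_factor == pytest.approx(np.pi * 1.2**2, rel=0.05)

    def test_zero_distance_zero_slope(self):
        assert calibrate_random_factor(max_dist=0.0).random_factor == 0.0

    def test_quadratic_scaling_in_distance(self):
        s1 = calibrate_random_factor(max_dist=0.6, seed=21).random_factor
        s2 = calibrate_random_factor(max_dist=1.2, seed=22).random_factor
        assert s2 / s1 == pytest.approx(4.0, rel=0.10)


class TestPairing:
    def test_single_pair_within_threshold(self):
        pre = _features([[1.0, 1.0]])
        post = _features([[1.0, 1.5]])
        out = pair_candidates(pre, post, 0.1)
        assert len(out) == 1
        assert out.loc[0, "distance"] == pytest.approx(0.5)
        assert out.loc[0, "pair_angle"] == pytest.approx(90.0)  # +y, downward

    def test_beyond_threshold_excluded(self):
        out = pair_candidates(_features([[0.0, 0.0]]), _features([[0.0, 1.3]]), 0.1)
        assert len(out) == 0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        pre = _features(rng.uniform(0, 20, (200, 2)))
        post = _features(rng.uniform(0, 20, (200, 2)))
        out = pair_candidates(pre, post, 0.1, max_dist=1.2)
        got = set(zip(out["pre_index"], out["post_index"]))
        expected = set()
        for i in range(200):
            for j in range(200):
                d = 0.1 * np.hypot(pre.xm[i] - post.xm[j], pre.ym[i] - post.ym[j])
                if d <= 1.2:
                    expected.add((i, j))
        assert got == expected


class TestPrior:
    def test_isolated_pair_gets_half(self, prior_model):
        pre = _features([[10.0, 10.0]])
        post = _features([[10.0, 10.4]])
        cands = pair_candidates(pre, post, 0.1)
        out = estimate_prior(cands, pre, post, 0.1, prior_model)
        assert out.loc[0, "prior_synapse"] == 0.5

    def test_random_pairs_four_gives_quarter(self):
        # five markers per channel in the window: rho = 0.2 /um^2 each;
        # with slope 4.0 the expected chance pairs are 4.0*0.2*0.2*25 = 4
        pm = PriorModel(random_factor=4.0)
        xs = np.linspace(9.0, 11.0, 5)
        pre = _features([[x, 10.0] for x in xs])
        post = _features([[x, 10.4] for x in xs])
        cands = pair_candidates(pre, post, 0.1)
        out = estimate_prior(cands, pre, post, 0.1, pm)
        assert np.allclose(out["random_pairs"], 4.0)
        assert np.allclose(out["prior_synapse"], 0.25)

    def test_boundary_exactly_two_is_half(self):
        pm = PriorModel(random_factor=2.0)
        xs = np.linspace(9.0, 11.0, 5)
        pre = _features([[x, 10.0] for x in xs])
        post = _features([[x, 10.4] for x in xs])
        out = estimate_prior(pair_candidates(pre, post, 0.1), pre, post, 0.1, pm)
        assert np.allclose(out["random_pairs"], 2.0)
        assert np.allclose(out["prior_synapse"], 0.5)

    def test_prior_sums_to_one(self, benchmark_all):
        _, tab = benchmark_all
        assert np.allclose(tab["prior_synapse"] + tab["prior_noise"], 1.0)
        assert ((tab["prior_synapse"] > 0) & (tab["prior_synapse"] <= 0.5)).all()


class TestScoring:
    def test_equal_likelihoods_equal_priors_give_half(self):
        model = _toy_model(0.3, 0.3)
        pre = _features([[5.0, 5.0]])
        post = _features([[5.0, 5.5]])
        cands = pair_candidates(pre, post, 0.1)
        cands["prior_synapse"] = 0.5
        out = score_candidates(cands, pre, post, model, subset="distance")
        assert out.loc[0, "posterior_synapse"] == pytest.approx(0.5)

    def test_hand_computed_posterior(self):
        # priors (0.25, 0.75), L_s = 0.4*0.5, L_n = 0.1*0.2:
        # posterior = 0.25*0.2 / (0.25*0.2 + 0.75*0.02) = 0.769230...
        model = _toy_model(0.4 * 0.5, 0.1 * 0.2)
        pre = _features([[5.0, 5.0]])
        post = _features([[5.0, 5.5]])
        cands = pair_candidates(pre, post, 0.1)
        cands["prior_synapse"] = 0.25
        out = score_candidates(cands, pre, post, model, subset="distance")
        expected = 0.25 * 0.2 / (0.25 * 0.2 + 0.75 * 0.02)
        assert out.loc[0, "posterior_synapse"] == pytest.approx(expected, rel=1e-9)

    def test_posteriors_normalized_on_benchmark(self, benchmark_all):
        _, tab = benchmark_all
        assert np.allclose(tab["posterior_synapse"] + tab["posterior_noise"], 1.0)
        assert tab["posterior_synapse"].between(0, 1).all()

    def test_monotone_in_prior(self):
        model = _toy_model(0.3, 0.1)
        pre = _features([[5.0, 5.0]])
        post = _features([[5.0, 5.5]])
        cands = pair_candidates(pre, post, 0.1)
        posts = []
        for p in (0.1, 0.3, 0.5):
            c = cands.copy()
            c["prior_synapse"] = p
            posts.append(score_candidates(c, pre, post, model,
                                          subset="distance").loc[0, "posterior_synapse"])
        assert posts[0] < posts[1] < posts[2]

    def test_missing_parameter_raises(self, default_model):
        pre = _features([[5.0, 5.0]])
        post = _features([[5.0, 5.5]])
        cands = pair_candidates(pre, post, 0.1)
        cands["prior_synapse"] = 0.5
        with pytest.raises(KeyError, match="mean"):
            score_candidates(cands, pre, post, default_model, subset="all")


class TestCalling:
    def _scored(self, posteriors, pre_idx, post_idx):
        n = len(posteriors)
        return pd.DataFrame({
            "pre_index": pre_idx, "post_index": post_idx,
            "distance": [0.5] * n, "pair_angle": [90.0] * n,
            "posterior_synapse": posteriors,
        })

    def test_strictly_above_threshold(self):
        scored = self._scored([0.4, 0.51, 0.9], [0, 1, 2], [0, 1, 2])
        pre = _features([[1, 1], [2, 2], [3, 3]])
        post = _features([[1, 1.5], [2, 2.5], [3, 3.5]])
        out = call_synapses(scored, pre, post, 0.1)
        assert len(out) == 2
        assert out["posterior_synapse"].min() > 0.5

    def test_one_to_one_greedy(self):
        scored = self._scored([0.8, 0.7], [0, 0], [0, 1])
        pre = _features([[1, 1]])
        post = _features([[1, 1.5], [1.4, 1.0]])
        out = call_synapses(scored, pre, post, 0.1, resolve="one_to_one")
        assert len(out) == 1
        assert out.iloc[0]["posterior_synapse"] == 0.8

    def test_resolve_none_keeps_both(self):
        scored = self._scored([0.8, 0.7], [0, 0], [0, 1])
        pre = _features([[1, 1]])
        post = _features([[1, 1.5], [1.4, 1.0]])
        assert len(call_synapses(scored, pre, post, 0.1, resolve="none")) == 2

    def test_midpoint_coordinates(self):
        scored = self._scored([0.9], [0], [0])
        pre = _features([[1.0, 1.0]])
        post = _features([[1.0, 1.8]])
        out = call_synapses(scored, pre, post, 0.1)
        assert out.iloc[0]["y_um"] == pytest.approx(1.4)


class TestTraining:
    def test_full_mask_leaves_noise_class_empty(self, small_scene):
        from quantos.benchmark import extract_channel_features

        data = extract_channel_features(small_scene)
        fp = data["pre"]["features"].drop(columns="in_opl")
        fq = data["post"]["features"].drop(columns="in_opl")
        all_true = (np.ones(len(fp), bool), np.ones(len(fq), bool))
        with pytest.raises(ValueError, match="noise"):
            build_class_model(fp, fq, all_true, 0.1)

    def test_training_recovers_generator_displacement(self, default_model):
        d = default_model.pair_densities["synapse"]["distance"]
        cfg = SceneConfig()
        assert d.params["mu"] == pytest.approx(cfg.disp_mean, abs=0.03)
        assert d.params["sigma"] == pytest.approx(cfg.disp_sd, abs=0.03)

    def test_model_json_roundtrip(self, default_model, tmp_path):
        path = tmp_path / "model.json"
        default_model.to_json(path)
        back = ClassModel.from_json(path)
        assert back.classes == default_model.classes
        assert back.parameters == default_model.parameters
        x = np.linspace(0, 5, 50)
        for cls in back.classes:
            a = back.marker_densities[cls]["pre"]["area"](x * 10)
            b = default_model.marker_densities[cls]["pre"]["area"](x * 10)
            assert np.allclose(a, b)


class TestEndToEnd:
    def test_auc_subset_nesting(self, benchmark_all, benchmark_distance):
        roc_all, _ = benchmark_all
        roc_dist, _ = benchmark_distance
        assert roc_all.auc >= roc_dist.auc - 0.02

    def test_pure_noise_scenes_low_call_rate(self, default_model, prior_model):
        """No generated pairs: at most 2% of noise candidates are called.

        Pooled over several scenes so the rate has enough candidates to be
        meaningful (a single default scene yields only ~15-40)."""
        from quantos.benchmark import extract_channel_features

        n_cand = n_called = 0
        for seed in range(300, 310):
            cfg = SceneConfig(seed=seed, n_pairs=0)
            scene = generate_scene(cfg)
            data = extract_channel_features(scene)
            scored, synapses = classify_scene(
                data["pre"]["features"], data["post"]["features"],
                default_model, prior_model, cfg.pixel_size)
            n_cand += len(scored)
            n_called += len(synapses)
        assert n_cand > 100
        assert n_called / n_cand <= 0.02

    def test_classification_deterministic(self, default_model, prior_model):
        cfg = SceneConfig(seed=301)
        from quantos.benchmark import extract_channel_features

        scene = generate_scene(cfg)
        data = extract_channel_features(scene)
        outs = []
        for _ in range(2):
            scored, syn = classify_scene(
                data["pre"]["features"], data["post"]["features"],
                default_model, prior_model, cfg.pixel_size)
            outs.append(syn.to_csv(index=False))
        assert outs[0] == outs[1]


class TestMaturity:
    @pytest.fixture(scope="class")
    def maturity_setup(self):
        from quantos.benchmark import extract_channel_features
        from quantos.classifier import _pairs_within

        def synapse_features(cfg):
            scene = generate_scene(cfg)
            data = extract_channel_features(scene)
            fp = data["pre"]["features"]
            fq = data["post"]["features"]
            pairs = _pairs_within(fp[fp.in_opl], fq[fq.in_opl], cfg.pixel_size, 1.2)
            pre = fp.loc[pairs["pre_index"]].reset_index(drop=True)
            post = fq.loc[pairs["post_index"]].reset_index(drop=True)
            return {"pre": pre, "post": post, "pairs": pairs}, pairs

        mature_cfgs = [SceneConfig(seed=400 + k, noise_region="outside_opl")
                       for k in range(3)]
        # immature regime: dimmer, more diffuse puncta (early development)
        immature_cfgs = [
            SceneConfig(seed=420 + k, noise_region="outside_opl",
                        pre_peak=60.0, post_peak=50.0,
                        pre_sigma_px=2.4, post_sigma_px=1.8)
            for k in range(3)
        ]

        def pooled(cfgs):
            parts = [synapse_features(c)[0] for c in cfgs]
            return {
                "pre": pd.concat([p["pre"] for p in parts], ignore_index=True),
                "post": pd.concat([p["post"] for p in parts], ignore_index=True),
                "pairs": pd.concat([p["pairs"] for p in parts], ignore_index=True),
            }

        mature = pooled(mature_cfgs)
        immature = pooled(immature_cfgs)
        model = build_maturity_model(mature, immature, 0.1)
        return model, mature, immature

    def test_mature_synapses_score_mature(self, maturity_setup):
        model, mature, _ = maturity_setup
        n = len(mature["pairs"])
        syn = mature["pairs"].copy()
        syn["pre_index"] = np.arange(n)
        syn["post_index"] = np.arange(n)
        out = score_maturity(syn, mature["pre"], mature["post"], model)
        assert len(out) == n  # row count preserved
        assert (out["log_mature"] - out["log_immature"]).mean() > 0

    def test_identical_classes_give_zero_difference(self, maturity_setup):
        model, mature, _ = maturity_setup
        sym = ClassModel(
            role="maturity",
            classes=("mature", "immature"),
            marker_densities={
                "mature": model.marker_densities["mature"],
                "immature": model.marker_densities["mature"],
            },
            pair_densities={
                "mature": model.pair_densities["mature"],
                "immature": model.pair_densities["mature"],
            },
            max_dist=1.2,
        )
        n = len(mature["pairs"])
        syn = mature["pairs"].copy()
        syn["pre_index"] = np.arange(n)
        syn["post_index"] = np.arange(n)
        out = score_maturity(syn, mature["pre"], mature["post"], sym)
        assert np.allclose(out["log_mature"], out["log_immature"])

    def test_wrong_role_rejected(self, default_model):
        with pytest.raises(ValueError, match="maturity"):
            score_maturity(pd.DataFrame({"pre_index": [], "post_index": []}),
                           pd.DataFrame(), pd.DataFrame(), default_model)
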