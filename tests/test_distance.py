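"""Distance Analysis: histogram, section moments, weighted distance,
weight optimization, EVI and ROC."""

import numpy as np
import pytest

from flimda import (
    FEATURE_NAMES,
    WEIGHTED_INDICES,
    ContractError,
    DAModel,
    InstrumentConfig,
    PhasorImage,
    assemble_feature_vector,
    build_histogram3d,
    evi_score,
    extract_slice_features,
    fit_group_stats,
    optimize_weights,
    raw_score,
    roc_curve,
    weighted_distance,
)
from flimda.errors import EmptyResultError


def phasor_from_points(g, s, intensity=None, shape=None):
    """Wrap flat (g, s) samples into a PhasorImage for histogramming."""
    g = np.asarray(g, dtype=float)
    if shape is None:
        side = int(np.ceil(np.sqrt(g.size)))
        shape = (side, side)
    n = shape[0] * shape[1]
    pad = n - g.size
    gg = np.concatenate([g, np.full(pad, np.nan)]).reshape(shape)
    ss = np.concatenate([np.asarray(s, float),
                         np.full(pad, np.nan)]).reshape(shape)
    inten = (np.ones(g.size) * 100.0 if intensity is None
             else np.asarray(intensity, float))
    ii = np.concatenate([inten, np.zeros(pad)]).reshape(shape)
    mask = ~np.isnan(gg)
    cfg = InstrumentConfig(width_px=shape[1], height_px=shape[0])
    return PhasorImage(g=gg, s=ss, intensity=ii, mask=mask,
                       calibrated=True, cfg=cfg)


class TestBuildHistogram:
    def test_single_phasor_single_bin(self):
        ph = phasor_from_points([0.43] * 50, [0.27] * 50)
        h = build_histogram3d(ph)
        assert h.counts.sum() == 50
        assert (h.counts > 0).sum() == 1

    def test_count_conservation_random_image(self):
        rng = np.random.default_rng(1)
        n = 400
        ph = phasor_from_points(rng.uniform(0, 1, n), rng.uniform(0, 0.5, n))
        h = build_histogram3d(ph)
        assert h.n_pixels == n
        assert h.section_counts.sum() == n
        # every unmasked pixel is in exactly one section, 1..4
        assert set(np.unique(h.section_assignment[ph.mask])) <= {1, 2, 3, 4}
        assert np.all(h.section_assignment[~ph.mask] == 0)

    def test_two_delta_clusters(self):
        g = np.array([0.22] * 100 + [0.71] * 100)
        s = np.array([0.13] * 100 + [0.42] * 100)
        h = build_histogram3d(phasor_from_points(g, s))
        nz = h.counts[h.counts > 0]
        assert sorted(nz.tolist()) == [100.0, 100.0]

    def test_intensity_sections_track_quartiles(self):
        n = 400
        rng = np.random.default_rng(2)
        inten = np.arange(1, n + 1, dtype=float)
        ph = phasor_from_points(rng.uniform(0.2, 0.8, n),
                                rng.uniform(0.1, 0.5, n), intensity=inten)
        h = build_histogram3d(ph)
        sec = h.section_assignment[ph.mask]
        # dimmest pixels in section 1, brightest in section 4
        assert sec[np.argsort(ph.intensity[ph.mask])[:50]].max() == 1
        assert sec[np.argsort(ph.intensity[ph.mask])[-50:]].min() == 4

    def test_zlevel_mode_sections_by_occupancy(self):
        g = np.array([0.3] * 160 + [0.7] * 40)  # dense and sparse cluster
        s = np.array([0.3] * 160 + [0.4] * 40)
        h = build_histogram3d(phasor_from_points(g, s), mode="zlevel")
        sec = h.section_assignment[h.section_assignment > 0]
        assert set(np.unique(sec)) == {1, 4}

    def test_empty_image_raises(self):
        ph = phasor_from_points([np.nan], [np.nan])
        with pytest.raises(EmptyResultError):
            build_histogram3d(ph)


class TestSliceFeatures:
    def test_isotropic_gaussian_cloud(self):
        rng = np.random.default_rng(3)
        n = 10_000
        g = rng.normal(0.5, 0.02, n)
        s = rng.normal(0.3, 0.02, n)
        h = build_histogram3d(phasor_from_points(g, s))
        # every section sees the same cloud (equal intensities -> quartile
        # split is arbitrary); check the pooled features via section sizes
        feats = [extract_slice_features(h, k) for k in range(1, 5)]
        total = sum(f.n_pixels for f in feats)
        assert total == n
        big = max(feats, key=lambda f: f.n_pixels)
        assert big.a == pytest.approx(0.02, rel=0.10)
        assert big.b == pytest.approx(0.02, rel=0.10)

    def test_collinear_cloud_angle_45(self):
        vals = np.linspace(0.2, 0.6, 500)
        h = build_histogram3d(phasor_from_points(vals, vals))
        f = extract_slice_features(h, 1)  # equal intensities pool in section 1
        assert f.angle_deg == pytest.approx(45.0, abs=2.0)
        assert f.b < 0.01
        assert f.a > 0.05

    def test_single_point_degenerate(self):
        h = build_histogram3d(phasor_from_points([0.4], [0.25]))
        f = extract_slice_features(h, 1)
        assert f.a == 0.0 and f.b == 0.0
        assert f.angle_deg == 0.0  # isotropy convention
        # center within half a bin of the true point
        assert f.g_cm == pytest.approx(0.4, abs=0.006)
        assert f.s_cm == pytest.approx(0.25, abs=0.004)

    def test_angle_range(self):
        rng = np.random.default_rng(4)
        for slope in (-3.0, -0.5, 0.5, 3.0):
            x = rng.uniform(0.3, 0.7, 300)
            y = 0.3 + slope * (x - 0.5) + rng.normal(0, 0.002, 300)
            h = build_histogram3d(phasor_from_points(x, np.clip(y, -0.19, 0.79)))
            f = extract_slice_features(h, 1)
            assert -90.0 <= f.angle_deg < 90.0

    def test_empty_section_zeroed_with_warning(self):
        # constant intensity => all pixels share one quartile boundary fate;
        # construct explicitly: 3 pixels cannot fill 4 sections
        ph = phasor_from_points([0.3, 0.4, 0.5], [0.2, 0.3, 0.4],
                                intensity=[10.0, 20.0, 30.0])
        h = build_histogram3d(ph)
        empties = [k for k in range(1, 5)
                   if h.section_counts[k - 1].sum() == 0]
        assert empties
        with pytest.warns(UserWarning, match="empty"):
            f = extract_slice_features(h, empties[0])
        assert f.n_pixels == 0 and f.a == 0.0


class TestFeatureVector:
    def test_exactly_24_parameters_20_weighted(self):
        rng = np.random.default_rng(5)
        ph = phasor_from_points(rng.uniform(0, 1, 200),
                                rng.uniform(0, 0.5, 200),
                                intensity=rng.uniform(50, 500, 200))
        vec = assemble_feature_vector(build_histogram3d(ph))
        assert vec.shape == (24,)
        assert len(FEATURE_NAMES) == 24
        assert len(WEIGHTED_INDICES) == 20
        assert all(not FEATURE_NAMES[i].endswith("n_pixels")
                   for i in WEIGHTED_INDICES)

    def test_pixel_counts_sum_to_total(self):
        rng = np.random.default_rng(6)
        n = 300
        ph = phasor_from_points(rng.uniform(0, 1, n), rng.uniform(0, 0.5, n),
                                intensity=rng.uniform(50, 500, n))
        vec = assemble_feature_vector(build_histogram3d(ph))
        npx = [vec[i] for i, nm in enumerate(FEATURE_NAMES)
               if nm.endswith("n_pixels")]
        assert sum(npx) == n

    def test_pixel_order_invariance(self):
        rng = np.random.default_rng(7)
        n = 256
        g = rng.uniform(0, 1, n)
        s = rng.uniform(0, 0.5, n)
        inten = rng.uniform(50, 500, n)
        perm = rng.permutation(n)
        v1 = assemble_feature_vector(
            build_histogram3d(phasor_from_points(g, s, inten)))
        v2 = assemble_feature_vector(
            build_histogram3d(phasor_from_points(g[perm], s[perm], inten[perm])))
        np.testing.assert_allclose(v1, v2, atol=1e-12)


def make_vectors(rng, n, mu, sd=1.0):
    return [mu + rng.normal(0, sd, 24) for _ in range(n)]


class TestGroupStatsAndDistance:
    def test_hand_computed_mean_variance(self):
        base = np.zeros(24)
        training = (
            [(base + 1, "H"), (base + 2, "H"), (base + 3, "H")]
            + [(base + 10, "UH"), (base + 12, "UH")]
        )
        mu_H, var_H, mu_UH, var_UH = fit_group_stats(training)
        assert np.allclose(mu_H, 2.0)
        assert np.allclose(var_H, 1.0)
        assert np.allclose(mu_UH, 11.0)
        assert np.allclose(var_UH, 2.0)

    def test_identical_vectors_hit_variance_floor(self):
        v = np.full(24, 3.0)
        mu_H, var_H, *_ = fit_group_stats(
            [(v, "H"), (v, "H"), (v + 1, "UH"), (v + 1, "UH")]
        )
        assert np.allclose(mu_H, 3.0)
        assert np.all(var_H > 0)  # floored, never zero
        assert np.all(var_H < 1e-3)

    def test_distance_zero_at_own_centroid(self):
        rng = np.random.default_rng(8)
        training = [(v, "H") for v in make_vectors(rng, 5, np.zeros(24))]
        training += [(v, "UH") for v in make_vectors(rng, 7, np.ones(24) * 5)]
        model = optimize_weights(training, budget=5)
        assert weighted_distance(model.mu_H, model, "H") == 0.0
        assert weighted_distance(model.mu_UH, model, "UH") == 0.0

    def test_single_weight_one_sd_gives_one(self):
        mu = np.zeros(24)
        var = np.ones(24)
        w = np.zeros(20)
        w[0] = 1.0
        model = DAModel(mu_H=mu, var_H=var, mu_UH=mu + 10, var_UH=var,
                        weights=w, evi_scale=1.0)
        x = mu.copy()
        x[WEIGHTED_INDICES[0]] = 1.0  # one SD from the H mean
        assert weighted_distance(x, model, "H") == pytest.approx(1.0)

    def test_all_zero_weights_give_zero_distance(self):
        model = DAModel(mu_H=np.zeros(24), var_H=np.ones(24),
                        mu_UH=np.ones(24), var_UH=np.ones(24),
                        weights=np.zeros(20), evi_scale=1.0)
        rng = np.random.default_rng(9)
        assert weighted_distance(rng.normal(size=24), model, "H") == 0.0

    def test_score_monotone_from_H_to_UH(self):
        rng = np.random.default_rng(10)
        training = [(v, "H") for v in make_vectors(rng, 6, np.zeros(24))]
        training += [(v, "UH") for v in make_vectors(rng, 6, np.ones(24) * 4)]
        model = optimize_weights(training, budget=5)
        ts = np.linspace(0, 1, 9)
        rs = [raw_score(model.mu_H + t * (model.mu_UH - model.mu_H), model)
              for t in ts]
        assert np.all(np.diff(rs) > 0)


class TestOptimizeWeights:
    def test_informative_parameter_keeps_weight_among_inert_nuisances(self):
        """One parameter separates the groups by 3 SD; the other 19 carry
        no signal at all (constant across embryos).  The optimizer must
        keep full weight on the signal and separate the groups."""
        rng = np.random.default_rng(11)
        informative = WEIGHTED_INDICES[2]
        training = []
        for lbl, shift, n in (("H", 0.0, 20), ("UH", 3.0, 20)):
            for _ in range(n):
                v = np.full(24, 7.0)  # inert nuisance background
                v[informative] = shift + rng.normal(0, 1.0)
                training.append((v, lbl))
        model = optimize_weights(training, budget=100)
        w_inf = model.weights[list(WEIGHTED_INDICES).index(informative)]
        assert w_inf >= 0.9
        scores = [raw_score(x, model) for x, _ in training]
        labels = [lbl for _, lbl in training]
        assert roc_curve(scores, labels)[2] >= 0.95

    def test_optimizer_beats_single_signal_solution_with_noisy_features(self):
        """With 19 iid noise parameters next to one 3-SD signal, the
        coordinate search must end at a training separation at least as
        good as weighting the signal alone, and still classify the
        training set nearly perfectly."""
        from flimda.distance import _score_matrix, _separation

        rng = np.random.default_rng(11)
        mu_H = np.zeros(24)
        mu_UH = np.zeros(24)
        informative = WEIGHTED_INDICES[2]
        mu_UH[informative] = 3.0
        training = [(v, "H") for v in make_vectors(rng, 20, mu_H)]
        training += [(v, "UH") for v in make_vectors(rng, 20, mu_UH)]
        model = optimize_weights(training, budget=100)
        X = np.vstack([x for x, _ in training])
        is_H = np.array([lbl == "H" for _, lbl in training])
        Z = _score_matrix(X, model.mu_H, model.var_H,
                          model.mu_UH, model.var_UH)
        e_inf = np.zeros(20)
        e_inf[list(WEIGHTED_INDICES).index(informative)] = 1.0

        def J(w):
            r = Z @ w
            return _separation(r[is_H], r[~is_H])

        assert model.training_meta["objective"] >= J(e_inf)
        scores = [raw_score(x, model) for x, _ in training]
        labels = [lbl for _, lbl in training]
        assert roc_curve(scores, labels)[2] >= 0.95

    def test_identical_groups_terminate_with_flag(self):
        v = np.arange(24, dtype=float)
        training = [(v + 0.001 * i, "H") for i in range(4)]
        training += [(v + 0.001 * i, "UH") for i in range(4)]
        with pytest.warns(UserWarning, match="indistinguishable"):
            model = optimize_weights(training, budget=3)
        assert model.training_meta["objective"] <= 1e-6

    def test_deterministic(self):
        rng = np.random.default_rng(12)
        training = [(v, "H") for v in make_vectors(rng, 5, np.zeros(24))]
        training += [(v, "UH") for v in make_vectors(rng, 7, np.ones(24))]
        m1 = optimize_weights(training, budget=20)
        m2 = optimize_weights(training, budget=20)
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.evi_scale == m2.evi_scale

    def test_experiment_sized_training_set(self):
        """5 healthy + 7 unhealthy embryos must train without degeneracy."""
        rng = np.random.default_rng(13)
        training = [(v, "H") for v in make_vectors(rng, 5, np.zeros(24))]
        training += [(v, "UH") for v in make_vectors(rng, 7, np.ones(24) * 2)]
        model = optimize_weights(training, budget=100)
        assert np.all(np.isfinite(model.weights))
        assert model.evi_scale > 0


class TestEVI:
    def _model(self):
        rng = np.random.default_rng(14)
        training = [(v, "H") for v in make_vectors(rng, 8, np.zeros(24))]
        training += [(v, "UH") for v in make_vectors(rng, 8, np.ones(24) * 3)]
        return optimize_weights(training, budget=20)

    def test_centroids_predicted_correctly(self):
        model = self._model()
        rh = evi_score(model.mu_H, model)
        ru = evi_score(model.mu_UH, model)
        assert rh.raw_score < 0 and rh.predicted == "H" and rh.evi < 0
        assert ru.raw_score > 0 and ru.predicted == "UH" and ru.evi > 0

    def test_magnitude_bounded_on_extreme_outliers(self):
        model = self._model()
        rng = np.random.default_rng(15)
        for scale in (0.1, 1.0, 100.0):
            for _ in range(20):
                x = rng.normal(0, scale, 24)
                r = evi_score(x, model)
                assert 1.0 <= abs(r.evi) <= 10.0

    def test_sign_convention_flip(self):
        model = self._model()
        default = evi_score(model.mu_H, model)
        flipped = evi_score(model.mu_H, model, healthy_negative=False)
        assert flipped.evi == -default.evi
        assert flipped.predicted == default.predicted == "H"

    def test_training_max_maps_to_ten(self):
        model = self._model()
        # the embryo that set the scale reaches exactly |EVI| = 10
        assert model.evi_scale > 0
        r = 1.0 / model.evi_scale
        assert 1.0 + 9.0 * r * model.evi_scale == pytest.approx(10.0)


class TestROC:
    def test_perfect_separation(self):
        auc = roc_curve([-3, -2, -1, 1, 2, 3],
                        ["H", "H", "H", "UH", "UH", "UH"])[2]
        assert auc == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(16)
        scores = rng.normal(size=200)
        labels = np.array(["H", "UH"])[rng.integers(0, 2, 200)]
        while len(set(labels)) < 2:  # pragma: no cover
            labels = np.array(["H", "UH"])[rng.integers(0, 2, 200)]
        auc = roc_curve(scores, labels)[2]
        assert 0.4 < auc < 0.6

    def test_equals_pair_counting_oracle(self):
        """AUC == Mann-Whitney U / (n_H * n_UH), brute force over pairs."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            scores = rng.integers(-5, 6, 12).astype(float)  # ties likely
            labels = ["H"] * 6 + ["UH"] * 6
            auc = roc_curve(scores, labels)[2]
            h = scores[:6]
            u = scores[6:]
            wins = sum((ui > hi) + 0.5 * (ui == hi) for ui in u for hi in h)
            assert auc == pytest.approx(wins / 36.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            roc_curve([1.0, 2.0], ["H", "H"])
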