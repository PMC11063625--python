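"""Demixed PCA: marginalization identities, axis recovery, variance
accounting, decoding significance, PCA baseline, leave-one-region-out."""

import numpy as np
import pytest

from emomem.dpca import (
    CONDITION_MARGINALIZATIONS,
    MARGINALIZATIONS,
    _fit_axes,
    _flat,
    decode_significance,
    estimate_signal_variance,
    explained_variance,
    fit_dpca,
    leave_one_region_out,
    marginalize,
    pca_baseline,
)
from emomem.psth import PopulationTensor


def random_tensor(rng, N=12, E=2, M=2, T=40):
    return rng.normal(0, 1, (N, E, M, T))


def planted_emotion_tensor(rng, N=20, T=40, snr=np.inf):
    """Rank-1 emotion structure g_u * s(t) * sign(e), plus optional noise."""
    g = rng.normal(0, 1, N)
    s = np.exp(-0.5 * ((np.linspace(-0.5, 2.5, T) - 0.4) / 0.25) ** 2)
    X = np.zeros((N, 2, 2, T))
    for e, sign in enumerate((1.0, -1.0)):
        X[:, e, :, :] = sign * np.outer(g, s)[:, None, :]
    if np.isfinite(snr):
        noise_sd = np.sqrt(np.var(X) / snr)
        X = X + rng.normal(0, noise_sd, X.shape)
    return X, g / np.linalg.norm(g)


def make_population(rng, X, n_trials=8, noise_sd=0.5, regions=None):
    """Wrap an average tensor as a PopulationTensor with noisy trials."""
    N, E, M, T = X.shape
    trials = [
        [
            [X[u, e, m] + rng.normal(0, noise_sd, (n_trials, T))
             for m in range(M)]
            for e in range(E)
        ]
        for u in range(N)
    ]
    avg = np.array(
        [[[trials[u][e][m].mean(axis=0) for m in range(M)] for e in range(E)]
         for u in range(N)]
    )
    return PopulationTensor(
        unit_ids=[f"u{i}" for i in range(N)],
        regions=regions or ["HIP"] * N,
        patient_ids=["p0"] * N,
        emotions=("emotional", "neutral"),
        memory_levels=("R", "F") if M == 2 else ("RHit", "Miss", "CR"),
        time=np.linspace(-0.5, 2.5, T),
        avg=avg,
        trial_rates=trials,
        counts=np.full((N, E, M), n_trials),
        dropped_units=[],
    )


class TestMarginalize:
    def test_condition_independent_tensor_has_null_condition_terms(self, rng):
        base = rng.normal(0, 1, (10, 1, 1, 30))
        X = np.tile(base, (1, 2, 2, 1))
        ms = marginalize(X)
        for k in ("emotion", "memory", "interaction"):
            assert np.abs(ms.terms[k]).max() == pytest.approx(0.0, abs=1e-12)

    def test_additive_exact_reconstruction(self, rng):
        X = random_tensor(rng)
        ms = marginalize(X)
        rel = np.abs(ms.reconstruction() - X).max() / np.abs(X).max()
        assert rel < 1e-10

    def test_pure_emotion_plant_all_variance_in_emotion_term(self, rng):
        X, _ = planted_emotion_tensor(rng)
        ms = marginalize(X)
        var_e = np.sum(ms.terms["emotion"] ** 2)
        var_cond = sum(
            np.sum(ms.terms[k] ** 2)
            for k in ("emotion", "memory", "interaction")
        )
        assert var_e / var_cond == pytest.approx(1.0, abs=1e-12)

    def test_singleton_axis_rejected(self, rng):
        with pytest.raises(ValueError):
            marginalize(rng.normal(0, 1, (5, 1, 2, 10)))


class TestFitDPCA:
    def test_pca_limit_matches_svd_oracle(self, rng):
        """lambda=0 with a single full marginalization reduces to PCA."""
        X = random_tensor(rng, N=10)
        Xf = _flat(X - X.mean(axis=(1, 2, 3), keepdims=True))
        F, D, _ = _fit_axes(Xf, {"time": Xf}, mu=0.0, q=5)
        U = np.linalg.svd(Xf, full_matrices=False)[0][:, :5]
        for k in range(5):
            cos = abs(F[:, k] @ U[:, k])
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_noiseless_planted_axis_recovered(self, rng):
        X, axis = planted_emotion_tensor(rng)
        model = fit_dpca(X, n_components=6)
        c = model.components_of("emotion")[0]
        d = model.decoders[c]
        cos = abs(d @ axis) / np.linalg.norm(d)
        assert cos > 0.99

    def test_noisy_axis_recovery_at_snr_5(self):
        """Replicate-averaged decoder-axis cosine stays above 0.9 at SNR 5."""
        cosines = []
        for rep in range(10):
            rng = np.random.default_rng(300 + rep)
            X, axis = planted_emotion_tensor(rng, snr=5.0)
            model = fit_dpca(X, n_components=6)
            c = model.components_of("emotion")[0]
            d = model.decoders[c]
            cosines.append(abs(d @ axis) / np.linalg.norm(d))
        assert np.mean(cosines) > 0.9

    def test_zero_tensor_no_nans(self):
        model = fit_dpca(np.zeros((6, 2, 2, 10)), n_components=3)
        assert np.isfinite(model.explained_var_pct).all()
        assert model.explained_var_pct.max() == 0.0

    def test_demixing_quality_on_planted_data(self, rng):
        """Each condition component's variance concentrates in its own
        marginalization."""
        N, T = 18, 40
        t = np.linspace(-0.5, 2.5, T)
        s = np.exp(-0.5 * ((t - 0.4) / 0.3) ** 2)
        X = np.zeros((N, 2, 2, T))
        ge, gm = rng.normal(0, 1, N), rng.normal(0, 1, N)
        for e in range(2):
            for m in range(2):
                X[:, e, m] = (
                    np.outer(ge, s) * (1 if e == 0 else -1)
                    + np.outer(gm, s**2) * (1 if m == 0 else -1)
                )
        model = fit_dpca(X, n_components=8)
        for phi in ("emotion", "memory"):
            c = model.components_of(phi)[0]
            j = MARGINALIZATIONS.index(phi)
            assert model.marg_var_pct[c, j] > 90.0

    def test_n_components_cannot_exceed_units(self, rng):
        with pytest.raises(ValueError):
            fit_dpca(random_tensor(rng, N=4), n_components=10)

    def test_encoders_orthonormal_within_marginalization(self, rng):
        model = fit_dpca(random_tensor(rng, N=15), n_components=10)
        for phi in MARGINALIZATIONS:
            comps = model.components_of(phi)
            if comps.size < 2:
                continue
            F = model.encoders[:, comps]
            gram = F.T @ F
            assert np.abs(gram - np.eye(len(comps))).max() < 1e-6

    def test_lambda_cv_runs_and_picks_grid_value(self, rng):
        X, _ = planted_emotion_tensor(rng, N=10)
        pop = make_population(rng, X, n_trials=5)
        model = fit_dpca(pop, single_trials=pop, n_components=4, lam="cv",
                         seed=0, n_folds=3)
        assert model.regularization >= 0.0


class TestExplainedVariance:
    def test_pie_shares_sum_to_100(self, rng):
        model = fit_dpca(random_tensor(rng, N=15), n_components=10)
        rep = explained_variance(model, first_k=8)
        assert sum(rep["pie_normalized_pct"].values()) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_cumulative_curve_non_decreasing(self, rng):
        model = fit_dpca(random_tensor(rng, N=15), n_components=10)
        rep = explained_variance(model)
        cum = np.asarray(rep["cumulative_pct"])
        assert (np.diff(cum) >= -1e-12).all()

    def test_pure_emotion_plant_dominates_condition_variance(self, rng):
        X, _ = planted_emotion_tensor(rng)
        model = fit_dpca(X, n_components=6)
        rep = explained_variance(model)["marginalization_totals_pct"]
        cond = rep["emotion"] + rep["memory"] + rep["interaction"]
        assert rep["emotion"] / cond > 0.999


class TestSignalVariance:
    def test_noiseless_trials_give_fraction_one(self, rng):
        X = random_tensor(rng, N=8)
        pop = make_population(rng, X, n_trials=4, noise_sd=0.0)
        assert estimate_signal_variance(pop) == pytest.approx(1.0)

    def test_pure_noise_small_fraction(self, rng):
        X = np.zeros((10, 2, 2, 20))
        pop = make_population(rng, X, n_trials=20, noise_sd=1.0)
        assert estimate_signal_variance(pop) <= 0.1

    def test_fewer_trials_more_noise_share(self, rng):
        X, _ = planted_emotion_tensor(rng, N=10)
        noise_shares = []
        for n_trials in (16, 8):
            r = np.random.default_rng(0)
            pop = make_population(r, X, n_trials=n_trials, noise_sd=1.0)
            noise_shares.append(1 - estimate_signal_variance(pop))
        assert noise_shares[1] > noise_shares[0]


class TestDecoding:
    def _window_tensor(self, rng, N=12, T=60, lo=0.2, hi=0.8):
        """Emotion separation confined to a known time window."""
        t = np.linspace(-0.5, 2.5, T)
        bump = ((t >= lo) & (t < hi)).astype(float)
        g = np.abs(rng.normal(1.0, 0.2, N))
        X = np.zeros((N, 2, 2, T))
        X[:, 0, :, :] = np.outer(g, bump)[:, None, :]
        X[:, 1, :, :] = -np.outer(g, bump)[:, None, :]
        return X, t, (t >= lo) & (t < hi)

    def test_perfect_separation_gives_accuracy_one(self, rng):
        X, _, _ = self._window_tensor(rng, lo=-0.5, hi=2.6)
        pop = make_population(rng, X, n_trials=6, noise_sd=0.01)
        model = fit_dpca(pop, n_components=4)
        sig = decode_significance(model, pop, "emotion", n_iter=30,
                                  n_shuffles=20, seed=0)
        assert sig.accuracy.min() > 0.99

    def test_planted_window_localized(self, rng):
        X, t, in_win = self._window_tensor(rng)
        pop = make_population(rng, X, n_trials=8, noise_sd=0.3)
        model = fit_dpca(pop, n_components=4)
        sig = decode_significance(model, pop, "emotion", n_iter=50,
                                  n_shuffles=50, seed=0)
        # significance covers the planted window and stays concentrated there
        assert sig.significant[in_win].mean() >= 0.8
        assert sig.significant[~in_win].mean() <= 0.2

    def test_label_shuffled_input_calibrated(self):
        """Condition labels carry no signal: few significant bins."""
        fractions = []
        for rep in range(4):
            rng = np.random.default_rng(400 + rep)
            X = np.zeros((10, 2, 2, 25))
            pop = make_population(rng, X, n_trials=8, noise_sd=1.0)
            model = fit_dpca(pop, n_components=4)
            sig = decode_significance(model, pop, "emotion", n_iter=40,
                                      n_shuffles=40, seed=rep)
            fractions.append(sig.significant.mean())
        assert np.mean(fractions) <= 0.07

    def test_accuracy_bounded_and_mask_matches_quantile(self, rng):
        X, _, _ = self._window_tensor(rng)
        pop = make_population(rng, X, n_trials=6, noise_sd=0.5)
        model = fit_dpca(pop, n_components=4)
        sig = decode_significance(model, pop, "emotion", n_iter=20,
                                  n_shuffles=20, seed=1)
        assert ((sig.accuracy >= 0) & (sig.accuracy <= 1)).all()
        np.testing.assert_array_equal(
            sig.significant, sig.accuracy > sig.shuffle_q975
        )

    def test_time_marginalization_not_decodable(self, rng):
        model = fit_dpca(random_tensor(rng, N=8), n_components=4)
        with pytest.raises(ValueError):
            decode_significance(model, None, "time")


class TestPCABaseline:
    def test_pca_compression_at_least_dpca(self, rng):
        X = random_tensor(rng, N=15)
        model = fit_dpca(X, n_components=5)
        pca = pca_baseline(X, n_components=5)
        assert pca.explained_var_pct.sum() >= \
            model.explained_var_pct[:5].sum() - 1e-9

    def test_orthonormal_loadings(self, rng):
        pca = pca_baseline(random_tensor(rng, N=10), n_components=5)
        gram = pca.loadings.T @ pca.loadings
        assert np.abs(gram - np.eye(5)).max() < 1e-10

    def test_rank_one_input_single_component(self, rng):
        u = rng.normal(0, 1, 8)
        v = rng.normal(0, 1, 2 * 2 * 20)
        X = np.outer(u, v).reshape(8, 2, 2, 20)
        X = X - X.mean(axis=(1, 2, 3), keepdims=True)
        pca = pca_baseline(X, n_components=4)
        assert pca.explained_var_pct[0] == pytest.approx(100.0, abs=1e-6)


class TestLeaveOneRegionOut:
    def _regional_population(self, rng):
        """Emotion structure carried only by AMY units."""
        N, T = 15, 30
        regions = (["AMY"] * 5 + ["HIP"] * 5 + ["EC"] * 5)
        t = np.linspace(-0.5, 2.5, T)
        bump = np.exp(-0.5 * ((t - 0.4) / 0.3) ** 2)
        X = np.zeros((N, 2, 2, T))
        for u in range(5):   # AMY only
            X[u, 0, :, :] = 2.0 * bump
            X[u, 1, :, :] = -2.0 * bump
        return make_population(rng, X, n_trials=8, noise_sd=0.4,
                               regions=regions)

    def test_excluding_empty_region_identity(self, rng):
        X = random_tensor(rng, N=6)
        pop = make_population(rng, X, n_trials=4)
        pop.regions[:] = ["HIP"] * 6
        rep = leave_one_region_out(pop, "EC", n_components=3, decode=False,
                                   seed=0)
        full = fit_dpca(pop, single_trials=pop, n_components=3, seed=0)
        np.testing.assert_allclose(rep["model"].decoders, full.decoders)

    def test_removing_amygdala_abolishes_emotion_significance(self, rng):
        pop = self._regional_population(rng)
        kw = dict(n_components=4, n_iter=30, n_shuffles=30, seed=0)
        no_amy = leave_one_region_out(pop, "AMY", **kw)
        no_ec = leave_one_region_out(pop, "EC", **kw)
        frac_no_amy = no_amy["significance"]["emotion"].significant.mean()
        frac_no_ec = no_ec["significance"]["emotion"].significant.mean()
        assert frac_no_ec > 0.5
        assert frac_no_amy < 0.1
        # variance share shifts away from emotion when AMY is removed
        assert no_amy["marg_totals_pct"]["emotion"] < \
            no_ec["marg_totals_pct"]["emotion"]

    def test_loop_over_regions_gives_three_reports(self, rng):
        pop = self._regional_population(rng)
        reports = [
            leave_one_region_out(pop, r, n_components=4, decode=False, seed=0)
            for r in ("HIP", "AMY", "EC")
        ]
        assert len(reports) == 3
        assert {r["excluded_region"] for r in reports} == {"HIP", "AMY", "EC"}
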