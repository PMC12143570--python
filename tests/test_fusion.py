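"""Pattern enumeration, count features, and the logistic fusion family."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from burstfusion import (
    count_window_features,
    enumerate_patterns,
    fit_classifier,
    lf_features,
    make_task_config,
)
from burstfusion.fusion import FusionClassifier, count_features_batch, lf_features_batch
from burstfusion.task import batch_arrays, sample_batch

# the worked 2-channel, 4-step example: channel 1 = (-1,-1,-1,1), channel 2 = (-1,-1,-1,0)
X_EXAMPLE = np.array([[-1, -1, -1, 1], [-1, -1, -1, 0]])


class TestEnumeration:
    def test_two_channel_window_two(self):
        table = enumerate_patterns(2, 2)
        assert table.size == 81
        pats = table.patterns
        np.testing.assert_array_equal(pats[0], [-1, -1, -1, -1])
        np.testing.assert_array_equal(pats[1], [-1, -1, -1, 0])
        np.testing.assert_array_equal(pats[-1], [1, 1, 1, 1])
        # complete and duplicate-free
        assert len({tuple(p) for p in pats}) == 81

    @pytest.mark.parametrize("nc,w,size", [(1, 1, 3), (2, 1, 9), (2, 3, 729)])
    def test_sizes(self, nc, w, size):
        assert enumerate_patterns(nc, w).size == size

    def test_resource_cap(self):
        with pytest.raises(ValueError, match="cap"):
            enumerate_patterns(2, 6)  # 3^12 > default 3^10

    def test_index_roundtrip(self):
        table = enumerate_patterns(2, 2)
        for idx in (0, 40, 80):
            assert table.index_of(table.patterns[idx]) == idx


class TestWindowCounts:
    def test_worked_example(self):
        table = enumerate_patterns(2, 2)
        counts = count_window_features(X_EXAMPLE, table)
        assert counts[table.index_of([-1, -1, -1, -1])] == 2
        assert counts[table.index_of([-1, 1, -1, 0])] == 1
        assert counts.sum() == 3  # all other patterns have count 0

    def test_all_zero_trial(self):
        table = enumerate_patterns(2, 2)
        counts = count_window_features(np.zeros((2, 5), dtype=int), table)
        assert counts[table.index_of([0, 0, 0, 0])] == 4
        assert counts.sum() == 4

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(x=arrays(np.int8, (2, 9), elements=st.integers(-1, 1)), w=st.integers(1, 3))
    def test_total_counts_identity(self, x, w):
        table = enumerate_patterns(2, w)
        assert count_window_features(x, table).sum() == 9 - w + 1

    def test_too_short_trial_rejected(self):
        table = enumerate_patterns(2, 3)
        with pytest.raises(ValueError, match="shorter"):
            count_window_features(np.zeros((2, 2), dtype=int), table)

    def test_batch_matches_single_and_sparse(self):
        rng = np.random.default_rng(0)
        x = rng.integers(-1, 2, size=(7, 2, 12))
        table = enumerate_patterns(2, 2)
        dense = count_features_batch(x, table)
        sparse = count_features_batch(x, table, sparse=True).toarray()
        np.testing.assert_array_equal(dense, sparse)
        for i in range(7):
            np.testing.assert_array_equal(dense[i], count_window_features(x[i], table))


class TestLFFeatures:
    def test_worked_example_tally(self):
        np.testing.assert_array_equal(lf_features(X_EXAMPLE), [3, 0, 1, 3, 1, 0])

    def test_order_free(self):
        rng = np.random.default_rng(1)
        x = rng.integers(-1, 2, size=(2, 20))
        shuffled = x[:, rng.permutation(20)]
        np.testing.assert_array_equal(lf_features(x), lf_features(shuffled))

    def test_lf_is_marginal_of_nlf(self):
        # LF features are a fixed linear projection of the w=1 pattern counts
        rng = np.random.default_rng(2)
        x = rng.integers(-1, 2, size=(5, 2, 15))
        table = enumerate_patterns(2, 1)
        nlf = count_features_batch(x, table)
        proj = np.zeros((table.size, 6))
        for p_idx, pat in enumerate(table.patterns):
            for ch in range(2):
                proj[p_idx, 3 * ch + (pat[ch] + 1)] = 1
        np.testing.assert_array_equal(nlf @ proj, lf_features_batch(x))


@pytest.fixture(scope="module")
def fitted(k3_batch):
    _, m, x, _ = k3_batch
    return {
        "lf": fit_classifier(x, m, "lf"),
        "nlf": fit_classifier(x, m, "nlf"),
        "nlf2": fit_classifier(x, m, "nlf_w", w=2),
    }


class TestClassifier:
    def test_parameter_counts(self, fitted):
        assert fitted["lf"].n_parameters == 6
        assert fitted["nlf"].n_parameters == 9
        assert fitted["nlf2"].n_parameters == 81

    def test_separable_batch_perfect_training_accuracy(self):
        # +1 trials show +1 bursts, -1 trials show -1 bursts, no noise
        x = np.zeros((40, 2, 10), dtype=int)
        y = np.repeat([1, -1], 20)
        x[:20, :, 3] = 1
        x[20:, :, 3] = -1
        clf = fit_classifier(x, y, "nlf")
        assert (clf.predict(x) == y).mean() == 1.0

    def test_pure_noise_accuracy_near_chance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(-1, 2, size=(2000, 2, 30))
        y = np.tile([1, -1], 1000)
        clf = fit_classifier(x[:1000], y[:1000], "nlf")
        acc = (clf.predict(x[1000:]) == y[1000:]).mean()
        assert abs(acc - 0.5) < 4 * np.sqrt(0.25 / 1000)

    def test_single_class_batch_rejected(self):
        x = np.zeros((10, 2, 5), dtype=int)
        with pytest.raises(ValueError, match="single class"):
            fit_classifier(x, np.ones(10), "nlf")

    def test_unfitted_predict_rejected(self):
        clf = FusionClassifier("nlf")
        with pytest.raises(RuntimeError, match="not been fitted"):
            clf.predict(np.zeros((1, 2, 5)))

    def test_symmetric_trial_scores_half(self, fitted):
        # an all-zero trial carries no direction evidence, so a model that
        # respects the task's label symmetry must score it exactly 0.5; we
        # enforce the symmetry by antisymmetrising the fitted coefficients
        # (pattern p and its sign-flip -p, at index size-1-idx, get opposite
        # weights) and check the documented tie rule maps 0.5 to +1
        payload = fitted["nlf"].to_dict()
        coefs = np.asarray(payload["coefficients"])
        payload["coefficients"] = ((coefs - coefs[::-1]) / 2).tolist()
        payload["intercept"] = 0.0
        sym = FusionClassifier.from_dict(payload)
        zero_trial = np.zeros((1, 2, 200), dtype=int)
        assert sym.predict_proba(zero_trial)[0] == 0.5
        assert sym.predict(zero_trial)[0] == 1

    def test_prediction_deterministic(self, fitted, k3_batch):
        _, _, x, _ = k3_batch
        a = fitted["nlf2"].predict(x[:50])
        b = fitted["nlf2"].predict(x[:50])
        np.testing.assert_array_equal(a, b)

    def test_time_shuffle_invariance_lf_nlf_but_not_nlf2(self, fitted, k3_batch):
        _, _, x, _ = k3_batch
        rng = np.random.default_rng(7)
        perm = rng.permutation(x.shape[2])
        shuffled = x[:100][:, :, perm]
        for kind in ("lf", "nlf"):
            np.testing.assert_array_equal(
                fitted[kind].predict(x[:100]), fitted[kind].predict(shuffled)
            )
        # witness: some trial changes its NLF_2 score under shuffling
        s_orig = fitted["nlf2"].predict_proba(x[:100])
        s_shuf = fitted["nlf2"].predict_proba(shuffled)
        assert np.max(np.abs(s_orig - s_shuf)) > 1e-6

    def test_nlf_is_special_case_of_window_family(self, k3_batch):
        _, _, x, _ = k3_batch
        clf_nlf = FusionClassifier("nlf", n_channels=2)
        clf_w1 = FusionClassifier("nlf_w", n_channels=2, w=1)
        np.testing.assert_array_equal(
            clf_nlf.features(x[:20]), clf_w1.features(x[:20])
        )

    def test_serialisation_roundtrip(self, fitted, k3_batch):
        _, _, x, _ = k3_batch
        clf = FusionClassifier.from_dict(fitted["nlf2"].to_dict())
        np.testing.assert_allclose(
            clf.predict_proba(x[:30]), fitted["nlf2"].predict_proba(x[:30])
        )


class TestCoefficientInterpretation:
    def test_large_sample_coefficients_track_log_likelihood_ratios(self):
        """With weak regularisation the fitted w=1 coefficients reproduce the
        analytic per-pattern log-likelihood-ratio differences of the k=1 task."""
        config = make_task_config(kind="fixed", k=1, seed=31)
        m, x, _ = batch_arrays(sample_batch(config, 30_000, seed=31))[0:3]
        clf = fit_classifier(x, m, "nlf", C=1e4)
        table = clf.table

        def pattern_llr(pat):
            # mixture over the hidden emission state at one time step
            def lik(mm):
                p = 1.0
                for v in pat:
                    if v == 0:
                        p_sig, p_noise = 1 - config.p_c - config.p_i, config.p_n
                    elif v == mm:
                        p_sig, p_noise = config.p_c, (1 - config.p_n) / 2
                    else:
                        p_sig, p_noise = config.p_i, (1 - config.p_n) / 2
                    p *= p_sig
                q = 1.0
                for v in pat:
                    q *= config.p_n if v == 0 else (1 - config.p_n) / 2
                return config.p_e * p + (1 - config.p_e) * q

            return np.log(lik(1) / lik(-1))

        coefs = clf.coefficients
        # counts sum to n, so only coefficient *differences* are identified
        i_pp = table.index_of([1, 1])
        i_mm = table.index_of([-1, -1])
        i_p0 = table.index_of([1, 0])
        fitted_diff = coefs[i_pp] - coefs[i_mm]
        analytic_diff = pattern_llr([1, 1]) - pattern_llr([-1, -1])
        assert fitted_diff == pytest.approx(analytic_diff, abs=0.04)
        fitted_diff2 = coefs[i_p0] - coefs[i_mm]
        analytic_diff2 = pattern_llr([1, 0]) - pattern_llr([-1, -1])
        assert fitted_diff2 == pytest.approx(analytic_diff2, abs=0.04)
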