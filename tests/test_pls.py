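"""Behavioral PLS: assembly, stacked correlations, SVD, resampling."""

import numpy as np
import pandas as pd
import pytest

from headnet.pls import (
    assemble_brain_matrix,
    band_bootstrap_summary,
    bootstrap_saliences,
    contrast_pls,
    delta_scalp_vs_exposure,
    permutation_test,
    scalp_scores,
    stacked_correlation,
    svd_pls,
)


def toy_inputs(n_sub=4, n_ch=4, n_freq=3, rng=None):
    rng = rng or np.random.default_rng(0)
    subjects = [f"S{i}" for i in range(n_sub)]
    pairs = [(f"C{i}", f"C{j}") for i in range(n_ch) for j in range(i + 1, n_ch)]
    freqs = np.linspace(2, 6, n_freq)
    d = {(s, ses): rng.random((len(pairs), n_freq)) for s in subjects for ses in ("pre", "post")}
    c = {k: rng.random((len(pairs), n_freq)) for k in d}
    p = {k: rng.random((n_ch, n_freq)) for k in d}
    return d, c, p, subjects, pairs, [f"C{i}" for i in range(n_ch)], freqs


class TestAssembleBrainMatrix:
    def test_toy_dimensions(self):
        brain, rows, cols = assemble_brain_matrix(*toy_inputs())
        assert brain.shape == (8, 6 * 3 + 6 * 3 + 4 * 3)
        assert (cols["block"] == "dwpli").sum() == 18
        assert (cols["block"] == "spd").sum() == 12
        assert list(rows["session"][:2]) == ["pre", "post"]

    def test_missing_session_raises(self):
        d, c, p, subjects, pairs, chans, freqs = toy_inputs()
        del d[(subjects[0], "post")]
        with pytest.raises(ValueError):
            assemble_brain_matrix(d, c, p, subjects, pairs, chans, freqs)

    def test_column_order_pair_major_then_frequency(self):
        d, c, p, subjects, pairs, chans, freqs = toy_inputs()
        brain, rows, cols = assemble_brain_matrix(d, c, p, subjects, pairs, chans, freqs)
        key = (subjects[0], "pre")
        np.testing.assert_array_equal(brain[0, : len(freqs)], d[key][0])
        np.testing.assert_array_equal(cols["freq"][: len(freqs)], freqs)


class TestStackedCorrelation:
    def test_brain_column_equal_to_behavior_gives_one(self, rng):
        n = 10
        beh = rng.standard_normal((2 * n, 2))
        conds = np.array(["pre", "post"] * n)
        brain = rng.standard_normal((2 * n, 5))
        brain[conds == "pre", 0] = beh[conds == "pre", 0]
        R = stacked_correlation(brain, beh, conds)
        assert R[0, 0] == pytest.approx(1.0)

    def test_consistent_subject_permutation_invariance(self, rng):
        n = 8
        brain = rng.standard_normal((2 * n, 6))
        beh = rng.standard_normal((2 * n, 2))
        conds = np.array(["pre"] * n + ["post"] * n)
        perm = np.concatenate([rng.permutation(n), n + rng.permutation(n)])
        np.testing.assert_allclose(
            stacked_correlation(brain, beh, conds),
            stacked_correlation(brain[perm], beh[perm], conds),
        )

    def test_zero_variance_brain_column_warns_and_zeroes(self, rng):
        brain = rng.standard_normal((8, 3))
        brain[:, 1] = 5.0
        beh = rng.standard_normal((8, 2))
        conds = np.array(["pre", "post"] * 4)
        with pytest.warns(UserWarning):
            R = stacked_correlation(brain, beh, conds)
        assert np.all(R[:, 1] == 0.0)

    def test_null_entries_at_sampling_scale(self, rng):
        n = 50
        brain = rng.standard_normal((2 * n, 400))
        beh = rng.standard_normal((2 * n, 2))
        conds = np.array(["pre", "post"] * n)
        R = stacked_correlation(brain, beh, conds)
        assert abs(R.std() - 1 / np.sqrt(n - 1)) < 0.03


class TestSvdPls:
    def test_rank_one_explains_everything(self):
        R = np.outer([1.0, 0.5, 0.2, 0.1], np.linspace(1, 2, 30))
        model = svd_pls(R)
        assert model.covariance_explained[0] == pytest.approx(1.0)

    def test_orthonormal_saliences(self, rng):
        model = svd_pls(rng.standard_normal((4, 50)))
        np.testing.assert_allclose(
            model.behavior_saliences.T @ model.behavior_saliences, np.eye(4), atol=1e-10
        )
        np.testing.assert_allclose(
            model.brain_saliences.T @ model.brain_saliences, np.eye(4), atol=1e-10
        )

    def test_singular_values_non_increasing_and_shares_sum_to_one(self, rng):
        model = svd_pls(rng.standard_normal((4, 50)))
        assert np.all(np.diff(model.singular_values) <= 0)
        assert model.covariance_explained.sum() == pytest.approx(1.0)

    def test_planted_rank_one_salience_recovered(self, rng):
        u = np.array([0.1, 0.2, 0.9, 0.1])
        u /= np.linalg.norm(u)
        v = rng.standard_normal(200)
        v /= np.linalg.norm(v)
        R = 3.0 * np.outer(u, v) + 0.01 * rng.standard_normal((4, 200))
        model = svd_pls(R)
        angle = np.degrees(np.arccos(abs(model.brain_saliences[:, 0] @ v)))
        assert angle < 5.0

    def test_contrast_mode_projects_onto_supplied_weights(self, rng):
        R = rng.standard_normal((4, 30))
        contrasts = np.array([[1.0, -1.0], [1.0, 1.0], [-1.0, -1.0], [-1.0, 1.0]]) / 2
        model = contrast_pls(R, contrasts)
        np.testing.assert_allclose(
            model.brain_saliences[:, 0] * model.singular_values[0],
            R.T @ contrasts[:, 0],
        )


class TestPermutationTest:
    def test_planted_lv_significant(self, rng):
        n = 18
        latent = rng.standard_normal(2 * n)
        brain = 0.8 * np.outer(latent, rng.standard_normal(60)) + rng.standard_normal((2 * n, 60))
        beh = np.column_stack([latent + 0.5 * rng.standard_normal(2 * n), rng.standard_normal(2 * n)])
        conds = np.array(["pre", "post"] * n)
        p = permutation_test(brain, beh, conds, 200, 0)
        assert p[0] <= 0.05

    def test_observed_from_null_gives_large_p(self, rng):
        n = 12
        brain = rng.standard_normal((2 * n, 20))
        beh = rng.standard_normal((2 * n, 2))
        conds = np.array(["pre", "post"] * n)
        p = permutation_test(brain, beh, conds, 200, 1)
        assert p[0] >= 1.0 / 200

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_test(
                rng.standard_normal((8, 5)),
                rng.standard_normal((8, 2)),
                np.array(["pre", "post"] * 4),
                10,
                0,
            )


class TestBootstrapSaliences:
    def test_behavior_sign_flip_leaves_magnitudes(self, rng):
        n = 10
        brain = rng.standard_normal((2 * n, 15))
        beh = rng.standard_normal((2 * n, 2))
        conds = np.array(["pre", "post"] * n)
        sids = np.repeat(np.arange(n), 2)
        a = bootstrap_saliences(brain, beh, conds, sids, 100, 3)
        flipped = beh.copy()
        flipped[:, 0] = -flipped[:, 0]
        b = bootstrap_saliences(brain, flipped, conds, sids, 100, 3)
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-8)

    def test_planted_block_sensitivity(self, rng):
        n = 18
        latent = rng.standard_normal(2 * n)
        brain = rng.standard_normal((2 * n, 40))
        brain[:, :10] += 1.5 * latent[:, None]
        beh = np.column_stack([latent + 0.3 * rng.standard_normal(2 * n), rng.standard_normal(2 * n)])
        conds = np.array(["pre", "post"] * n)
        sids = np.repeat(np.arange(n), 2)
        ratios = bootstrap_saliences(brain, beh, conds, sids, 150, 4)
        sensitivity = (np.abs(ratios[:10, 0]) > 1.96).mean()
        assert sensitivity >= 0.8


class TestScalpScores:
    def test_row_equal_to_salience_scores_norm(self):
        v = np.zeros((4, 1))
        v[:, 0] = [0.5, 0.5, 0.5, 0.5]
        brain = v[:, 0][None, :]
        assert scalp_scores(brain, v)[0, 0] == pytest.approx(1.0)

    def test_orthogonal_row_scores_zero(self):
        v = np.array([[1.0], [0.0]])
        brain = np.array([[0.0, 3.0]])
        assert scalp_scores(brain, v)[0, 0] == 0.0

    def test_hand_computation(self):
        brain = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 0.0, 1.0], [2.0, 0.0, 1.0, 0.0]])
        v = np.array([[1.0], [0.5], [-1.0], [0.0]])
        np.testing.assert_allclose(scalp_scores(brain, v)[:, 0], [-1.0, 0.5, 1.0])


class TestDeltaScalpVsExposure:
    def test_constant_exposure_raises(self, rng):
        rows = pd.DataFrame(
            {"subject_id": ["a", "a", "b", "b"], "session": ["pre", "post"] * 2}
        )
        scores = rng.standard_normal(4)
        exposure = pd.Series([1.0, 1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            delta_scalp_vs_exposure(scores, rows, exposure)

    def test_planted_linear_link_recovered(self, rng):
        subjects = [f"s{i}" for i in range(12)]
        exposure = pd.Series(rng.lognormal(0, 1, 12), index=subjects)
        rows = pd.DataFrame(
            [
                {"subject_id": s, "session": ses}
                for s in subjects
                for ses in ("pre", "post")
            ]
        )
        scores = np.array(
            [
                0.0 if ses == "pre" else 2.0 * exposure[s] + 0.1 * rng.standard_normal()
                for s in subjects
                for ses in ("pre", "post")
            ]
        )
        res = delta_scalp_vs_exposure(scores, rows, exposure, n_boot=100, seed=0)
        assert res["r"] > 0.9


class TestBandBootstrapSummary:
    def test_hand_built_ratio_vector(self):
        cols = pd.DataFrame(
            {
                "block": ["dwpli"] * 4 + ["coh"] * 2,
                "freq": [2.0, 3.0, 5.0, 6.0, 2.0, 3.0],
            }
        )
        ratios = np.array([3.0, 3.0, -2.5, 1.0, 9.9, 9.9])
        with pytest.warns(UserWarning):
            out = band_bootstrap_summary(ratios, cols)
        assert out["delta"] == pytest.approx(3.0)  # coh block excluded
        assert out["theta"] == pytest.approx(-2.5)  # sub-threshold 1.0 excluded
        assert out["gamma"] == 0.0
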