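import numpy as np
import pandas as pd
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform

from nitrilink.diversity import alpha_diversity, bray_curtis
from nitrilink.link import (
    CollinearityError,
    adjusted_r2,
    aic_select,
    composition_model,
    composition_models,
    dbrda,
    diversity_models,
    fit_mlr,
    hierarchical_partition,
    lag_models,
    pcoa,
    rf_importance,
)
from nitrilink.subcommunity import SubcommunitySet


def distance_frame(points, ids=None):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return pd.DataFrame(d, index=ids, columns=ids)


def procrustes_error(recovered, original):
    a = recovered - recovered.mean(axis=0)
    b = original - original.mean(axis=0)
    r, _ = orthogonal_procrustes(a, b)
    return np.linalg.norm(a @ r - b)


class TestAdjustedR2:
    def test_closed_form(self):
        assert adjusted_r2(0.5, n=10, p=3) == pytest.approx(0.25)

    def test_negative_at_zero_r2(self):
        assert adjusted_r2(0.0, n=10, p=3) == pytest.approx(-0.5)

    def test_never_exceeds_r2(self, rng):
        for _ in range(50):
            r2 = rng.uniform(0, 1)
            n = int(rng.integers(8, 60))
            p = int(rng.integers(1, 5))
            assert adjusted_r2(r2, n, p) <= r2 + 1e-12

    def test_equality_iff_perfect(self):
        assert adjusted_r2(1.0, 10, 3) == 1.0


class TestPcoa:
    def test_collinear_points_brute_force(self):
        # points at 0, 1, 3 on a line: exactly one positive eigenvalue
        ord_res = pcoa(distance_frame([[0.0], [1.0], [3.0]]), n_axes=3)
        positive = ord_res.eigenvalues > 1e-9
        assert positive.sum() == 1
        axis = ord_res.scores.iloc[:, 0].to_numpy()
        gaps = np.abs(np.subtract.outer(axis, axis))
        assert sorted(gaps[np.triu_indices(3, 1)]) == pytest.approx([1, 2, 3])

    def test_duplicated_sample_identical_scores(self):
        ord_res = pcoa(
            distance_frame([[0, 0], [1, 1], [1, 1], [3, 0]]), n_axes=2
        )
        assert np.allclose(
            ord_res.scores.iloc[1], ord_res.scores.iloc[2], atol=1e-10
        )

    def test_euclidean_recovery(self, rng):
        points = rng.normal(size=(12, 2))
        ord_res = pcoa(distance_frame(points), n_axes=2)
        assert procrustes_error(ord_res.scores.to_numpy(), points) < 1e-8

    def test_eigenvalues_sorted_scores_centered(self, rng):
        points = rng.normal(size=(10, 4))
        ord_res = pcoa(distance_frame(points), n_axes=3)
        eig = ord_res.eigenvalues
        assert all(eig[i] >= eig[i + 1] - 1e-12 for i in range(len(eig) - 1))
        assert np.allclose(ord_res.scores.mean(axis=0), 0, atol=1e-9)
        assert (ord_res.proportion_explained > 0).all()

    def test_asymmetric_rejected(self):
        bad = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=["a", "b"],
                           columns=["a", "b"])
        with pytest.raises(ValueError):
            pcoa(bad)


class TestFitMlr:
    def test_perfect_fit(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 2)), columns=["x1", "x2"])
        y = 2 * x["x1"] - x["x2"]
        summ = fit_mlr(y, x)
        assert summ.r2 == pytest.approx(1.0)
        assert summ.adj_r2 == pytest.approx(1.0)
        assert summ.model_p < 1e-10

    def test_adjusted_formula_consistency(self, rng):
        x = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("abc"))
        y = x["a"] + rng.normal(size=15)
        summ = fit_mlr(y, x)
        assert summ.adj_r2 == pytest.approx(adjusted_r2(summ.r2, 15, 3))

    def test_standardized_coefficients(self, rng):
        x = pd.DataFrame({"x1": rng.normal(size=50)})
        y = 3 * x["x1"]
        summ = fit_mlr(y, x)
        # slope on the standardized scale is the correlation: exactly 1 here
        assert summ.coefficients[0] == pytest.approx(1.0)

    def test_collinearity_names_columns(self, rng):
        x = pd.DataFrame({"x1": rng.normal(size=20)})
        x["x2"] = 2 * x["x1"]
        with pytest.raises(CollinearityError, match="x"):
            fit_mlr(rng.normal(size=20), x)

    def test_needs_enough_samples(self, rng):
        x = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ValueError, match="n > p"):
            fit_mlr(rng.normal(size=4), x)


class TestCompositionModels:
    def test_identity_slice_reproduces_total(self, small_dataset):
        counts, rate = small_dataset["counts"], small_dataset["rate"]
        every = SubcommunitySet("all", frozenset(counts.columns))
        res = composition_models(rate, counts, {0.1: every})
        total = res[res["community_slice"] == "total"].iloc[0]
        assoc = res[res["community_slice"] == "associated"].iloc[0]
        assert assoc["adj_r2"] == pytest.approx(total["adj_r2"])
        assert assoc["p_model"] == pytest.approx(total["p_model"])

    def test_one_record_per_cutoff_and_slice(self, small_dataset):
        counts, rate = small_dataset["counts"], small_dataset["rate"]
        truth = small_dataset["truth"]
        nit = SubcommunitySet(
            "nitrifier", frozenset(truth.index[truth["role"] == "nitrifier"])
        )
        sets = {
            0.1: SubcommunitySet("a", frozenset(counts.columns[:6])),
            0.5: SubcommunitySet("b", frozenset(counts.columns[:3])),
            0.9: SubcommunitySet("c", frozenset()),
        }
        res = composition_models(rate, counts, sets, nitrifiers=nit)
        assert len(res) == 3 + 2
        assert (res["community_slice"] == "associated").sum() == 3
        empty = res[res["cutoff"] == 0.9].iloc[0]
        assert np.isnan(empty["adj_r2"]) and empty["n_taxa"] == 0


class TestDiversityModels:
    def test_exact_function_of_richness(self, rng):
        counts = pd.DataFrame(
            (rng.uniform(size=(30, 15)) < 0.6) * rng.integers(1, 50, (30, 15))
        )
        alpha = alpha_diversity(counts)
        rate = 2.0 * alpha["richness"] + 5
        res = diversity_models(rate, {"total": alpha})
        assert res["adj_r2"].iloc[0] == pytest.approx(1.0)
        assert res["predictors"].iloc[0] == "richness,shannon,simpson"

    def test_noise_rate_centered_near_zero(self, rng):
        adj = []
        for _ in range(30):
            counts = pd.DataFrame(rng.integers(0, 60, size=(25, 12)))
            alpha = alpha_diversity(counts)
            adj.append(
                diversity_models(
                    rng.normal(size=25), {"total": alpha}
                )["adj_r2"].iloc[0]
            )
        assert abs(np.mean(adj)) < 0.1


class TestLagModels:
    @staticmethod
    def _scores_and_rate(rng, n=40):
        scores = pd.DataFrame(
            rng.normal(size=(n, 3)),
            index=[f"s{i}" for i in range(n)],
            columns=["PCo1", "PCo2", "PCo3"],
        )
        dates = pd.Series(
            pd.date_range("2018-05-01", periods=n, freq="D"),
            index=scores.index,
        )
        return scores, dates

    def test_lag_zero_matches_unlagged(self, rng):
        scores, dates = self._scores_and_rate(rng)
        rate = pd.Series(
            scores["PCo1"] * 2 + rng.normal(scale=0.1, size=len(scores)),
            index=scores.index,
        )
        res = lag_models(rate, scores, dates, lags=(0,))
        direct = fit_mlr(rate, scores)
        assert res["adj_r2"].iloc[0] == pytest.approx(direct.adj_r2)
        assert res["n"].iloc[0] == len(scores)

    def test_n_decreases_by_lag(self, rng):
        scores, dates = self._scores_and_rate(rng)
        rate = pd.Series(rng.normal(size=len(scores)), index=scores.index)
        res = lag_models(rate, scores, dates, lags=(0, 2, 4, 6, 8))
        assert list(res["n"]) == [40, 38, 36, 34, 32]

    def test_planted_lag_recovered(self, rng):
        scores, dates = self._scores_and_rate(rng, n=60)
        shifted = scores["PCo1"].shift(4).fillna(0.0)
        rate = pd.Series(3 * shifted.to_numpy(), index=scores.index)
        res = lag_models(rate, scores, dates, lags=(0, 2, 4, 6, 8))
        assert res.loc[res["adj_r2"].idxmax(), "lag"] == 4


class TestRfImportance:
    def test_dominant_predictor_ranks_first(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        y = 5 * x["a"] + rng.normal(scale=0.3, size=60)
        table = rf_importance(y, x, n_trees=200, seed=0)
        assert table.ranks["a"] == 1
        assert table.oob_r2 > 0.5

    def test_duplicated_predictor_shares_importance(self, rng):
        x = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = 4 * x["a"] + rng.normal(scale=0.3, size=60)
        x2 = x.copy()
        x2["a2"] = x["a"]
        t1 = rf_importance(y, x, n_trees=200, seed=1)
        t2 = rf_importance(y, x2, n_trees=200, seed=1)
        assert t2.importances["a"] > 0 and t2.importances["a2"] > 0
        assert abs(t2.oob_r2 - t1.oob_r2) < 0.15

    def test_null_importances_near_zero(self, rng):
        signs = []
        for seed in range(6):
            x = pd.DataFrame(rng.normal(size=(40, 4)))
            y = rng.normal(size=40)
            table = rf_importance(y, x, n_trees=100, seed=seed)
            signs.extend(np.sign(table.importances))
        # permutation increases hover around zero under the null
        assert 0.1 < np.mean(np.array(signs) > 0) < 0.9

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            rf_importance(
                rng.normal(size=5), pd.DataFrame(rng.normal(size=(5, 2)))
            )


class TestDbrda:
    def test_self_explanation(self, rng):
        points = rng.normal(size=(20, 3))
        dist = distance_frame(points)
        env = pd.DataFrame(points, index=dist.index, columns=list("abc"))
        fraction, _, _ = dbrda(dist, env)
        assert fraction == pytest.approx(1.0, abs=1e-8)

    def test_exact_linear_construction(self, rng):
        env = pd.DataFrame(
            rng.normal(size=(25, 3)), columns=list("abc"),
            index=[f"s{i}" for i in range(25)],
        )
        coords = env.to_numpy() @ rng.normal(size=(3, 4))
        fraction, scores, eig = dbrda(distance_frame(coords, list(env.index)), env)
        assert fraction == pytest.approx(1.0, abs=1e-8)
        assert len(eig) <= 3

    def test_null_env_small_fraction(self, rng):
        points = rng.normal(size=(60, 5))
        dist = distance_frame(points)
        env = pd.DataFrame(
            rng.normal(size=(60, 1)), index=dist.index, columns=["noise"]
        )
        fraction, _, _ = dbrda(dist, env)
        assert fraction < 0.1

    def test_collinear_env_rejected(self, rng):
        points = rng.normal(size=(15, 2))
        dist = distance_frame(points)
        env = pd.DataFrame(
            {"a": rng.normal(size=15)}, index=dist.index
        )
        env["b"] = 2 * env["a"]
        with pytest.raises(CollinearityError, match="b|a"):
            dbrda(dist, env)


class TestAicSelect:
    def test_planted_variable_selected_first(self, rng):
        driver = rng.normal(size=(30, 1))
        coords = np.hstack([driver * 3, driver * -2]) + rng.normal(
            scale=0.1, size=(30, 2)
        )
        dist = distance_frame(coords)
        env = pd.DataFrame(
            {
                "signal": driver[:, 0],
                "noise1": rng.normal(size=30),
                "noise2": rng.normal(size=30),
            },
            index=dist.index,
        )
        selected = aic_select(dist, env)
        assert selected[0] == "signal"

    def test_all_noise_selects_few(self, rng):
        points = rng.normal(size=(40, 4))
        dist = distance_frame(points)
        env = pd.DataFrame(
            rng.normal(size=(40, 5)), index=dist.index,
            columns=[f"n{i}" for i in range(5)],
        )
        selected = aic_select(dist, env)
        assert len(selected) <= 5

    def test_deterministic(self, rng):
        points = rng.normal(size=(25, 3))
        dist = distance_frame(points)
        env = pd.DataFrame(
            rng.normal(size=(25, 4)), index=dist.index, columns=list("abcd")
        )
        assert aic_select(dist, env) == aic_select(dist, env)


class TestHierarchicalPartition:
    def test_single_variable_equals_marginal(self, rng):
        points = rng.normal(size=(20, 3))
        dist = distance_frame(points)
        env = pd.DataFrame({"a": rng.normal(size=20)}, index=dist.index)
        part = hierarchical_partition(dist, env)
        fraction, _, _ = dbrda(dist, env)
        assert part.individual["a"] == pytest.approx(fraction)
        assert part.total_constrained == pytest.approx(fraction)

    def test_orthogonal_predictors_exact(self):
        # build coordinates where orthonormal x1, x2 explain 30% and 20%;
        # all basis vectors orthogonal to 1 so centering leaves them intact
        n = 16
        raw = np.c_[np.ones(n), np.random.default_rng(5).normal(size=(n, 4))]
        basis = np.linalg.qr(raw)[0][:, 1:]
        x1, x2, r1, r2 = basis.T
        coords = (
            np.sqrt(0.3) * np.outer(x1, [1, 0])
            + np.sqrt(0.2) * np.outer(x2, [0, 1])
            + np.sqrt(0.25) * np.outer(r1, [1, 0])
            + np.sqrt(0.25) * np.outer(r2, [0, 1])
        )
        coords -= coords.mean(axis=0)
        dist = distance_frame(coords)
        ids = dist.index
        env = pd.DataFrame({"x1": x1, "x2": x2}, index=ids)
        part = hierarchical_partition(dist, env)
        assert part.individual["x1"] == pytest.approx(0.3, abs=1e-8)
        assert part.individual["x2"] == pytest.approx(0.2, abs=1e-8)
        assert part.individual.sum() == pytest.approx(
            part.total_constrained, abs=1e-8
        )

    def test_sum_identity_random(self, rng):
        for _ in range(10):
            points = rng.normal(size=(18, 3))
            dist = distance_frame(points)
            env = pd.DataFrame(
                rng.normal(size=(18, 4)), index=dist.index,
                columns=list("abcd"),
            )
            part = hierarchical_partition(dist, env)
            assert part.individual.sum() == pytest.approx(
                part.total_constrained, abs=1e-8
            )

    def test_too_many_variables(self, rng):
        points = rng.normal(size=(20, 2))
        dist = distance_frame(points)
        env = pd.DataFrame(
            rng.normal(size=(20, 16)), index=dist.index,
            columns=[f"v{i}" for i in range(16)],
        )
        with pytest.raises(ValueError, match="15"):
            hierarchical_partition(dist, env)


def test_composition_model_end_to_end(small_dataset):
    summ = composition_model(
        small_dataset["rate"], small_dataset["counts"], n_axes=3
    )
    assert summ.n == len(small_dataset["counts"])
    assert len(summ.predictors) == 3
    assert summ.adj_r2 <= summ.r2
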