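"""Meta-ensemble fitting: simplex weights, exclusion sweep, combiners."""

import math

import numpy as np
import pandas as pd
import pytest

import couplingswarm as cs
from couplingswarm.ensemble import (
    EnsembleFit,
    _optimize_simplex,
    _prediction_matrix,
    _type_sorted,
    combine,
    contributor_count,
    fit_weights,
    grid_search_simplex,
    k_sweep,
    split_fit_eval,
)
from couplingswarm.errors import ConfigurationError, IncompleteSubmissionError
from couplingswarm.scoring import MAE_FLOOR, score_errors

from conftest import make_dataset, submission_from_errors

FLAT_CURVE = (0.0, 0.0, 50.0, 1.29, -3.59)


def population(seed=0, n_teams=6, n_molecules=200, rho=0.5, **kwargs):
    cfg = cs.PopulationConfig(
        n_molecules=n_molecules, couplings_per_molecule=10, n_teams=n_teams,
        n_clusters=kwargs.pop("n_clusters", 2), within_cluster_correlation=rho,
        submissions_per_team=1, improvement_curve=FLAT_CURVE, seed=seed,
        **kwargs)
    ds = cs.generate_dataset(cfg)
    return ds, cs.generate_submissions(ds, cfg)


class TestCombine:
    def test_degenerate_weight_vector(self, two_type_dataset):
        a = submission_from_errors(two_type_dataset, 1.0, team_id="a")
        b = submission_from_errors(two_type_dataset, -2.0, team_id="b")
        out = combine([a, b], weights=[1.0, 0.0])
        np.testing.assert_allclose(out.predictions.to_numpy(),
                                   a.predictions.to_numpy())

    def test_equal_weights_average(self, two_type_dataset):
        a = submission_from_errors(two_type_dataset, -1.0)
        b = submission_from_errors(two_type_dataset, 1.0)
        out = combine([a, b], weights=[0.5, 0.5])
        np.testing.assert_allclose(out.predictions.to_numpy(),
                                   two_type_dataset.truth("test").to_numpy())

    def test_median_order_statistic(self, two_type_dataset):
        subs = [submission_from_errors(two_type_dataset, e)
                for e in (1.0, 100.0, 2.0)]
        out = combine(subs, combiner="median")
        expected = two_type_dataset.truth("test").to_numpy() + 2.0
        np.testing.assert_allclose(out.predictions.to_numpy(), expected)

    def test_median_even_count_lower_middle(self, two_type_dataset):
        subs = [submission_from_errors(two_type_dataset, e)
                for e in (1.0, 2.0, 3.0, 4.0)]
        out = combine(subs, combiner="median")
        expected = two_type_dataset.truth("test").to_numpy() + 2.0
        np.testing.assert_allclose(out.predictions.to_numpy(), expected)

    def test_per_type_weights(self, two_type_dataset):
        a = submission_from_errors(two_type_dataset, 1.0)
        b = submission_from_errors(two_type_dataset, 3.0)
        weights = {"1JHC": [1.0, 0.0], "3JHH": [0.0, 1.0]}
        out = combine([a, b], weights=weights,
                      types=two_type_dataset.types("test"))
        resid = out.predictions.to_numpy() - two_type_dataset.truth("test").to_numpy()
        types = two_type_dataset.types("test").to_numpy()
        assert np.allclose(resid[types == "1JHC"], 1.0)
        assert np.allclose(resid[types == "3JHH"], 3.0)

    def test_coverage_mismatch_rejected(self, two_type_dataset):
        a = submission_from_errors(two_type_dataset, 1.0)
        b = submission_from_errors(two_type_dataset, 2.0)
        b.predictions = b.predictions.drop(b.predictions.index[0])
        with pytest.raises(IncompleteSubmissionError):
            combine([a, b], weights=[0.5, 0.5])


class TestFitWeights:
    def test_single_constituent_identity(self):
        ds, subs = population(seed=1, n_teams=3)
        fit = fit_weights(subs, ds, k=3, seed=0)
        assert list(fit.weights.values()) == [1.0]
        assert fit.constituent_ranks == [3]

    def test_perfect_constituent_dominates(self):
        ds, subs = population(seed=2, n_teams=3)
        perfect = cs.SubmissionSet(
            team_id="oracle", predictions=ds.truth("test").copy())
        fit = fit_weights(list(subs) + [perfect], ds, k=1, seed=0)
        rank_of_perfect = [r for r, t in fit.team_ids.items() if t == "oracle"][0]
        assert fit.weights[rank_of_perfect] == pytest.approx(1.0, abs=1e-9)
        assert fit.fit_score == pytest.approx(math.log(MAE_FLOOR))

    def test_simplex_feasibility(self):
        ds, subs = population(seed=3, n_teams=8)
        fit = fit_weights(subs, ds, k=1, seed=0)
        w = np.array(list(fit.weights.values()))
        assert (w >= -1e-12).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_vertex_dominance(self, seed):
        """Fit-half ME score never exceeds any constituent's fit-half score."""
        ds, subs = population(seed=seed, n_teams=6)
        fit = fit_weights(subs, ds, k=1, seed=seed)
        y = ds.truth("test").reindex(fit.fit_record_ids).to_numpy()
        t = ds.types("test").reindex(fit.fit_record_ids).to_numpy()
        for sub in subs:
            p = _prediction_matrix([sub], fit.fit_record_ids)[:, 0]
            individual = score_errors(np.abs(p - y), t).score
            assert fit.fit_score <= individual + 1e-12

    def test_per_type_no_worse_than_global(self):
        """The per-type feasible set contains the global solution."""
        ds, subs = population(seed=4, n_teams=5)
        g = fit_weights(subs, ds, k=1, mode="global", seed=0)
        p = fit_weights(subs, ds, k=1, mode="per_type", seed=0)
        assert p.fit_score <= g.fit_score + 1e-9

    def test_external_rank_order_respected(self):
        ds, subs = population(seed=5, n_teams=4)
        order = [3, 2, 1, 0]
        fit = fit_weights(subs, ds, k=1, seed=0, rank_order=order)
        assert fit.team_ids[1] == subs[3].team_id
        assert fit.team_ids[4] == subs[0].team_id

    def test_empty_ensemble_rejected(self):
        ds, subs = population(seed=6, n_teams=3)
        with pytest.raises(ConfigurationError):
            fit_weights(subs, ds, k=4, seed=0)

    def test_overlapping_halves_rejected(self):
        ds, subs = population(seed=7, n_teams=3)
        ids = ds.record_ids("test")
        with pytest.raises(ConfigurationError):
            fit_weights(subs, ds, k=1, fit_ids=ids[:10], eval_ids=ids[5:20])

    def test_stratified_halves_cover_types(self):
        ds, subs = population(seed=8)
        fit_ids, eval_ids = split_fit_eval(ds, seed=3)
        types = ds.types("test")
        assert set(types.reindex(fit_ids)) == set(types.reindex(eval_ids))
        assert np.intersect1d(fit_ids, eval_ids).size == 0
        assert len(fit_ids) + len(eval_ids) == len(ds.record_ids("test"))


class TestGridOracle:
    def test_optimizer_matches_grid_three_constituents(self):
        """SLSQP multi-start finds a solution at least as good as the
        exhaustive 0.001-step simplex lattice (to 1e-6 in score)."""
        rng = np.random.default_rng(3)
        n = 60
        y = rng.normal(0, 5, n)
        types = np.array(["1JHC"] * 30 + ["3JHH"] * 30)
        P = y[:, None] + rng.normal(0, [[1.0, 1.5, 2.0]], (n, 3))
        _, grid_score = grid_search_simplex(P, y, types, step=0.001)
        Ps, ys, slices = _type_sorted(P, y, types)
        _, opt_score = _optimize_simplex(Ps, ys, slices)
        assert opt_score <= grid_score + 1e-6

    def test_grid_finds_planted_vertex(self):
        # one constituent is exactly the truth: grid must give it weight 1
        y = np.linspace(-5, 5, 20)
        types = np.array(["1JHC"] * 10 + ["3JHH"] * 10)
        P = np.column_stack([y, y + 2.0, y + 3.0])
        w, s = grid_search_simplex(P, y, types, step=0.05)
        np.testing.assert_allclose(w, [1.0, 0.0, 0.0])
        assert s == pytest.approx(math.log(MAE_FLOOR))


class TestContributorCount:
    def _fit_with_weights(self, weights):
        ranks = list(range(1, len(weights) + 1))
        return EnsembleFit(
            constituent_ranks=ranks,
            team_ids={r: f"t{r}" for r in ranks},
            weights=dict(zip(ranks, weights)), k=1, mode="global",
            combiner="mean", fit_record_ids=np.array([]),
            eval_record_ids=np.array([]), fit_score=0.0, eval_score=0.0)

    def test_single_full_weight(self):
        assert contributor_count(self._fit_with_weights([1.0])) == 1

    def test_threshold_is_strict(self):
        fit = self._fit_with_weights([0.5, 0.3, 0.15, 0.04, 0.009, 0.001])
        assert contributor_count(fit, 0.01) == 4

    def test_default_threshold(self):
        fit = self._fit_with_weights([0.99, 0.01])
        assert fit.contributor_count_at() == 1  # 0.01 is not > 0.01


class TestKSweep:
    def test_last_k_single_model_zero_gap(self):
        ds, subs = population(seed=9, n_teams=4)
        result = k_sweep(subs, ds, [4], seed=0)
        row = result.table.iloc[0]
        assert row["gap"] == pytest.approx(0.0, abs=1e-12)

    def test_best_individual_non_decreasing(self):
        ds, subs = population(seed=10, n_teams=6)
        result = k_sweep(subs, ds, range(1, 7), seed=0)
        best = result.table["best_score"].to_numpy()
        assert np.all(np.diff(best) >= -1e-12)

    def test_failures_recorded_without_abort(self):
        ds, subs = population(seed=11, n_teams=3)
        result = k_sweep(subs, ds, [1, 2, 3, 4], seed=0)
        assert 4 in result.failures
        assert list(result.table["k"]) == [1, 2, 3]

    def test_redundant_top_widens_mid_k_gap(self):
        """Three mutually correlated leaders over a field of many
        independent similar mid-skill models: excluding the leaders leaves
        diversity the ME can exploit, so the gap at mid k exceeds the gap
        at k=1."""
        cfg = cs.PopulationConfig(
            n_molecules=300, couplings_per_molecule=10, n_teams=10,
            n_clusters=8,
            cluster_assignment={0: 0, 1: 0, 2: 0, 3: 1, 4: 2, 5: 3,
                                6: 4, 7: 5, 8: 6, 9: 7},
            within_cluster_correlation=0.9,
            team_skill={0: 0.2, 1: 0.22, 2: 0.25, 3: 1.0, 4: 1.0, 5: 1.0,
                        6: 1.0, 7: 1.0, 8: 1.0, 9: 1.0},
            submissions_per_team=1, improvement_curve=FLAT_CURVE, seed=12)
        ds = cs.generate_dataset(cfg)
        subs = cs.generate_submissions(ds, cfg)
        result = k_sweep(subs, ds, [1, 4], seed=0)
        gaps = dict(zip(result.table["k"], result.table["gap"]))
        assert gaps[4] > gaps[1]


class TestIndependentPoolScaling:
    def test_sqrt_m_error_reduction(self):
        """An ME of m independent equal-skill models shrinks the
        geometric-mean error ~ sqrt(m)-fold relative to one model."""
        m = 16
        cfg = cs.PopulationConfig(
            n_molecules=7200, couplings_per_molecule=20, n_teams=m,
            n_clusters=m, within_cluster_correlation=0.0,
            team_skill={j: 1.0 for j in range(m)},
            submissions_per_team=1, improvement_curve=FLAT_CURVE, seed=13)
        ds = cs.generate_dataset(cfg)
        assert len(ds.record_ids("test")) >= 50_000
        subs = cs.generate_submissions(ds, cfg)
        fit = fit_weights(subs, ds, k=1, seed=0)
        y = ds.truth("test").reindex(fit.eval_record_ids).to_numpy()
        t = ds.types("test").reindex(fit.eval_record_ids).to_numpy()
        individual = np.mean([
            score_errors(
                np.abs(_prediction_matrix([s], fit.eval_record_ids)[:, 0] - y),
                t).score
            for s in subs])
        ratio = math.exp(individual - fit.eval_score)
        assert ratio == pytest.approx(math.sqrt(m), rel=0.10)
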