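"""GSEA: signal-to-noise ranking, running-sum walk, permutation p,
consensus risk-pathway rule."""

import numpy as np
import pandas as pd
import pytest

import riskmir as rm
from riskmir import gsea


def ranked_series(ids, metrics):
    order = np.lexsort((np.asarray(ids, dtype=object), -np.asarray(metrics, dtype=float)))
    return pd.Series(np.asarray(metrics, dtype=float)[order], index=np.asarray(ids, dtype=object)[order])


class TestRanking:
    def test_hand_signal_to_noise_value(self, study_factory):
        # case mean 2, sd 0.5; control mean 1, sd 0.5 -> (2-1)/(0.5+0.5) = 1
        s = study_factory([[1.5, 2.0, 2.5]], [[0.5, 1.0, 1.5]])
        assert gsea.signal_to_noise(s).iloc[0] == pytest.approx(1.0)

    def test_sigma_floor_applies(self, study_factory):
        # tiny spread: sigma floored at max(0.2*|mu|, 0.2)
        s = study_factory([[5.0, 5.0, 5.000001]], [[1.0, 1.0, 1.000001]])
        metric = gsea.signal_to_noise(s).iloc[0]
        assert metric == pytest.approx(4.0 / (0.2 * 5 + 0.2))

    def test_ties_break_by_feature_id(self, study_factory):
        case = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9, 9.5, 10]])
        ctrl = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [0, 0.5, 1]])
        s = study_factory(case, ctrl, feature_ids=["zeta", "alpha", "big"])
        ranked = gsea.rank_by_signal_to_noise(s)
        tied = [i for i in ranked.index if i in ("zeta", "alpha")]
        assert tied == ["alpha", "zeta"]

    def test_small_group_is_design_error(self, study_factory):
        s = study_factory([[1.0, 2.0]], [[1.0, 2.0, 3.0]])
        with pytest.raises(rm.DesignError):
            gsea.rank_by_signal_to_noise(s)


class TestEnrichmentScore:
    def test_top_block_with_equal_metrics_scores_one(self):
        ranked = ranked_series([f"g{i}" for i in range(1, 11)], [2, 2] + [1] * 8)
        es, walk, lead = gsea.enrichment_score(ranked, {"g1", "g2"})
        assert es == pytest.approx(1.0)
        assert lead == {"g1", "g2"}

    def test_bottom_block_scores_minus_one(self):
        ranked = ranked_series([f"g{i}" for i in range(1, 11)], [1] * 8 + [0.5, 0.5])
        es, _, lead = gsea.enrichment_score(ranked, {"g9", "g10"})
        assert es == pytest.approx(-1.0)
        assert lead == {"g9", "g10"}

    def test_weight_zero_walk_matches_hand_values(self):
        ranked = ranked_series(["g1", "g2", "g3", "g4"], [4, 3, 2, 1])
        es, walk, _ = gsea.enrichment_score(ranked, {"g1", "g3"}, weight_exponent=0.0)
        assert np.allclose(walk, [0.5, 0.0, 0.5, 0.0])
        assert es == pytest.approx(0.5)

    def test_walk_terminates_at_zero_and_es_bounded(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 60)
            ids = [f"g{i}" for i in range(n)]
            metrics = rng.normal(0, 1, n)
            members = rng.choice(ids, size=rng.integers(1, n), replace=False)
            es, walk, _ = gsea.enrichment_score(ranked_series(ids, metrics), set(members),
                                                weight_exponent=float(rng.choice([0, 1, 2])))
            assert abs(walk[-1]) < 1e-9
            assert -1 - 1e-12 <= es <= 1 + 1e-12

    def test_reversing_list_negates_weight_zero_es(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(12)]
        metrics = np.sort(rng.normal(0, 1, 12))[::-1]
        members = {"g2", "g5", "g7"}
        es_f, _, _ = gsea.enrichment_score(pd.Series(metrics, index=ids), members, 0.0)
        es_r, _, _ = gsea.enrichment_score(pd.Series(metrics[::-1], index=ids[::-1]), members, 0.0)
        assert es_f == pytest.approx(-es_r, abs=1e-12)

    def test_disjoint_set_is_error(self):
        ranked = ranked_series(["g1", "g2"], [1, 0])
        with pytest.raises(rm.ConfigError):
            gsea.enrichment_score(ranked, {"x"})


class TestPermutationP:
    def _study(self, study_factory, shift, seed=0, n_feat=60, members=10):
        rng = np.random.default_rng(seed)
        case = rng.normal(0, 0.5, (n_feat, 6))
        ctrl = rng.normal(0, 0.5, (n_feat, 6))
        case[:members] += shift
        return study_factory(case, ctrl)

    def test_fixed_seed_is_deterministic(self, study_factory):
        s = self._study(study_factory, shift=0.4)
        pathway = [f"f{i + 1}" for i in range(10)]
        p1 = gsea.gsea_permutation_p(s, pathway, n_perm=50, seed=9)
        p2 = gsea.gsea_permutation_p(s, pathway, n_perm=50, seed=9)
        assert p1 == p2

    def test_planted_shift_is_significant(self, study_factory):
        s = self._study(study_factory, shift=2.0)
        p = gsea.gsea_permutation_p(s, [f"f{i + 1}" for i in range(10)], n_perm=100, seed=1)
        assert p < 0.05

    def test_p_respects_support_bounds(self, study_factory):
        s = self._study(study_factory, shift=0.0, seed=4)
        p = gsea.gsea_permutation_p(s, [f"f{i + 1}" for i in range(10)], n_perm=20, seed=2)
        assert 1 / 21 <= p <= 1


class TestRiskPathwayRule:
    def _results(self, ps_by_ds):
        return {
            ds: [gsea.GseaResult(ds, name, 0.5, np.zeros(1), p, frozenset(), 100)
                 for name, p in ps.items()]
            for ds, ps in ps_by_ds.items()
        }

    def test_half_of_datasets_is_not_risk(self):
        table = gsea.select_sig_pathways(self._results({"d1": {"P": 0.05}, "d2": {"P": 0.2}}))
        assert not bool(table.loc["P", "risk"])

    def test_two_thirds_is_risk(self):
        table = gsea.select_sig_pathways(
            self._results({"d1": {"P": 0.05}, "d2": {"P": 0.05}, "d3": {"P": 0.2}})
        )
        assert bool(table.loc["P", "risk"])

    def test_single_dataset_below_threshold_is_risk(self):
        table = gsea.select_sig_pathways(self._results({"d1": {"P": 0.09}}))
        assert bool(table.loc["P", "risk"])

    def test_missing_pathway_counts_as_not_significant(self):
        table = gsea.select_sig_pathways(
            self._results({"d1": {"P": 0.01}, "d2": {}})
        )
        assert table.loc["P", "n_sig"] == 1 and not bool(table.loc["P", "risk"])
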