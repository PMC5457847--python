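"""Differential expression: Welch/moderated statistics, Fisher combination,
DE calling rules."""

import numpy as np
import pytest
from scipy import stats

import riskmir as rm
from riskmir import de


class TestWelch:
    def test_identical_groups_give_null_record(self, study_factory):
        s = study_factory([[1, 2, 3]], [[1, 2, 3]])
        rec = de.welch_t_table(s).iloc[0]
        assert rec["t"] == 0 and rec["p"] == 1 and rec["log2fc"] == 0
        assert rec["direction"] == "flat"

    def test_zero_variance_unequal_means_is_degenerate(self, study_factory):
        s = study_factory([[0, 0, 0]], [[1, 1, 1]])
        rec = de.welch_t_table(s).iloc[0]
        assert rec["degenerate"]
        assert rec["direction"] == "down"
        assert rec["p"] == np.finfo(float).tiny

    def test_matches_hand_computed_welch_formula(self, study_factory):
        case = np.array([2.1, 1.9, 2.0, 2.2])
        ctrl = np.array([1.0, 0.9, 1.1, 1.0])
        s = study_factory([case], [ctrl])
        rec = de.welch_t_table(s).iloc[0]
        # independent hand computation of the Welch statistic and df
        v1, v2 = case.var(ddof=1), ctrl.var(ddof=1)
        se2 = v1 / 4 + v2 / 4
        t_hand = (case.mean() - ctrl.mean()) / np.sqrt(se2)
        df_hand = se2**2 / ((v1 / 4) ** 2 / 3 + (v2 / 4) ** 2 / 3)
        assert rec["t"] == pytest.approx(t_hand, abs=1e-10)
        assert rec["df"] == pytest.approx(df_hand, abs=1e-10)
        assert rec["p"] == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), abs=1e-12)

    def test_shift_invariance_and_label_swap_antisymmetry(self, study_factory):
        rng = np.random.default_rng(5)
        case, ctrl = rng.normal(0, 1, (6, 5)), rng.normal(0.5, 1, (6, 4))
        base = de.welch_t_table(study_factory(case, ctrl))
        shifted = de.welch_t_table(study_factory(case + 7.3, ctrl + 7.3))
        swapped = de.welch_t_table(study_factory(ctrl, case))
        assert np.allclose(base["t"], shifted["t"])
        assert np.allclose(base["p"], shifted["p"])
        assert np.allclose(base["log2fc"], -swapped["log2fc"])


class TestModerated:
    def test_equal_variances_collapse_to_pooled_t(self, study_factory):
        # every feature shares the same sample variance: complete shrinkage
        # with s0^2 = s^2, so the moderated t equals the pooled-variance t
        base_case = np.array([0.0, 1.0, 2.0])
        base_ctrl = np.array([1.0, 2.0, 3.0])
        case = np.vstack([base_case + i for i in range(12)])
        ctrl = np.vstack([base_ctrl + 2 * i for i in range(12)])
        s = study_factory(case, ctrl)
        table = de.moderated_t_table(s)
        assert np.isinf(table.attrs["d0"])
        v_pooled = (2 * base_case.var(ddof=1) + 2 * base_ctrl.var(ddof=1)) / 4
        assert table.attrs["s0_sq"] == pytest.approx(v_pooled, rel=1e-10)
        diff = case.mean(axis=1) - ctrl.mean(axis=1)
        t_pooled = diff / np.sqrt(v_pooled * (1 / 3 + 1 / 3))
        assert np.allclose(table["t"], t_pooled)

    def test_forced_infinite_prior_df_gives_complete_shrinkage(self, study_factory):
        rng = np.random.default_rng(0)
        s = study_factory(rng.normal(0, 1, (20, 4)), rng.normal(0, 2, (20, 4)))
        table = de.moderated_t_table(s, d0=np.inf, s0_sq=1.7)
        se_expected = np.sqrt(1.7 * (1 / 4 + 1 / 4))
        assert np.allclose(table["se"], se_expected)

    def test_few_features_fall_back_to_welch(self, study_factory):
        rng = np.random.default_rng(1)
        s = study_factory(rng.normal(0, 1, (4, 4)), rng.normal(0, 1, (4, 4)))
        assert np.allclose(de.moderated_t_table(s)["t"], de.welch_t_table(s)["t"])

    def test_null_p_values_are_uniform(self, study_factory):
        rng = np.random.default_rng(7)
        s = study_factory(rng.normal(5, 1, (500, 8)), rng.normal(5, 1, (500, 8)))
        p = de.moderated_t_table(s)["p"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestFisherCombine:
    def _table(self, p, fc=1.0, se=0.5):
        import pandas as pd
        return pd.DataFrame(
            {"log2fc": [fc], "t": [1.0], "df": [4.0], "p": [p], "p_adj": [p],
             "se": [se], "direction": ["up" if fc > 0 else "down"], "degenerate": [False]},
            index=pd.Index(["g"], name="feature"),
        )

    def test_unit_p_values_combine_to_one(self):
        out = de.fisher_combine([self._table(1.0), self._table(1.0)])
        assert out["x2"].iloc[0] == 0
        assert out["p"].iloc[0] == 1

    def test_half_half_matches_chi_square_closed_form(self):
        out = de.fisher_combine([self._table(0.5), self._table(0.5)])
        x2 = -2 * (np.log(0.5) + np.log(0.5))
        assert out["x2"].iloc[0] == pytest.approx(2.7726, abs=1e-4)
        # df=4 closed form: exp(-x/2) * (1 + x/2)
        assert out["p"].iloc[0] == pytest.approx(np.exp(-x2 / 2) * (1 + x2 / 2), abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(0.5966, abs=1e-4)

    def test_single_study_is_identity_on_p(self):
        out = de.fisher_combine([self._table(0.1234)])
        assert out["p"].iloc[0] == pytest.approx(0.1234, rel=1e-12)

    def test_monotone_in_each_input_p(self):
        base = de.fisher_combine([self._table(0.3), self._table(0.4)])["p"].iloc[0]
        lower = de.fisher_combine([self._table(0.2), self._table(0.4)])["p"].iloc[0]
        assert lower < base

    def test_discordant_directions_flagged(self):
        out = de.fisher_combine([self._table(0.5, fc=1.0), self._table(0.5, fc=-1.0)])
        assert bool(out["discordant"].iloc[0])

    def test_nonpositive_p_is_domain_error(self):
        bad = self._table(0.5)
        bad["p"] = 0.0
        with pytest.raises(rm.ConfigError):
            de.fisher_combine([bad, self._table(0.5)])


class TestCallDe:
    def _table(self, rows):
        import pandas as pd
        return pd.DataFrame(rows, columns=["p", "log2fc"]).assign(direction="up")

    def test_human_rule_is_strict(self):
        t = self._table([(0.049, 0.1), (0.05, 5.0)])
        out = de.call_de(t, p_threshold=0.05)
        assert list(out.index) == [0]

    def test_rat_rule_is_inclusive_on_both_thresholds(self):
        t = self._table([(0.05, 1.0), (0.05, 0.99), (0.051, 3.0)])
        out = de.call_de(t, p_threshold=0.05, fc_threshold=2.0)
        assert list(out.index) == [0]

    def test_empty_table_selects_nothing(self):
        t = self._table([])
        assert len(de.call_de(t)) == 0
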