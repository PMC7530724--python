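"""Fold changes, set-vs-background t statistics, Stouffer and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from xgage.enrich import (
    Contrast,
    bh_fdr,
    pairwise_fold_changes,
    run_gage,
    set_t_statistic,
    stouffer_combine,
)
from xgage.errors import DesignError, InvalidInputError


def _design(treatments=("C", "E"), n_rep=3, paired=False):
    samples = [f"{t}{r + 1}" for t in treatments for r in range(n_rep)]
    return pd.DataFrame(
        {
            "treatment": [t for t in treatments for _ in range(n_rep)],
            "pair": [str(r + 1) if paired else "" for _ in treatments for r in range(n_rep)],
        },
        index=samples,
    )


class TestPairwiseFoldChanges:
    def test_identical_samples_give_zero_column(self):
        design = _design(n_rep=1)
        m = pd.DataFrame({"C1": [1.0, 2.0], "E1": [1.0, 2.0]}, index=["g1", "g2"])
        fcm = pairwise_fold_changes(m, Contrast.from_name("E_vs_C"), design)
        np.testing.assert_array_equal(fcm.values.to_numpy(), 0.0)

    def test_unpaired_enumerates_cartesian_pairs(self):
        design = pd.DataFrame(
            {"treatment": ["E", "E", "C", "C", "C"]},
            index=["E1", "E2", "C1", "C2", "C3"],
        )
        m = pd.DataFrame(
            np.arange(10.0).reshape(2, 5), index=["g1", "g2"], columns=design.index
        )
        fcm = pairwise_fold_changes(m, Contrast.from_name("E_vs_C"), design)
        assert fcm.n_columns == 6
        assert fcm.pairs == [(t, r) for t in ["E1", "E2"] for r in ["C1", "C2", "C3"]]

    def test_paired_blocks_hand_computed(self):
        design = _design(n_rep=3, paired=True)
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.normal(size=(4, 6)), index=[f"g{i}" for i in range(4)],
            columns=design.index,
        )
        fcm = pairwise_fold_changes(m, Contrast.from_name("E_vs_C", paired=True), design)
        assert fcm.n_columns == 3
        for lab in ("1", "2", "3"):
            np.testing.assert_allclose(
                fcm.values[f"pair:{lab}"].to_numpy(),
                m[f"E{lab}"].to_numpy() - m[f"C{lab}"].to_numpy(),
            )

    def test_missing_pair_mate_is_design_error(self):
        design = _design(n_rep=2, paired=True)
        design.loc["E2", "pair"] = "9"
        m = pd.DataFrame(np.ones((2, 4)), index=["g1", "g2"], columns=design.index)
        with pytest.raises(DesignError):
            pairwise_fold_changes(m, Contrast.from_name("E_vs_C", paired=True), design)

    def test_null_z_variance_counts_shared_samples(self):
        design = _design(n_rep=3)
        m = pd.DataFrame(
            np.random.default_rng(0).normal(size=(5, 6)),
            index=[f"g{i}" for i in range(5)], columns=design.index,
        )
        fcm = pairwise_fold_changes(m, Contrast.from_name("E_vs_C"), design)
        # 9 columns; 18 ordered pairs sharing exactly one sample (rho=1/2)
        assert fcm.null_z_variance() == pytest.approx(9 + 2 * 18 * 0.5)
        fcm_paired = pairwise_fold_changes(
            m, Contrast.from_name("E_vs_C", paired=True),
            _design(n_rep=3, paired=True),
        )
        assert fcm_paired.null_z_variance() == pytest.approx(3.0)


class TestSetTStatistic:
    def test_set_equal_to_background_is_null(self):
        fc = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        t, p_up, p_down = set_t_statistic(fc, {"a", "b"})
        assert t == 0.0 and p_up == pytest.approx(0.5) and p_down == pytest.approx(0.5)

    def test_matches_welch_formula_on_ten_numbers(self):
        # set fc {2,2,2}; background = all ten values {0 x7, 2 x3}
        fc = pd.Series([2.0, 2.0, 2.0] + [0.0] * 7,
                       index=[f"g{i}" for i in range(10)])
        set_genes = {"g0", "g1", "g2"}
        t, p_up, p_down = set_t_statistic(fc, set_genes)
        m_s, v_s, n_s = 2.0, 0.0, 3
        m_b, v_b, n_b = fc.mean(), fc.var(ddof=1), 10
        se2 = v_s / n_s + v_b / n_b
        t_exp = (m_s - m_b) / np.sqrt(se2)
        df_exp = se2**2 / ((v_s / n_s) ** 2 / 2 + (v_b / n_b) ** 2 / 9)
        assert t == pytest.approx(t_exp)
        assert p_up == pytest.approx(stats.t.sf(t_exp, df_exp))
        assert p_down == pytest.approx(stats.t.cdf(t_exp, df_exp))

    def test_agrees_with_scipy_welch_in_complement_mode(self):
        # independent route: scipy Welch t of set vs complement
        from xgage.enrich import _membership, _one_sided_p, _welch_vs_background

        rng = np.random.default_rng(7)
        fc = rng.normal(size=(40, 1))
        genes = pd.Index([f"g{i}" for i in range(40)])
        sets = {"s": frozenset(genes[:12])}
        terms, member = _membership(genes, sets)
        t, df, _ = _welch_vs_background(fc, member, set_vs_complement=True)
        ref = stats.ttest_ind(fc[:12, 0], fc[12:, 0], equal_var=False)
        assert t[0, 0] == pytest.approx(ref.statistic)
        p_up, _ = _one_sided_p(t, df)
        assert p_up[0, 0] == pytest.approx(
            stats.ttest_ind(fc[:12, 0], fc[12:, 0], equal_var=False,
                            alternative="greater").pvalue
        )

    def test_null_p_values_approximately_uniform(self):
        # set small relative to the background: the set-vs-all overlap is
        # then negligible and the one-sided p is calibrated
        rng = np.random.default_rng(8)
        p_ups = []
        genes = pd.Index([f"g{i}" for i in range(400)])
        for _ in range(1000):
            fc = pd.Series(rng.normal(size=400), index=genes)
            _, p_up, _ = set_t_statistic(fc, set(genes[:10]))
            p_ups.append(p_up)
        assert stats.kstest(p_ups, "uniform").pvalue > 0.01


class TestStouffer:
    def test_single_p_identity(self):
        assert stouffer_combine([0.037]) == pytest.approx(0.037, abs=1e-12)

    def test_two_fives_hand_value(self):
        # z = 2 * 1.6449 / sqrt(2) = 2.3262 -> p = 0.0100
        assert stouffer_combine([0.05, 0.05]) == pytest.approx(0.0100, abs=5e-5)

    def test_neutral_inputs_stay_neutral(self):
        assert stouffer_combine([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_matches_normal_cdf_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = rng.uniform(0.001, 0.999, size=rng.integers(1, 8))
            z = stats.norm.ppf(1 - p)
            expected = 1 - stats.norm.cdf(z.sum() / np.sqrt(len(p)))
            assert stouffer_combine(p) == pytest.approx(expected, abs=1e-9)

    def test_matches_scipy_combine_pvalues(self):
        p = [0.01, 0.2, 0.6]
        expected = stats.combine_pvalues(p, method="stouffer").pvalue
        assert stouffer_combine(p) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            stouffer_combine([])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 0.99), min_size=1, max_size=6),
        st.data(),
    )
    def test_monotone_in_each_input(self, ps, data):
        i = data.draw(st.integers(0, len(ps) - 1))
        smaller = list(ps)
        smaller[i] = ps[i] * 0.5
        assert stouffer_combine(smaller) <= stouffer_combine(ps) + 1e-12


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.3]), [0.3])

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj_sorted = np.minimum.accumulate(
                (m * p[order] / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(adj_sorted, 1.0)
            np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=25)
        assert (bh_fdr(p) >= p - 1e-15).all()


def _toy_instance(seed=13, n_genes=30, effect=1.5):
    rng = np.random.default_rng(seed)
    design = _design(n_rep=3)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    m = pd.DataFrame(
        rng.normal(8, 0.5, size=(n_genes, 6)), index=genes, columns=design.index
    )
    sets = {f"s{j}": frozenset(genes[j * 6:(j + 1) * 6]) for j in range(5)}
    # graded planted effects so the sets rank differently
    for j, frac in enumerate([1.0, 0.6, 0.3, 0.1, 0.0]):
        rows = list(sets[f"s{j}"])
        m.loc[rows, design.index[design["treatment"] == "E"]] += effect * frac
    return m, sets, design


class TestRunGage:
    def test_planted_up_term_significant_only_upward(self):
        m, sets, design = _toy_instance(effect=3.0)
        tab = run_gage(m, sets, Contrast.from_name("E_vs_C"), design)
        up = tab[(tab.term == "s0") & (tab.direction == "up")].iloc[0]
        down = tab[(tab.term == "s0") & (tab.direction == "down")].iloc[0]
        assert up.fdr < 0.05
        assert down.fdr > 0.5

    def test_direction_antisymmetry_bitwise(self):
        m, sets, design = _toy_instance(seed=14)
        tab = run_gage(m, sets, Contrast.from_name("E_vs_C"), design)
        neg = run_gage(-m, sets, Contrast.from_name("E_vs_C"), design)
        for col in ("z", "p", "fdr"):
            np.testing.assert_array_equal(
                tab[tab.direction == "up"][col].to_numpy(),
                neg[neg.direction == "down"][col].to_numpy(),
            )
            np.testing.assert_array_equal(
                tab[tab.direction == "down"][col].to_numpy(),
                neg[neg.direction == "up"][col].to_numpy(),
            )

    def test_location_invariance_per_sample(self):
        m, sets, design = _toy_instance(seed=15)
        shifted = m.copy()
        shifted["E1"] += 7.5  # shifts every gene's fc in E1-columns equally
        tab = run_gage(m, sets, Contrast.from_name("E_vs_C"), design)
        tab2 = run_gage(shifted, sets, Contrast.from_name("E_vs_C"), design)
        np.testing.assert_allclose(
            tab["z"].to_numpy(), tab2["z"].to_numpy(), rtol=1e-9, atol=1e-9
        )

    def test_rank_agreement_with_permutation_oracle(self):
        m, sets, design = _toy_instance(seed=16, effect=1.0)
        tab = run_gage(m, sets, Contrast.from_name("E_vs_C"), design)
        up = tab[tab.direction == "up"].set_index("term")

        # oracle: gene-label permutation p for the summed set fold change
        fc = (
            m[design.index[design["treatment"] == "E"]].to_numpy()[:, :, None]
            - m[design.index[design["treatment"] == "C"]].to_numpy()[:, None, :]
        ).reshape(len(m), -1).sum(axis=1)
        rng = np.random.default_rng(0)
        perm_p = {}
        masks = {t: m.index.isin(g) for t, g in sets.items()}
        observed = {t: fc[mask].mean() for t, mask in masks.items()}
        exceed = {t: 1 for t in sets}
        for _ in range(10_000):
            perm = rng.permutation(fc)
            for t, mask in masks.items():
                if perm[mask].mean() >= observed[t]:
                    exceed[t] += 1
        perm_p = {t: exceed[t] / 10_001 for t in sets}
        terms = sorted(sets)
        rho = stats.spearmanr(
            [up.loc[t, "p"] for t in terms], [perm_p[t] for t in terms]
        ).statistic
        assert rho >= 0.9 - 1e-9

    def test_null_p_values_uniform_over_many_sets(self):
        # >=500 disjoint sets under a pure-noise matrix: combined p ~ U(0,1)
        rng = np.random.default_rng(17)
        design = _design(n_rep=3)
        n_sets, set_size = 600, 5
        genes = [f"g{i}" for i in range(n_sets * set_size)]
        m = pd.DataFrame(
            rng.normal(8, 1, size=(len(genes), 6)), index=genes, columns=design.index
        )
        sets = {
            f"s{j:03d}": frozenset(genes[j * set_size:(j + 1) * set_size])
            for j in range(n_sets)
        }
        tab = run_gage(m, sets, Contrast.from_name("E_vs_C"), design)
        for direction in ("up", "down"):
            p = tab[tab.direction == direction].p
            assert stats.kstest(p, "uniform").pvalue > 0.01
            assert 0.02 <= (p < 0.05).mean() <= 0.09

    def test_empty_gene_sets_warn_and_return_empty(self):
        m, _, design = _toy_instance()
        with pytest.warns(UserWarning):
            tab = run_gage(m, {}, Contrast.from_name("E_vs_C"), design)
        assert len(tab) == 0
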