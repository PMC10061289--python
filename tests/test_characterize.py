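import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomune.characterize import (
    bh_adjust,
    chi_square_independence,
    de_screen,
    km_logrank,
    ora_hypergeometric,
)
from oracles import bh_step_up, hypergeom_upper_tail


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, np.nan])

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1,
            max_size=25,
        )
    )
    def test_matches_oracle_and_order_invariant(self, ps):
        adjusted = bh_adjust(ps)
        assert np.allclose(adjusted, bh_step_up(ps), atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        assert np.allclose(np.asarray(adjusted)[perm], bh_adjust(list(np.asarray(ps)[perm])))

    def test_flat_adjusted_vectors_are_fixpoints(self):
        # a tie-flattened BH output re-adjusts to itself
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(adjusted), adjusted)


class TestDeScreen:
    def _expr(self, rng, n_genes=30, n_in=12, n_out=24):
        cols = [f"s{i}" for i in range(n_in + n_out)]
        labels = pd.Series(["T"] * n_in + ["R"] * n_out, index=cols)
        expr = pd.DataFrame(
            rng.lognormal(2, 0.5, size=(n_genes, n_in + n_out)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=cols,
        )
        return expr, labels

    def test_planted_fourfold_marker_flagged(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            expr, labels = self._expr(r, n_in=50, n_out=100)
            expr.iloc[0, :50] *= 16.0  # strong in-group marker
            table = de_screen(expr, labels, "T")
            hits += int(table.loc["g0", "differential"])
        assert hits >= 9

    def test_identical_distributions_not_flagged(self, rng):
        expr, labels = self._expr(rng)
        table = de_screen(expr, labels, "T")
        assert not table["differential"].any()

    def test_exact_boundary_log2fc_excluded(self):
        # in-group mean FPKM+1 exactly double the out-group: log2FC == 1
        cols = [f"s{i}" for i in range(8)]
        labels = pd.Series(["T"] * 4 + ["R"] * 4, index=cols)
        expr = pd.DataFrame(
            [[7.0, 7, 7, 7, 3, 3, 3, 3]], index=["g"], columns=cols
        )
        table = de_screen(expr, labels, "T")
        assert table.loc["g", "log2_fc"] == pytest.approx(1.0)
        assert not table.loc["g", "differential"]

    def test_constant_gene_gets_p_one_and_stays(self, rng):
        expr, labels = self._expr(rng)
        expr.iloc[5] = 2.0
        table = de_screen(expr, labels, "T")
        assert table.loc["g5", "p_value"] == 1.0
        assert "g5" in table.index

    def test_small_group_rejected(self, rng):
        expr, labels = self._expr(rng)
        labels[:] = "R"
        labels.iloc[0] = "T"
        with pytest.raises(ValueError, match="3 samples"):
            de_screen(expr, labels, "T")


class TestOra:
    def test_full_overlap_closed_form(self):
        universe = {f"g{i}" for i in range(20)}
        gene_set = {f"g{i}" for i in range(5)}
        p, overlap = ora_hypergeometric(gene_set, gene_set, universe)
        assert overlap == 5
        assert p == pytest.approx(1 / 15504, rel=1e-12)

    def test_minimal_overlap_is_certain(self):
        universe = {f"g{i}" for i in range(10)}
        p, overlap = ora_hypergeometric({"g9"}, {"g0", "g1"}, universe)
        assert overlap == 0
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("u,s,h", [(12, 4, 6), (10, 5, 5), (8, 3, 2)])
    def test_matches_exhaustive_enumeration(self, u, s, h, rng):
        universe = {f"g{i}" for i in range(u)}
        gene_set = set(rng.choice(sorted(universe), size=s, replace=False))
        hits = set(rng.choice(sorted(universe), size=h, replace=False))
        p, overlap = ora_hypergeometric(hits, gene_set, universe)
        assert p == pytest.approx(
            hypergeom_upper_tail(overlap, u, s, h), abs=1e-12
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ora_hypergeometric(set(), set(), set())


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        stat, p = chi_square_independence([[5, 10, 15], [5, 10, 15]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_diagonal_hand_value(self):
        stat, p = chi_square_independence([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)

    def test_doubling_cells_doubles_statistic(self, rng):
        table = rng.integers(1, 30, size=(3, 3))
        s1, _ = chi_square_independence(table)
        s2, _ = chi_square_independence(table * 2)
        assert s2 == pytest.approx(2 * s1)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [3, 4]])


class TestKmLogrank:
    def _survival(self, times, events, ids=None):
        ids = ids or [f"s{i}" for i in range(len(times))]
        return pd.DataFrame(
            {"os_months": times, "os_event": events},
            index=pd.Index(ids, name="sample_id"),
        )

    def test_no_censoring_matches_empirical_survival(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 10.0]
        surv = self._survival(times + [1.0], [1] * 6 + [1])
        labels = pd.Series(["a"] * 6 + ["b"], index=surv.index)
        curves = km_logrank(surv, labels)
        a = curves.groups["a"]
        # after m of n events the curve equals (n - m) / n
        lookup = dict(zip(a["time"], a["survival"]))
        for m, t in enumerate(times, start=1):
            assert lookup[t] == pytest.approx((6 - m) / 6)

    def test_identical_groups_give_null_statistic(self):
        times = [2.0, 3.0, 5.0, 8.0]
        surv = self._survival(times * 2, [1, 0, 1, 1] * 2)
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=surv.index)
        curves = km_logrank(surv, labels)
        assert curves.statistic == pytest.approx(0.0, abs=1e-12)
        assert curves.p_value == pytest.approx(1.0)

    def test_group_without_events_handled(self):
        surv = self._survival([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0])
        labels = pd.Series(["a", "a", "b", "b"], index=surv.index)
        curves = km_logrank(surv, labels)
        assert np.isfinite(curves.statistic)
        assert (curves.groups["b"]["survival"] == 1.0).all()

    def test_three_group_hazard_ratio_power(self):
        """Exponential groups with 3x hazard spread are detected reliably."""
        rejections = 0
        n_rep = 25
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            hazards = np.repeat([1 / 30, 1 / 60, 1 / 20], 100)
            times = r.exponential(1 / hazards)
            surv = self._survival(times, [1] * 300)
            labels = pd.Series(np.repeat(list("abc"), 100), index=surv.index)
            if km_logrank(surv, labels).p_value < 0.05:
                rejections += 1
        assert rejections >= int(0.9 * n_rep)
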