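"""Positional EFP statistics: counts, ratios, permutation and closed-form nulls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from enzloc import (
    analytic_null,
    count_positions,
    efp_report,
    estimate_q,
    load_efps,
    permutation_null,
    ratio_first_and_last,
    ratio_first_or_last,
)
from enzloc.efp import UndefinedRatioError, from_flags


class TestLoading:
    def test_flags_from_membership(self, tmp_path):
        p = tmp_path / "efps.tsv"
        p.write_text("E1\tR1,R2,R3\nE2\tR3,R2,R1\n")
        efps = load_efps(p, {"R1", "R3"})
        assert efps[0].loc_flags == (True, False, True)
        assert efps[0].k == 2 and efps[0].L == 3
        efps0 = load_efps(p, set())
        assert efps0[0].k == 0

    def test_unknown_reaction_warns_flag_false(self, tmp_path, caplog):
        p = tmp_path / "efps.tsv"
        p.write_text("E1\tR1,RX,R3\n")
        with caplog.at_level("WARNING"):
            efps = load_efps(p, {"R1"}, known_reactions={"R1", "R3"})
        assert "RX" in caplog.text
        assert efps[0].loc_flags == (True, False, False)

    def test_empty_efp_line_is_parse_error(self, tmp_path):
        p = tmp_path / "efps.tsv"
        p.write_text("E1\t\n")
        with pytest.raises(ValueError):
            load_efps(p, set())

    def test_out_of_range_lengths_dropped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "efps.tsv"
        p.write_text("E1\tR1,R2\nE2\tR1,R2,R3\n")
        with caplog.at_level("WARNING"):
            efps = load_efps(p, set())
        assert len(efps) == 1 and efps[0].L == 3
        assert "outside" in caplog.text


class TestCounts:
    def test_direct_counts(self):
        efps = from_flags([[1, 0, 0], [0, 0, 1], [1, 0, 1]])
        row = count_positions(efps).loc[3]
        assert row["n_any"] == 3 and row["n_first"] == 2
        assert row["n_last"] == 2 and row["n_both"] == 1
        assert row["n_first_or_last"] == 3

    def test_interior_only_flag(self):
        row = count_positions(from_flags([[0, 1, 0]])).loc[3]
        assert row["n_any"] == 1 and row["n_intermediate"] == 1
        assert row["n_first"] == 0 and row["n_last"] == 0

    def test_inclusion_exclusion_invariant(self):
        rng = np.random.default_rng(3)
        efps = from_flags([(rng.random(int(rng.integers(3, 13))) < 0.4).astype(int)
                           for _ in range(300)])
        df = count_positions(efps)
        assert (df["n_first_or_last"] == df["n_first"] + df["n_last"] - df["n_both"]).all()
        assert (df["n_both"] <= df[["n_first", "n_last"]].min(axis=1)).all()
        assert (df.drop(columns="n_total").le(df["n_total"], axis=0)).all().all()


class TestRatios:
    def test_first_or_last(self):
        efps = from_flags([[1, 0, 0], [0, 0, 1], [1, 0, 1]])
        assert ratio_first_or_last(efps, 3) == 1.0
        assert ratio_first_or_last(from_flags([[0, 1, 0]]), 3) == 0.0

    def test_first_and_last(self):
        assert ratio_first_and_last(from_flags([[1, 0, 1], [1, 1, 0]]), 3) == 0.5
        assert ratio_first_and_last(from_flags([[1, 0, 1]]), 3) == 1.0

    def test_undefined_ratios_raise(self):
        with pytest.raises(UndefinedRatioError):
            ratio_first_or_last(from_flags([[0, 0, 0]]), 3)
        with pytest.raises(UndefinedRatioError):
            ratio_first_and_last(from_flags([[1, 0, 0]]), 3)


class TestQTable:
    def test_conditional_estimate(self):
        q = estimate_q(from_flags([[1, 0, 0], [1, 0, 1], [0, 0, 0]]))
        assert dict(zip(q["k"], q["q"])) == {1: 0.5, 2: 0.5}

    def test_rows_sum_to_one_per_length(self):
        rng = np.random.default_rng(5)
        efps = from_flags([(rng.random(int(rng.integers(3, 13))) < 0.3).astype(int)
                           for _ in range(400)])
        q = estimate_q(efps)
        assert (q["k"] >= 1).all()
        sums = q.groupby("L")["q"].sum()
        assert np.allclose(sums, 1.0)

    def test_absent_length_has_no_row(self):
        q = estimate_q(from_flags([[1, 0, 0]]))
        assert set(q["L"]) == {3}


class TestAnalyticNull:
    def test_single_flag_length_three(self):
        # q(1;3)=1: chance that the one flag sits at either terminal is 2/3
        q = estimate_q(from_flags([[1, 0, 0]]))
        an = analytic_null(q, 3)
        assert an.p_first == pytest.approx(1 / 3)
        assert an.p_first_or_last == pytest.approx(2 / 3)

    def test_two_flags_length_four_both_terminals(self):
        q = pd.DataFrame({"L": [4], "k": [2], "n": [1], "q": [1.0]})
        assert analytic_null(q, 4).p_both == pytest.approx(1 / 6)

    def test_saturated_efp(self):
        q = pd.DataFrame({"L": [5], "k": [5], "n": [1], "q": [1.0]})
        an = analytic_null(q, 5)
        assert (an.p_first, an.p_both, an.p_first_or_last) == (1.0, 1.0, 1.0)

    def test_missing_length_raises(self):
        with pytest.raises(KeyError):
            analytic_null(estimate_q(from_flags([[1, 0, 0]])), 7)

    def test_bounds_for_random_q_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            L = int(rng.integers(3, 13))
            ks = rng.choice(np.arange(1, L + 1), size=int(rng.integers(1, L)), replace=False)
            w = rng.random(len(ks))
            q = pd.DataFrame({"L": L, "k": ks, "n": 1, "q": w / w.sum()})
            an = analytic_null(q, L)
            assert an.p_first_or_last >= max(an.p_first, an.p_last) - 1e-12
            assert an.p_first_or_last <= an.p_first + an.p_last + 1e-12
            assert 0.0 <= an.p_both <= an.p_first + 1e-12


class TestPermutationNull:
    @pytest.mark.parametrize("method", ["group", "shuffle"])
    def test_single_flag_null_frequency(self, method):
        # one EFP [1,0,0]: 2 of the 3 equally likely placements hit a terminal
        ns = permutation_null(from_flags([[1, 0, 0]]), 3, n_perm=10000,
                              seed=1, method=method)
        assert ns.null_mean == pytest.approx(2 / 3, abs=0.02)

    def test_saturated_flags_give_p_one(self):
        ns = permutation_null(from_flags([[1, 1, 1]]), 3, n_perm=500, seed=2)
        assert ns.p == 1.0 and ns.null_sd == 0.0 and ns.degenerate

    @pytest.mark.parametrize("method", ["group", "shuffle"])
    def test_first_and_last_null_frequency(self, method):
        # C(3,2)=3 placements of two flags; only {1,3} hits both terminals
        ns = permutation_null(from_flags([[1, 0, 1]]), 3, statistic="first_and_last",
                              n_perm=10000, seed=3, method=method)
        assert ns.null_mean == pytest.approx(1 / 3, abs=0.02)

    def test_no_eligible_efp_raises(self):
        with pytest.raises(UndefinedRatioError):
            permutation_null(from_flags([[0, 0, 0]]), 3, n_perm=10)

    def test_group_and_shuffle_samplers_agree(self):
        rng = np.random.default_rng(11)
        efps = from_flags([(rng.random(int(rng.integers(3, 9))) < 0.35).astype(int)
                           for _ in range(60)])
        a = permutation_null(efps, None, n_perm=4000, seed=4, method="group")
        b = permutation_null(efps, None, n_perm=4000, seed=5, method="shuffle")
        se = math.hypot(a.null_sd / math.sqrt(a.n_draws), b.null_sd / math.sqrt(b.n_draws))
        assert abs(a.null_mean - b.null_mean) < 4 * se
        assert a.null_sd == pytest.approx(b.null_sd, rel=0.1)

    def test_null_mean_matches_exact_enumeration(self):
        # independent oracle: average over every placement of every EFP
        efps = from_flags([[1, 0, 0, 0], [1, 1, 0, 0], [0, 1, 0, 1, 0]])
        expect = np.mean([
            np.mean([1 if (0 in c or e.L - 1 in c) else 0
                     for c in itertools.combinations(range(e.L), e.k)])
            for e in efps
        ])
        ns = permutation_null(efps, None, n_perm=20000, seed=6)
        assert ns.null_mean == pytest.approx(expect, abs=0.01)


class TestReport:
    def test_ordering_invariance(self):
        rng = np.random.default_rng(13)
        efps = from_flags([(rng.random(int(rng.integers(3, 13))) < 0.3).astype(int)
                           for _ in range(200)])
        fwd = efp_report(efps, n_perm=0)
        rev = efp_report(list(reversed(efps)), n_perm=0)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_degraded_mode_without_permutations(self):
        df = efp_report(from_flags([[1, 0, 0], [0, 0, 1], [1, 0, 1]]), n_perm=0)
        row = df[(df["L"] == 3) & (df["statistic"] == "first_or_last")].iloc[0]
        assert row["observed"] == 1.0
        assert np.isfinite(row["analytic"])
        assert np.isnan(row["perm_p"])

    def test_undefined_rows_kept_and_marked(self):
        df = efp_report(from_flags([[1, 0, 0]]), n_perm=0)
        assert len(df) == 20  # 10 lengths x 2 statistics, nothing dropped
        sub = df[(df["L"] == 7)]
        assert not sub["defined"].any()

    def test_empty_input_gives_empty_table(self):
        assert efp_report([], n_perm=0).empty
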