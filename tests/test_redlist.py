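"""Red List category semantics, status transitions, and the G-test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from caperisk.redlist import (SpeciesThreatRecord, StatusTransition,
                              ThreatCategory, g_statistic, is_threatened,
                              read_species_csv, status_change_index,
                              tertile_transition_gtest, threat_score,
                              transition_g, write_species_csv)
from oracles import multinomial_llr_g

CATS = list(ThreatCategory)


def rec(name, genus="G", cat=ThreatCategory.LC, qds=None):
    return SpeciesThreatRecord(name, genus, "F", "O", cat, qds)


class TestCategories:
    @pytest.mark.parametrize("code,expect", [
        ("LC", False), ("NT", False), ("VU", True), ("EN", True),
        ("CR", True), ("EW", True), ("EX", True),
    ])
    def test_threat_dichotomy(self, code, expect):
        assert is_threatened(ThreatCategory.parse(code)) is expect

    def test_scores_span_scale(self):
        assert threat_score(ThreatCategory.LC) == 0
        assert threat_score(ThreatCategory.VU) == 2
        assert threat_score(ThreatCategory.EW) == 5

    def test_score_strictly_monotone(self):
        scores = [threat_score(c) for c in CATS if c != ThreatCategory.EX]
        assert scores == sorted(scores) and len(set(scores)) == len(scores)

    def test_extinct_not_scorable(self):
        with pytest.raises(ValueError, match="0-5 scale"):
            threat_score(ThreatCategory.EX)

    @pytest.mark.parametrize("bad", ["DD", "NE", "XX", ""])
    def test_unknown_or_unassessed_codes_rejected(self, bad):
        with pytest.raises(ValueError):
            ThreatCategory.parse(bad)

    def test_total_order(self):
        assert (ThreatCategory.LC < ThreatCategory.NT < ThreatCategory.VU
                < ThreatCategory.EN < ThreatCategory.CR < ThreatCategory.EW
                < ThreatCategory.EX)


class TestTransitions:
    def test_delta_is_sign_of_rank_change(self):
        t = StatusTransition("x", ThreatCategory.LC, ThreatCategory.EN)
        assert t.delta == 1
        assert StatusTransition("x", ThreatCategory.CR, ThreatCategory.VU).delta == -1
        assert StatusTransition("x", ThreatCategory.EN, ThreatCategory.EN).delta == 0

    def test_change_index_sums_within_genus(self):
        old = [rec("a", cat=ThreatCategory.LC), rec("b", cat=ThreatCategory.VU),
               rec("c", cat=ThreatCategory.EN)]
        new = [rec("a", cat=ThreatCategory.EN), rec("b", cat=ThreatCategory.LC),
               rec("c", cat=ThreatCategory.EN)]
        index, report = status_change_index(old, new)
        assert index == {"G": 0}
        assert report["n_shared"] == 3

    def test_unpaired_species_counted_not_summed(self):
        old = [rec("a"), rec("only_old")]
        new = [rec("a", cat=ThreatCategory.VU), rec("only_new")]
        index, report = status_change_index(old, new)
        assert index == {"G": 1}
        assert report["n_only_old"] == report["n_only_new"] == 1

    def test_identical_lists_give_zero_everywhere(self):
        old = [rec(f"s{i}", genus=f"g{i % 3}",
                   cat=CATS[i % 5]) for i in range(12)]
        index, _ = status_change_index(old, old)
        assert all(v == 0 for v in index.values())

    def test_antisymmetry_under_list_swap(self):
        rng = np.random.default_rng(1)
        old = [rec(f"s{i}", genus=f"g{i % 4}",
                   cat=CATS[rng.integers(6)]) for i in range(30)]
        new = [rec(r.species_name, r.genus, cat=CATS[rng.integers(6)])
               for r in old]
        fwd, _ = status_change_index(old, new)
        rev, _ = status_change_index(new, old)
        assert fwd == {g: -v for g, v in rev.items()}

    def test_disjoint_lists_error(self):
        with pytest.raises(ValueError, match="no shared species"):
            status_change_index([rec("a")], [rec("b")])


class TestGStatistic:
    def test_zero_when_observed_equals_expected(self):
        assert g_statistic([10, 20, 30], [10, 20, 30]) == pytest.approx(0)

    def test_printed_tertile_counts(self):
        # goodness-of-fit of 43:44 against the 28:62 bottom-tertile proportions
        assert g_statistic([43, 44], [27.0667, 59.9333]) == pytest.approx(
            12.62, abs=0.01)

    @given(st.lists(st.integers(0, 60), min_size=2, max_size=6).filter(
        lambda o: sum(o) > 0))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_multinomial_likelihood_ratio_oracle(self, observed):
        o = np.array(observed, float)
        rng = np.random.default_rng(int(o.sum()))
        p = rng.dirichlet(np.ones(len(o)))
        e = p * o.sum()
        assert g_statistic(o, e) == pytest.approx(
            multinomial_llr_g(o, e), abs=1e-9)
        assert g_statistic(o, e) >= 0

    def test_close_to_pearson_chisq_at_large_expected(self):
        """G and Pearson chi-square agree asymptotically: with all expected
        counts >= 20 the typical relative deviation is below 5%."""
        rng = np.random.default_rng(3)
        rel = []
        for _ in range(50):
            e = rng.uniform(20, 200, size=4)
            o = rng.poisson(e).astype(float)
            o = o * e.sum() / o.sum()
            g = g_statistic(o, e)
            chi2 = float(((o - e) ** 2 / e).sum())
            if chi2 > 0.1:
                rel.append(abs(g - chi2) / chi2)
        assert np.mean(rel) < 0.05
        assert max(rel) < 0.2

    def test_total_mismatch_rejected(self):
        with pytest.raises(ValueError, match="totals differ"):
            g_statistic([10, 10], [5, 5])


class TestTertileGTest:
    @staticmethod
    def synth_transitions(top_inc, top_non, bot_inc, bot_non, n_mid=30):
        """Three tertiles of genera whose species realize the given counts."""
        transitions, genus_of = [], {}
        spec = [("top", ThreatCategory.CR, top_inc, top_non),
                ("mid", ThreatCategory.VU, n_mid // 2, n_mid - n_mid // 2),
                ("bot", ThreatCategory.LC, bot_inc, bot_non)]
        sp = 0
        for block, old_cat, n_inc, n_non in spec:
            for j in range(3):  # three genera per tertile
                for k in range(n_inc // 3 + (j < n_inc % 3)):
                    name = f"s{sp}"; sp += 1
                    genus_of[name] = f"{block}{j}"
                    transitions.append(StatusTransition(
                        name, old_cat, ThreatCategory(min(int(old_cat) + 1, 5))))
                for k in range(n_non // 3 + (j < n_non % 3)):
                    name = f"s{sp}"; sp += 1
                    genus_of[name] = f"{block}{j}"
                    transitions.append(StatusTransition(name, old_cat, old_cat))
        return transitions, genus_of

    def test_reproduces_printed_g(self):
        transitions, genus_of = self.synth_transitions(43, 44, 28, 62)
        res = tertile_transition_gtest(transitions, genus_of)
        assert res["top_counts"] == (43, 44)
        assert res["bottom_counts"] == (28, 62)
        assert res["G"] == pytest.approx(12.61, abs=0.05)
        assert res["p"] < 0.001

    def test_independence_framing_is_available_but_different(self):
        assert transition_g([43, 44], [28, 62],
                            framing="independence") == pytest.approx(6.21, abs=0.05)

    def test_identical_ratios_give_zero(self):
        transitions, genus_of = self.synth_transitions(20, 40, 20, 40)
        assert tertile_transition_gtest(transitions, genus_of)["G"] == \
            pytest.approx(0, abs=1e-9)

    def test_invariant_to_genus_relabelling(self):
        transitions, genus_of = self.synth_transitions(43, 44, 28, 62)
        perm = {g: f"renamed_{g}" for g in set(genus_of.values())}
        res1 = tertile_transition_gtest(transitions, genus_of)
        res2 = tertile_transition_gtest(
            transitions, {s: perm[g] for s, g in genus_of.items()})
        assert res1["G"] == pytest.approx(res2["G"])

    def test_p_from_chi2_1df(self):
        transitions, genus_of = self.synth_transitions(43, 44, 28, 62)
        res = tertile_transition_gtest(transitions, genus_of)
        assert res["p"] == pytest.approx(float(stats.chi2.sf(res["G"], 1)))


class TestIO:
    def test_species_csv_round_trip(self, tmp_path):
        recs = [rec("Aa bb", genus="Aa", cat=ThreatCategory.EN, qds=3),
                rec("Cc dd", genus="Cc", cat=ThreatCategory.LC)]
        path = tmp_path / "species.csv"
        write_species_csv(recs, path)
        assert read_species_csv(path) == recs

    def test_missing_columns_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species,genus\nx,y\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_species_csv(p)
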