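import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from rbplandscape.data_io import (
    BinaryInteractionNetwork,
    FunctionalUnit,
    FunctionalUnitCompendium,
)
from rbplandscape.enrichment_core import (
    ContingencyTable,
    bh_adjust,
    build_contingency,
    compare_networks,
    compute_landscape,
    fisher_exact_two_sided,
    log2_interaction_ratio,
    permutation_control,
)


def enumeration_fisher(a, b, c, d):
    """Independent oracle: exact-fraction enumeration over fixed margins."""
    N, K, n = a + b + c + d, a + b, a + c
    if N == 0:
        return 1.0
    denom = comb(N, n)
    amin, amax = max(0, n - (N - K)), min(K, n)
    probs = {x: comb(K, x) * comb(N - K, n - x) for x in range(amin, amax + 1)}
    total = sum(q for q in probs.values() if q <= probs[a])
    return float(Fraction(total, denom))


class TestContingency:
    net = BinaryInteractionNetwork(
        frozenset({"R", "Z"}),
        frozenset(f"g{i}" for i in range(1, 11)),
        frozenset({("R", "g1"), ("R", "g7")}),
    )
    bg = frozenset(f"g{i}" for i in range(1, 11))

    def test_direct_counts(self):
        u = FunctionalUnit("U", "complex", frozenset({"g1", "g2", "g3"}))
        t = build_contingency("R", u, self.net, self.bg)
        assert (t.a, t.b, t.c, t.d) == (1, 2, 1, 6)

    def test_rbp_without_targets(self):
        u = FunctionalUnit("U", "complex", frozenset({"g1", "g2", "g3"}))
        t = build_contingency("Z", u, self.net, self.bg)
        assert t.a == 0 and t.c == 0 and t.n == 10

    def test_unit_equal_to_background(self):
        u = FunctionalUnit("U", "complex", self.bg)
        t = build_contingency("R", u, self.net, self.bg)
        assert t.c == 0 and t.d == 0 and t.a == 2

    def test_unit_outside_background_rejected(self):
        u = FunctionalUnit("U", "complex", frozenset({"zz"}))
        with pytest.raises(ValueError):
            build_contingency("R", u, self.net, self.bg)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestLog2Ratio:
    def test_balanced_proportions_give_zero(self):
        assert log2_interaction_ratio(ContingencyTable(5, 5, 500, 500)) == 0.0

    def test_fourfold_ratio(self):
        assert log2_interaction_ratio(ContingencyTable(8, 2, 200, 800)) == pytest.approx(2.0)

    def test_zero_cell_sentinels(self):
        assert log2_interaction_ratio(ContingencyTable(0, 10, 100, 900)) == -math.inf
        assert log2_interaction_ratio(ContingencyTable(5, 5, 0, 900)) == math.inf
        assert math.isnan(log2_interaction_ratio(ContingencyTable(0, 10, 0, 900)))

    def test_empty_margin_is_an_error(self):
        with pytest.raises(ValueError):
            log2_interaction_ratio(ContingencyTable(0, 0, 5, 5))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st_h.tuples(*[st_h.integers(1, 40)] * 4))
    def test_antisymmetric_under_unit_complement_swap(self, counts):
        # exchanging the unit and non-unit rows negates the log ratio
        a, b, c, d = counts
        r = log2_interaction_ratio(ContingencyTable(a, b, c, d))
        r_swapped = log2_interaction_ratio(ContingencyTable(c, d, a, b))
        assert r == pytest.approx(-r_swapped)


class TestFisherExact:
    def test_worked_example_34_of_70(self):
        # margins 4/4 x 4/4: enumeration gives 34/70
        assert fisher_exact_two_sided(ContingencyTable(3, 1, 1, 3)) == pytest.approx(34 / 70)

    def test_extreme_diagonal_table(self):
        # C(10,5)=252; the two extreme tables each have probability 1/252
        assert fisher_exact_two_sided(ContingencyTable(5, 0, 0, 5)) == pytest.approx(2 / 252)

    def test_most_probable_table_has_p_one(self):
        assert fisher_exact_two_sided(ContingencyTable(2, 2, 2, 2)) == pytest.approx(1.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st_h.tuples(*[st_h.integers(0, 15)] * 4))
    def test_matches_enumeration_oracle(self, counts):
        t = ContingencyTable(*counts)
        assert fisher_exact_two_sided(t) == pytest.approx(
            enumeration_fisher(*counts), abs=1e-12
        )

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st_h.tuples(*[st_h.integers(0, 25)] * 4))
    def test_matches_scipy(self, counts):
        a, b, c, d = counts
        ours = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        ref = st.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


class TestBhAdjust:
    def test_step_up_worked_example(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st_h.lists(st_h.floats(0, 1), min_size=1, max_size=20))
    def test_never_below_raw_and_order_preserving(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestLandscape:
    def test_planted_regulons_called_enriched(self, strong_instance):
        ls = strong_instance["landscape"]
        ledger = strong_instance["ledger"]
        calls = {(r.rbp_id, r.unit_id): r.direction for r in ls.table.itertuples()}
        planted_enr = [(r, u) for r, u, m in ledger.planted if m == "enrich"]
        hits = sum(calls[p] == "enriched" for p in planted_enr)
        assert hits / len(planted_enr) >= 0.95

    def test_alpha_zero_silences_all_calls(self, strong_instance):
        ls = compute_landscape(
            strong_instance["network"],
            strong_instance["compendium"],
            strong_instance["background"],
            alpha=0.0,
        )
        assert (ls.table.direction == "none").all()

    def test_one_record_per_pair_and_margin_invariant(self, strong_instance):
        ls = strong_instance["landscape"]
        df = ls.table
        assert not df.duplicated(["rbp_id", "unit_id"]).any()
        n_bg = len(strong_instance["background"])
        assert ((df.a + df.b + df.c + df.d) == n_bg).all()

    def test_direction_consistent_with_ratio_and_alpha(self, strong_instance):
        df = strong_instance["landscape"].table
        sig = df[df.direction != "none"]
        assert ((sig.direction == "enriched") == (sig.log2_ratio > 0)).all()
        assert (sig.p_adj < strong_instance["landscape"].alpha).all()

    def test_global_family_is_more_lenient_than_bonferroni_like_union(self, strong_instance):
        ls = compute_landscape(
            strong_instance["network"],
            strong_instance["compendium"],
            strong_instance["background"],
            family="global",
        )
        # same raw p-values, different correction family
        per_rbp = strong_instance["landscape"].table.sort_values(["rbp_id", "unit_id"])
        glob = ls.table.sort_values(["rbp_id", "unit_id"])
        assert np.allclose(per_rbp.p.to_numpy(), glob.p.to_numpy())
        assert not np.allclose(per_rbp.p_adj.to_numpy(), glob.p_adj.to_numpy())


class TestPermutationControl:
    def test_promiscuous_rbps_fail_and_specific_pass(self, strong_instance):
        verdicts = strong_instance["verdicts"]
        ledger = strong_instance["ledger"]
        for r in ledger.promiscuous:
            assert not verdicts[r].kept
        planted_rbps = {r for r, _, _ in ledger.planted}
        kept = sum(verdicts[r].kept for r in planted_rbps)
        assert kept / len(planted_rbps) >= 0.95

    def test_empirical_p_uses_add_one_rule(self, strong_instance):
        v = next(
            v for v in strong_instance["verdicts"].values() if v.testable
        )
        S = len(v.null_enriched)
        k = sum(1 for x in v.null_enriched if x >= v.observed_n_enriched)
        assert v.empirical_p_enriched == pytest.approx((1 + k) / (1 + S))
        assert 0 < v.empirical_p_enriched <= 1

    def test_untestable_rbps_have_no_null_counts(self, strong_instance):
        untestable = [v for v in strong_instance["verdicts"].values() if not v.testable]
        assert untestable, "expected some RBPs with no significant result"
        for v in untestable:
            assert v.null_enriched == () and not v.kept

    def test_reproducible_given_seed(self, strong_instance):
        kw = dict(
            n_shuffles=50,
            seed=7,
            landscape=strong_instance["landscape"],
        )
        v1 = permutation_control(
            strong_instance["network"],
            strong_instance["compendium"],
            strong_instance["background"],
            **kw,
        )
        v2 = permutation_control(
            strong_instance["network"],
            strong_instance["compendium"],
            strong_instance["background"],
            **kw,
        )
        assert v1 == v2


class TestCompareNetworks:
    universe = frozenset(f"g{i}" for i in range(1000))

    def net(self, targets):
        return BinaryInteractionNetwork(
            frozenset({"R"}), self.universe, frozenset(("R", g) for g in targets)
        )

    def test_identical_target_sets_strongly_associated(self):
        targets = frozenset(f"g{i}" for i in range(50))
        df = compare_networks(self.net(targets), self.net(targets), self.universe)
        row = df.iloc[0]
        assert row.odds_ratio == math.inf and row.p < 1e-10

    def test_independent_sets_rarely_significant(self, rng):
        genes = sorted(self.universe)
        n_sig = 0
        for _ in range(20):
            t1 = frozenset(rng.choice(genes, 50, replace=False))
            t2 = frozenset(rng.choice(genes, 50, replace=False))
            df = compare_networks(self.net(t1), self.net(t2), self.universe)
            n_sig += int(df.iloc[0].p < 0.05)
        assert n_sig <= 4

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            compare_networks(self.net(set()), self.net(set()), frozenset())
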