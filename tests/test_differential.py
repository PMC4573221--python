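"""OR / RANK / JSD differential scores and the colored community network."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from konet import (
    AbundanceTable,
    NumericError,
    ValidationError,
    construct_metabolic_network,
    construct_ssn,
    differential_analyze,
    jensen_shannon_bernoulli,
    score_jsd,
    score_or,
    score_rank,
)
from conftest import make_table

TWO_STATES = {"a1": "s1", "a2": "s1", "b1": "s2", "b2": "s2"}


def two_state_table(rows, labels=None):
    """rows: {sample: {ko: count}}; default labels prefix a->s1, b->s2."""
    if labels is None:
        labels = {s: "s1" if s.startswith("a") else "s2" for s in rows}
    return make_table(rows, state_labels=labels)


def random_two_state_table(rng, n_kos=10, n_per_state=3):
    rows = {}
    labels = {}
    for st_, prefix in (("s1", "a"), ("s2", "b")):
        for i in range(n_per_state):
            s = f"{prefix}{i}"
            rows[s] = {
                f"K{j:05d}": float(rng.integers(0, 20)) for j in range(n_kos)
            }
            labels[s] = st_
    return make_table(rows, state_labels=labels)


class TestScoreOR:
    def test_identical_states_score_zero_everywhere(self):
        rows = {"a1": {"K1": 2.0, "K2": 1.0}, "b1": {"K1": 2.0, "K2": 1.0}}
        res = score_or(two_state_table(rows), "s1", "s2", pseudocount=0.0)
        np.testing.assert_allclose(res.raw["odds_ratio"], 1.0)
        np.testing.assert_allclose(res.scores, 0.0)
        assert set(res.directions) == {"unchanged"}

    def test_hand_worked_two_ko_example(self):
        rows = {"a1": {"k1": 2.0, "k2": 1.0}, "b1": {"k1": 1.0, "k2": 2.0}}
        res = score_or(two_state_table(rows), "s1", "s2", pseudocount=0.0)
        by_ko = dict(zip(res.ko_ids, res.raw["odds_ratio"]))
        assert by_ko["k1"] == pytest.approx(4.0)
        scores = dict(zip(res.ko_ids, res.scores))
        assert scores["k1"] == pytest.approx(2.0)
        dirs = dict(zip(res.ko_ids, res.directions))
        assert dirs == {"k1": "enriched", "k2": "depleted"}

    @pytest.mark.parametrize("seed", range(5))
    def test_label_swap_inverts_or_and_flips_directions(self, seed):
        rng = np.random.default_rng(seed)
        t = random_two_state_table(rng)
        fwd = score_or(t, "s1", "s2")
        rev = score_or(t, "s2", "s1")
        np.testing.assert_allclose(
            rev.raw["odds_ratio"], 1.0 / fwd.raw["odds_ratio"], rtol=1e-9
        )
        np.testing.assert_allclose(rev.scores, fwd.scores, atol=1e-12)
        flip = {"enriched": "depleted", "depleted": "enriched",
                "unchanged": "unchanged"}
        assert rev.directions == [flip[d] for d in fwd.directions]

    def test_zero_total_state_with_zero_pseudocount_is_numeric_error(self):
        rows = {"a1": {"K1": 0.0}, "b1": {"K1": 2.0}}
        with pytest.raises(NumericError):
            score_or(two_state_table(rows), "s1", "s2", pseudocount=0.0)

    def test_zero_in_one_state_ko_is_infinite_and_flagged(self, caplog):
        rows = {"a1": {"K1": 2.0, "K2": 0.0}, "b1": {"K1": 1.0, "K2": 3.0}}
        res = score_or(two_state_table(rows), "s1", "s2", pseudocount=0.0)
        scores = dict(zip(res.ko_ids, res.scores))
        assert np.isinf(scores["K2"])
        assert any("infinite" in r.message for r in caplog.records)

    def test_default_pseudocount_keeps_scores_finite(self):
        rows = {"a1": {"K1": 2.0, "K2": 0.0}, "b1": {"K1": 1.0, "K2": 3.0}}
        res = score_or(two_state_table(rows), "s1", "s2")
        assert np.isfinite(res.scores).all()

    def test_empty_state_rejected(self):
        rows = {"a1": {"K1": 1.0}, "b1": {"K1": 1.0}}
        with pytest.raises(ValidationError):
            score_or(two_state_table(rows), "s1", "nope")


class TestScoreRank:
    def test_identical_samples_score_zero(self):
        rows = {"a1": {"K1": 3.0, "K2": 1.0}, "b1": {"K1": 3.0, "K2": 1.0}}
        res = score_rank(two_state_table(rows), "s1", "s2")
        np.testing.assert_allclose(res.scores, 0.0)

    def test_rank_reversal_example(self):
        rows = {"a1": {"k1": 3.0, "k2": 1.0}, "b1": {"k1": 1.0, "k2": 3.0}}
        res = score_rank(two_state_table(rows), "s1", "s2")
        scores = dict(zip(res.ko_ids, res.scores))
        dirs = dict(zip(res.ko_ids, res.directions))
        assert scores == pytest.approx({"k1": 1.0, "k2": 1.0})
        assert dirs == {"k1": "enriched", "k2": "depleted"}

    def test_full_tie_gives_average_rank_and_zero_scores(self):
        rows = {"a1": {"K1": 2.0, "K2": 2.0, "K3": 2.0},
                "b1": {"K1": 5.0, "K2": 5.0, "K3": 5.0}}
        res = score_rank(two_state_table(rows), "s1", "s2")
        np.testing.assert_allclose(res.raw["mean_rank_state1"], 2.0)  # (m+1)/2
        np.testing.assert_allclose(res.scores, 0.0)

    def test_zero_abundance_kos_tie_at_the_bottom(self):
        rows = {"a1": {"K1": 5.0, "K2": 0.0, "K3": 0.0},
                "b1": {"K1": 5.0, "K2": 1.0, "K3": 0.0}}
        res = score_rank(two_state_table(rows), "s1", "s2")
        m1 = dict(zip(res.ko_ids, res.raw["mean_rank_state1"]))
        assert m1["K2"] == m1["K3"] == 2.5

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        t = random_two_state_table(rng)
        res = score_rank(t, "s1", "s2")
        transformed = AbundanceTable.from_counts(
            t.sample_ids, t.ko_ids, np.expm1(t.counts), t.state_labels
        )
        res2 = score_rank(transformed, "s1", "s2")
        np.testing.assert_allclose(res2.scores, res.scores, atol=1e-12)


class TestScoreJSD:
    def test_identical_distributions_score_zero(self):
        rows = {"a1": {"K1": 3.0, "K2": 1.0}, "b1": {"K1": 3.0, "K2": 1.0}}
        res = score_jsd(two_state_table(rows), "s1", "s2")
        np.testing.assert_allclose(res.scores, 0.0)

    def test_disjoint_support_attains_the_base2_bound(self):
        assert jensen_shannon_bernoulli(np.array([1.0]), np.array([0.0]))[0] == (
            pytest.approx(1.0)
        )

    def test_half_versus_certain_example(self):
        got = jensen_shannon_bernoulli(np.array([0.5]), np.array([1.0]))[0]
        assert got == pytest.approx(0.311278, abs=1e-6)

    @given(
        p=st.floats(min_value=0, max_value=1, allow_nan=False),
        q=st.floats(min_value=0, max_value=1, allow_nan=False),
    )
    def test_symmetry_bounds_and_identity_of_indiscernibles(self, p, q):
        a = jensen_shannon_bernoulli(np.array([p]), np.array([q]))[0]
        b = jensen_shannon_bernoulli(np.array([q]), np.array([p]))[0]
        assert a == pytest.approx(b, abs=1e-12)
        assert 0.0 <= a <= 1.0
        if p == q:
            assert a == pytest.approx(0.0, abs=1e-12)
        elif abs(p - q) > 1e-9:
            assert a > 0.0

    def test_direction_follows_state1_mean(self):
        rows = {"a1": {"K1": 9.0, "K2": 1.0}, "b1": {"K1": 1.0, "K2": 9.0}}
        res = score_jsd(two_state_table(rows), "s1", "s2")
        dirs = dict(zip(res.ko_ids, res.directions))
        assert dirs == {"K1": "enriched", "K2": "depleted"}


class TestDifferentialAnalyze:
    def build(self, rows, reactions, labels=None):
        table = two_state_table(rows, labels)
        ref = construct_metabolic_network(reactions)
        ssns = [construct_ssn(table, s, ref) for s in table.sample_ids]
        return table, ssns

    def test_identical_ssns_are_all_neutral(self, chain_reactions):
        rows = {"a1": {"K1": 2.0, "K2": 1.0}, "b1": {"K1": 2.0, "K2": 1.0}}
        table, ssns = self.build(rows, chain_reactions)
        net, res = differential_analyze(ssns, table, table.state_labels)
        assert all(
            net.graph.nodes[n]["direction"] == "unchanged"
            and net.graph.nodes[n]["color"] == "#CCCCCC"
            for n in net.graph.nodes
        )

    def test_union_of_overlapping_ssns(self, chain_reactions):
        rows = {"a1": {"K1": 1.0, "K2": 1.0}, "b1": {"K2": 1.0, "K3": 1.0}}
        table, ssns = self.build(rows, chain_reactions)
        net, _ = differential_analyze(ssns, table, table.state_labels)
        assert net.nodes == {"K1", "K2", "K3"}
        assert net.edges == {("K1", "K2"), ("K2", "K3")}
        assert net.kind == "differential"

    def test_state1_only_ko_is_colored_red_under_or(self, chain_reactions):
        rows = {
            "a1": {"K1": 5.0, "K2": 5.0, "K3": 5.0},
            "b1": {"K2": 5.0, "K3": 5.0},
        }
        table, ssns = self.build(rows, chain_reactions)
        net, res = differential_analyze(
            ssns, table, table.state_labels, method="or", pseudocount=1e-6
        )
        assert net.graph.nodes["K1"]["direction"] == "enriched"
        assert net.graph.nodes["K1"]["color"] == "#FF0000"

    def test_default_threshold_is_09_quantile_of_nonzero_scores(self, chain_reactions):
        rows = {
            "a1": {"K1": 8.0, "K2": 2.0, "K3": 1.0},
            "b1": {"K1": 1.0, "K2": 2.0, "K3": 8.0},
        }
        table, ssns = self.build(rows, chain_reactions)
        _, res = differential_analyze(ssns, table, table.state_labels, method="rank")
        nonzero = res.scores[res.scores > 0]
        assert res.threshold_used == pytest.approx(np.quantile(nonzero, 0.9))

    def test_missing_state_ssn_rejected(self, chain_reactions):
        rows = {"a1": {"K1": 1.0}, "b1": {"K1": 1.0}}
        table, ssns = self.build(rows, chain_reactions)
        with pytest.raises(ValidationError, match="no SSN"):
            differential_analyze(ssns[:1], table, table.state_labels)

    def test_unknown_method_rejected(self, chain_reactions):
        rows = {"a1": {"K1": 1.0}, "b1": {"K1": 1.0}}
        table, ssns = self.build(rows, chain_reactions)
        with pytest.raises(ValidationError, match="method"):
            differential_analyze(ssns, table, table.state_labels, method="ttest")

    def test_tsv_export_round_trip_columns(self, tmp_path, chain_reactions):
        rows = {"a1": {"K1": 2.0, "K2": 1.0}, "b1": {"K1": 1.0, "K2": 2.0}}
        table, ssns = self.build(rows, chain_reactions)
        _, res = differential_analyze(ssns, table, table.state_labels)
        p = tmp_path / "diff.tsv"
        res.to_tsv(p)
        header = p.read_text().splitlines()[0].split("\t")
        assert header[:3] == ["ko", "score", "direction"]
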