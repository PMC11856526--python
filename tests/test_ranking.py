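"""Rank-score aggregation: medians, tie handling, normalization, the
weighted aggregate, oracle equivalence and the algebraic invariants."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfrank.annotation_io import ValidationError
from surfrank.ranking import (
    RankingConfig,
    aggregate_scores,
    assign_rank_scores,
    median_expression,
    normalize_scores,
    rank_targets,
    round_half_away_from_zero,
)

from conftest import (
    TABLE1_AGGREGATES,
    TABLE1_MODALITY,
    TABLE1_RS,
    make_bulk_dataset,
    oracle_median,
    oracle_rank_scores,
    oracle_rank_table,
    random_ranking_instance,
)


class TestMedianExpression:
    def test_odd_and_even_counts(self):
        ds = make_bulk_dataset(np.array([[1.0], [3.0], [100.0]]), ["g"])
        assert median_expression(ds, ["g"]) == {"g": 3.0}
        ds2 = make_bulk_dataset(np.array([[1.0], [3.0]]), ["g"])
        assert median_expression(ds2, ["g"]) == {"g": 2.0}

    def test_case_group_only(self):
        values = np.array([[1.0], [1.0], [99.0], [99.0]])
        ds = make_bulk_dataset(values, ["g"], n_case=2)
        assert median_expression(ds, ["g"], "case") == {"g": 1.0}
        assert median_expression(ds, ["g"], "control") == {"g": 99.0}

    def test_matches_sort_based_oracle_on_random_matrix(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(8)]
        ds = make_bulk_dataset(rng.gamma(2, 10, (35, 8)), genes)
        med = median_expression(ds, genes)
        for g in genes:
            assert med[g] == oracle_median(ds.values[g].tolist())

    def test_missing_gene_warns_and_is_excluded(self):
        ds = make_bulk_dataset(np.ones((3, 1)), ["g"])
        with pytest.warns(UserWarning, match="not present"):
            med = median_expression(ds, ["g", "absent"])
        assert set(med) == {"g"}


class TestRankScores:
    def test_eight_distinct_medians_span_the_scale(self):
        med = {f"g{i}": float(i) for i in range(8)}
        rs = assign_rank_scores(med)
        assert rs["g7"] == pytest.approx(0.8)
        assert sorted(rs.values()) == pytest.approx([0.1 * k for k in range(1, 9)])

    def test_single_gene(self):
        assert assign_rank_scores({"g": 5.0}) == {"g": pytest.approx(0.1)}

    def test_two_way_tie_for_top_among_four(self):
        med = {"a": 1.0, "b": 2.0, "c": 9.0, "d": 9.0}
        rs = assign_rank_scores(med)
        # tied genes share the mean of their tied ranks' scores; either
        # resolution of the tie gives one of (0.3, 0.4), averaging to 0.35
        assert rs["c"] == rs["d"] == pytest.approx((0.3 + 0.4) / 2)
        assert sum(rs.values()) == pytest.approx(0.1 + 0.2 + 0.3 + 0.4)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            med = {f"g{i}": float(v) for i, v in
                   enumerate(rng.integers(0, 4, rng.integers(1, 7)))}
            got = assign_rank_scores(med)
            want = oracle_rank_scores(med)
            assert got == pytest.approx(want)


class TestNormalizedScores:
    def test_published_ratio(self):
        ns = normalize_scores({"a": 0.7, "b": 0.8})
        assert ns["a"] == pytest.approx(0.875)
        assert ns["b"] == pytest.approx(1.0)

    def test_single_gene_is_one(self):
        assert normalize_scores({"g": 0.1}) == {"g": pytest.approx(1.0)}

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.dictionaries(st.sampled_from("abcdef"),
                           st.floats(0.01, 10), min_size=1))
    def test_algebraic_inverse(self, rs):
        ns = normalize_scores(rs)
        top = max(rs.values())
        for g in rs:
            assert ns[g] * top == pytest.approx(rs[g])
        assert max(ns.values()) == pytest.approx(1.0)


class TestAggregateScores:
    def test_published_target_row(self):
        ns = {"A": {"g": 0.875}, "C": {"g": 1.0}, "G": {"g": 1.0},
              "H": {"g": 0.875}}
        mod = {"A": "transcript", "C": "transcript", "G": "transcript",
               "H": "protein"}
        t = aggregate_scores(ns, mod)
        assert round_half_away_from_zero(t.xbar_t["g"]) == 0.958
        assert round_half_away_from_zero(t.xbar_tp["g"]) == 0.938

    def test_equal_components_are_fixed_point(self):
        ns = {"T": {"g": 0.6}, "P": {"g": 0.6}}
        t = aggregate_scores(ns, {"T": "transcript", "P": "protein"})
        assert t.xbar_tp["g"] == pytest.approx(0.6)

    def test_no_protein_datasets_degenerates_to_transcript_mean(self):
        ns = {"T1": {"g": 0.4}, "T2": {"g": 0.8}}
        t = aggregate_scores(ns, {"T1": "transcript", "T2": "transcript"})
        assert t.xbar_tp["g"] == pytest.approx(t.xbar_t["g"]) == pytest.approx(0.6)

    def test_gene_missing_somewhere_is_dropped_with_warning(self):
        ns = {"T": {"g": 1.0, "h": 0.5}, "P": {"g": 1.0}}
        with pytest.warns(UserWarning, match="missing"):
            t = aggregate_scores(ns, {"T": "transcript", "P": "protein"})
        assert t.genes == ["g"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_scores({}, {})


class TestPublishedTableReproduction:
    """Feeding the published per-dataset rank scores through the chain
    reproduces the published aggregate columns at 3 decimals."""

    def test_full_table(self):
        ns = {ds: normalize_scores(rs) for ds, rs in TABLE1_RS.items()}
        t = aggregate_scores(ns, TABLE1_MODALITY, rank_scores=TABLE1_RS)
        for g, (xt, xp, xtp) in TABLE1_AGGREGATES.items():
            assert round_half_away_from_zero(t.xbar_t[g]) == xt
            assert round_half_away_from_zero(t.xbar_p[g]) == xp
            assert round_half_away_from_zero(t.xbar_tp[g]) == xtp
        assert t.top_gene == "TM4SF4"


class TestRankTargetsEndToEnd:
    def test_single_dataset_single_gene(self):
        ds = make_bulk_dataset(np.ones((3, 1)), ["g"])
        t = rank_targets([ds], [], ["g"])
        assert t.xbar_tp["g"] == pytest.approx(1.0)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            datasets, genes = random_ranking_instance(rng)
            transcript = [d for d in datasets if d.modality == "transcript"]
            protein = [d for d in datasets if d.modality == "protein"]
            t = rank_targets(transcript, protein, genes)
            want = oracle_rank_table(datasets, genes)
            for g in t.genes:
                assert t.xbar_tp[g] == pytest.approx(want["xbar_tp"][g], abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_scale_invariance_and_bounds(self, seed):
        """Multiplying one dataset's values by a positive constant leaves
        the table unchanged; all scores live in (0, 1]."""
        rng = np.random.default_rng(seed)
        datasets, genes = random_ranking_instance(rng)
        transcript = [d for d in datasets if d.modality == "transcript"]
        protein = [d for d in datasets if d.modality == "protein"]
        t1 = rank_targets(transcript, protein, genes)
        scaled = (transcript + protein)[0]
        scaled.values = scaled.values * 37.5
        t2 = rank_targets(transcript, protein, genes)
        for g in t1.genes:
            assert t1.xbar_tp[g] == pytest.approx(t2.xbar_tp[g], abs=1e-12)
            assert 0 < t1.xbar_tp[g] <= 1
            lo = min(t1.xbar_t[g], t1.xbar_p[g]) if protein and transcript else 0
            hi = max(t1.xbar_t[g], t1.xbar_p[g])
            if protein and transcript:
                assert lo - 1e-12 <= t1.xbar_tp[g] <= hi + 1e-12
        for ds in t1.normalized_scores.values():
            assert max(ds.values()) == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_monotonicity_in_one_dataset_median(self, seed):
        """Raising one gene's values in one dataset (no new ties) never
        lowers its rank score, normalized score or aggregate."""
        rng = np.random.default_rng(seed)
        datasets, genes = random_ranking_instance(rng)
        if len(genes) < 2:
            return
        transcript = [d for d in datasets if d.modality == "transcript"]
        protein = [d for d in datasets if d.modality == "protein"]
        t1 = rank_targets(transcript, protein, genes)
        target, ds = genes[0], datasets[0]
        before = t1.rank_scores[ds.dataset_id][target]
        ds.values[target] = ds.values[target] + 1e6  # clears every tie upward
        t2 = rank_targets(transcript, protein, genes)
        assert t2.rank_scores[ds.dataset_id][target] >= before - 1e-12
        assert t2.xbar_tp[target] >= t1.xbar_tp[target] - 1e-12


@pytest.mark.parametrize(
    "value, expected",
    [(0.5625, 0.563), (0.71875, 0.719), (0.4583333, 0.458), (-0.0005, -0.001)],
)
def test_round_half_away_from_zero(value, expected):
    assert round_half_away_from_zero(value) == expected


def test_rs_step_must_be_positive():
    with pytest.raises(ValidationError):
        RankingConfig(rs_step=0)
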