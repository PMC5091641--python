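import numpy as np
import pytest

from clanseeker import (
    AlignmentHit,
    DetectionMatrix,
    build_family_graph,
    clan_groups,
    cols_vs_prob_summary,
    minimal_seed_set,
    specificity_curve,
)


def hit(q, t, prob, aass=None, cols=30, pval=0.5):
    return AlignmentHit(
        query_id=q, target_id=t, score=10.0, score_ss=0.0, cols=cols,
        ss_sim=0.0, prob_ss=prob, score_aass=aass if aass is not None else -prob,
        pval=pval, evalue=pval,
    )


class TestFamilyGraph:
    def test_strong_edges_by_threshold(self):
        hits = [hit("A", "B", 90), hit("B", "C", 86), hit("D", "E", 84)]
        g = build_family_graph(hits)
        assert [(a, b) for a, b, _ in g.strong_edges] == [("A", "B"), ("B", "C")]
        assert clan_groups(g) == [["A", "B", "C"], ["D"], ["E"]]

    def test_weak_edge_requires_clean_list_above(self):
        # in A's list the borderline hit ranks above the first negative
        hits_a = [hit("A", "F", 70, aass=-70), hit("A", "X", 40, aass=-40)]
        truth = {("A", "F"): True, ("A", "X"): False}
        g = build_family_graph(hits_a, truth=truth)
        assert [(a, b) for a, b, _ in g.weak_edges] == [("A", "F")]

        # same band, but a known negative ranks above it
        hits_b = [hit("A", "X", 80, aass=-80), hit("A", "G", 70, aass=-70)]
        truth_b = {("A", "X"): False, ("A", "G"): True}
        g2 = build_family_graph(hits_b, truth=truth_b)
        assert g2.weak_edges == []

    def test_without_truth_band_only_and_flagged(self):
        g = build_family_graph([hit("A", "F", 70)])
        assert g.curated is False
        assert [(a, b) for a, b, _ in g.weak_edges] == [("A", "F")]

    def test_no_self_edges(self):
        g = build_family_graph([hit("A", "A", 99)])
        assert g.strong_edges == [] and g.weak_edges == []


class TestClanGroups:
    def test_empty_edges_give_singletons(self):
        hits = [hit("A", "B", 10), hit("C", "D", 20)]
        g = build_family_graph(hits)
        assert clan_groups(g) == [["A"], ["B"], ["C"], ["D"]]

    def test_partition_property_and_monotone_merging(self):
        rng = np.random.default_rng(4)
        nodes = [f"N{i}" for i in range(12)]
        hits = [
            hit(a, b, float(rng.uniform(0, 100)))
            for a in nodes for b in nodes if a != b and rng.random() < 0.3
        ]
        g_lo = build_family_graph(hits, strong_min=95)
        g_hi = build_family_graph(hits, strong_min=60)
        for g in (g_lo, g_hi):
            comps = clan_groups(g)
            flat = [n for c in comps for n in c]
            assert sorted(flat) == sorted(g.nodes)
        assert len(clan_groups(g_hi)) <= len(clan_groups(g_lo))

    def test_weak_edges_merge_only_when_requested(self):
        hits = [hit("A", "B", 70)]
        g = build_family_graph(hits)
        assert clan_groups(g, use_weak=False) == [["A"], ["B"]]
        assert clan_groups(g, use_weak=True) == [["A", "B"]]


class TestMinimalSeedSet:
    def test_identity_matrix_needs_all_seeds(self):
        m = DetectionMatrix(["s1", "s2", "s3"], ["d1", "d2", "d3"], np.eye(3))
        assert minimal_seed_set(m) == ["s1", "s2", "s3"]

    def test_greedy_matches_exact_optimum(self):
        det = np.array(
            [[1, 1, 0], [0, 1, 1], [0, 0, 1]], dtype=bool
        )
        m = DetectionMatrix(["s1", "s2", "s3"], ["d1", "d2", "d3"], det)
        greedy = minimal_seed_set(m)
        exact = minimal_seed_set(m, exact=True)
        assert greedy == ["s1", "s2"]
        assert len(exact) == 2

    def test_universal_seed_wins(self):
        det = np.array([[1, 1, 1], [1, 0, 0]], dtype=bool)
        m = DetectionMatrix(["all", "one"], ["d1", "d2", "d3"], det)
        assert minimal_seed_set(m) == ["all"]

    def test_infeasible_reports_uncoverable(self):
        det = np.array([[1, 0], [1, 0]], dtype=bool)
        m = DetectionMatrix(["s1", "s2"], ["d1", "d2"], det)
        with pytest.raises(ValueError, match="d2"):
            minimal_seed_set(m)

    def test_greedy_within_log_bound_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            det = rng.random((6, 10)) < 0.4
            det[:, ~det.any(axis=0)] = True   # make feasible
            m = DetectionMatrix(
                [f"s{i}" for i in range(6)],
                [f"d{j}" for j in range(10)],
                det,
            )
            greedy = minimal_seed_set(m)
            exact = minimal_seed_set(m, exact=True)
            bound = len(exact) * (1 + np.log(det.sum(axis=1).max()))
            assert len(greedy) <= bound


class TestBenchmarkCurves:
    def test_all_true_hits_have_zero_observed_rate(self):
        hits = [hit("q", f"t{i}", float(p)) for i, p in enumerate(
            np.linspace(6, 99, 30)
        )]
        truth = {(h.query_id, h.target_id): True for h in hits}
        df = specificity_curve(hits, truth)
        observed = df.loc[df.n > 0, "observed_false_rate"]
        assert (observed == 0).all()
        assert df.n.sum() == len(hits)

    def test_single_negative_rate(self):
        hits = [hit("q", f"t{i}", 62.0) for i in range(10)]
        truth = {(h.query_id, h.target_id): i != 0 for i, h in enumerate(hits)}
        df = specificity_curve(hits, truth)
        row = df[(df.prob_lo == 60) & (df.prob_hi == 65)].iloc[0]
        assert row.n == 10 and row.observed_false_rate == pytest.approx(0.1)
        assert df.attrs["max_negative_prob"] == pytest.approx(62.0)

    def test_missing_truth_label_rejected(self):
        with pytest.raises(ValueError, match="truth"):
            specificity_curve([hit("q", "t", 50)], {})

    def test_cols_summary_single_true(self):
        hits = [hit("q", "t", 90.0, cols=30)]
        trues, falses = cols_vs_prob_summary(
            hits, {("q", "t"): True}
        )
        assert trues.iloc[0].to_dict() == {
            "centile": 90, "mean_cols": 30.0, "n": 1,
        }
        assert falses.empty

    def test_cols_summary_matches_hand_aggregation(self):
        rng = np.random.default_rng(10)
        hits, truth = [], {}
        for i in range(100):
            p = float(rng.uniform(50, 100))
            c = int(rng.integers(6, 80))
            h = hit("q", f"t{i}", p, cols=c)
            hits.append(h)
            truth[("q", f"t{i}")] = bool(rng.random() < 0.8)
        trues, falses = cols_vs_prob_summary(hits, truth)
        # independent aggregation with plain dicts
        agg = {}
        for h in hits:
            if truth[(h.query_id, h.target_id)]:
                agg.setdefault(int(np.floor(h.prob_ss)), []).append(h.cols)
        for _, row in trues.iterrows():
            assert row["mean_cols"] == pytest.approx(
                np.mean(agg[int(row["centile"])])
            )
            assert row["n"] == len(agg[int(row["centile"])])
        assert len(falses) == sum(not v for v in truth.values())
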