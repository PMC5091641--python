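import math

import numpy as np
import pytest

from clanseeker import (
    ScoringParams,
    align_local,
    co_emission_score,
    read_hit_table,
    score_aass,
    sort_hits,
    ss_agreement_score,
    write_hit_table,
)
from clanseeker.align import pair_score_matrices
from clanseeker.profile import ProfileColumn
from conftest import UNIFORM_BG, pure_profile

from oracle import oracle_local_score, random_profile


def col(freqs=None, aa=None, ss="C", conf=0):
    if aa is not None:
        f = np.zeros(20)
        f["ACDEFGHIKLMNPQRSTVWY".index(aa)] = 1.0
    else:
        f = np.asarray(freqs)
    return ProfileColumn(freqs=f, ss_state=ss, ss_conf=conf)


class TestCoEmission:
    def test_matched_pure_columns(self):
        c = col(aa="A")
        assert co_emission_score(c, c, UNIFORM_BG) == pytest.approx(
            math.log2(20)
        )

    def test_uniform_columns_score_zero(self):
        c = col(freqs=UNIFORM_BG)
        assert co_emission_score(c, c, UNIFORM_BG) == pytest.approx(0.0)

    def test_half_matched_column(self):
        a = col(aa="A")
        f = np.zeros(20)
        f[0] = f[1] = 0.5
        assert co_emission_score(a, col(freqs=f), UNIFORM_BG) == pytest.approx(
            math.log2(10)
        )

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = col(freqs=rng.dirichlet(np.ones(20)))
            b = col(freqs=rng.dirichlet(np.ones(20)))
            assert co_emission_score(a, b, UNIFORM_BG) == pytest.approx(
                co_emission_score(b, a, UNIFORM_BG)
            )

    def test_disjoint_pure_columns_without_pseudocounts(self):
        s = co_emission_score(col(aa="A"), col(aa="C"), UNIFORM_BG)
        assert s == float("-inf")


class TestSsAgreement:
    @pytest.mark.parametrize(
        "q, t, expected",
        [
            (("E", 9), ("E", 9), 1.0),
            (("E", 9), ("H", 9), -2.0),
            (("E", 6), ("E", 3), (6 / 9) * (3 / 9)),
            (("C", 9), ("E", 9), 0.0),
            (("H", 9), ("C", 9), 0.0),
        ],
    )
    def test_base_matrix_and_confidence_scaling(self, q, t, expected):
        a = col(aa="A", ss=q[0], conf=q[1])
        b = col(aa="A", ss=t[0], conf=t[1])
        assert ss_agreement_score(a, b) == pytest.approx(expected, abs=1e-4)


class TestAlignLocal:
    def test_self_alignment_of_distinct_pure_columns(self, uniform_params):
        p = pure_profile("ACDEFGHIKL")
        params = ScoringParams(lamda=0.0, background=UNIFORM_BG.copy())
        h = align_local(p, p, params)
        assert h.cols == 10
        assert h.score == pytest.approx(10 * math.log2(20))
        assert h.pairs == [(i, i) for i in range(1, 11)]
        assert h.q_aln == h.t_aln == "ACDEFGHIKL"

    def test_matches_enumeration_oracle_on_small_profiles(self):
        rng = np.random.default_rng(123)
        params = ScoringParams(background=UNIFORM_BG.copy())
        for k in range(100):
            n, m = rng.integers(1, 6, size=2)
            q = random_profile(rng, int(n), "q")
            t = random_profile(rng, int(m), "t")
            saa, sss = pair_score_matrices(q, t, params)
            S = saa + params.lamda * sss
            expected = oracle_local_score(S, params.gap_open, params.gap_extend)
            got = align_local(q, t, params).score
            assert got == pytest.approx(expected, abs=1e-9), f"pair {k}"

    def test_ss_weight_adds_lamda_per_column_on_fixed_path(self):
        ss = [("E", 9)] * 10
        p = pure_profile("ACDEFGHIKL", ss=ss)
        base = ScoringParams(lamda=0.0, background=UNIFORM_BG.copy())
        weighted = ScoringParams(lamda=0.11, background=UNIFORM_BG.copy())
        h0 = align_local(p, p, base)
        h1 = align_local(p, p, weighted)
        assert h1.pairs == h0.pairs
        assert h1.score - h0.score == pytest.approx(0.11 * h0.cols)
        assert h1.score_ss == pytest.approx(10.0)
        assert h1.ss_sim == pytest.approx(1.0)

    def test_symmetry_with_mirrored_pairs(self):
        rng = np.random.default_rng(77)
        params = ScoringParams(background=UNIFORM_BG.copy())
        for _ in range(30):
            q = random_profile(rng, int(rng.integers(3, 12)), "q")
            t = random_profile(rng, int(rng.integers(3, 12)), "t")
            h_qt = align_local(q, t, params)
            h_tq = align_local(t, q, params)
            assert h_qt.score == pytest.approx(h_tq.score, abs=1e-9)
            assert h_qt.cols == h_tq.cols
            assert [(j, i) for i, j in h_qt.pairs] == h_tq.pairs

    def test_zero_lamda_equals_all_loop_states(self):
        rng = np.random.default_rng(9)
        q = random_profile(rng, 8, "q")
        t = random_profile(rng, 8, "t")
        q_c, t_c = q.strip_ss(), t.strip_ss()
        params0 = ScoringParams(lamda=0.0, background=UNIFORM_BG.copy())
        params = ScoringParams(lamda=0.11, background=UNIFORM_BG.copy())
        assert align_local(q, t, params0).score == pytest.approx(
            align_local(q_c, t_c, params).score
        )


class TestScoreAass:
    def test_printed_formula_capped(self):
        v = score_aass(-20.0, math.exp(-20), 8.0, 5.0, 0.11, True)
        assert v == pytest.approx(-47.444, abs=1e-3)

    def test_printed_formula_uncapped(self):
        v = score_aass(-20.0, math.exp(-20), 8.0, 5.0, 0.11, False)
        assert v == pytest.approx(-48.667, abs=1e-3)

    def test_second_branch_near_null(self):
        v = score_aass(math.log(0.5), 0.5, 10.0, 0.0, 0.11, True)
        assert v == pytest.approx(-3.8145, abs=1e-3)

    def test_domain_error_at_pval_one(self):
        with pytest.raises(ValueError):
            score_aass(0.0, 1.0, 10.0, 0.0, 0.11, True)

    def test_cap_property_on_random_tuples(self):
        rng = np.random.default_rng(2024)
        for _ in range(10_000):
            logp = -float(rng.uniform(0, 40))
            score = float(rng.uniform(-10, 100))
            score_ss = float(rng.uniform(-30, 60))
            lamda = float(rng.choice([0.0, 0.11, 0.3]))
            capped = score_aass(logp, math.exp(logp), score, score_ss, lamda, True)
            uncapped = score_aass(logp, math.exp(logp), score, score_ss, lamda, False)
            assert uncapped <= capped + 1e-12
            equal = abs(uncapped - capped) < 1e-12
            cond = lamda * score_ss <= max(0.0, 0.2 * (score - 8.0)) + 1e-12
            assert equal == cond


class TestHitTables:
    def test_round_trip_and_sort_order(self, tmp_path):
        rng = np.random.default_rng(3)
        params = ScoringParams(background=UNIFORM_BG.copy())
        hits = []
        for i in range(5):
            q = random_profile(rng, 10, f"q{i}")
            t = random_profile(rng, 10, f"t{i}")
            h = align_local(q, t, params)
            h.pval, h.logPval = 0.5, math.log(0.5)
            h.evalue, h.prob_ss = 2.5, float(rng.uniform(0, 100))
            h.score_aass = float(rng.normal())
            hits.append(h)
        path = tmp_path / "hits.tsv"
        write_hit_table(hits, path)
        again = read_hit_table(path)
        aass = [h.score_aass for h in again]
        assert aass == sorted(aass)
        by_id = {(h.query_id, h.target_id): h for h in again}
        for h in hits:
            g = by_id[(h.query_id, h.target_id)]
            assert g.score == pytest.approx(h.score, abs=1e-4)
            assert g.cols == h.cols
            assert g.q_aln == h.q_aln
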