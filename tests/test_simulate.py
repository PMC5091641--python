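import numpy as np
import pytest

from clanseeker import (
    ClanSpec,
    build_clan,
    build_contaminated_construct,
    evolve_domain,
    evolve_sequence,
    fold_template,
    sample_ancestor,
)
from clanseeker.msa import GAP_CHARS

UNIFORM = np.full(20, 0.05)


class TestAncestor:
    def test_template_shape(self):
        t = fold_template(110)
        assert len(t) == 110
        assert t.count("H") >= 8
        # seven strand blocks
        import re
        assert len(re.findall(r"E+", t)) == 7
        assert t.rstrip("C").endswith("H")

    def test_length_and_determinism(self):
        spec = ClanSpec(domain_len_range=(100, 100), seed=0)
        a1 = sample_ancestor(spec, np.random.default_rng(0))
        a2 = sample_ancestor(spec, np.random.default_rng(0))
        assert len(a1[0]) == 100
        assert a1[0] == a2[0] and a1[1] == a2[1]
        assert np.array_equal(a1[2], a2[2])

    def test_structured_positions_have_high_confidence(self):
        spec = ClanSpec(seed=1)
        seq, states, conf = sample_ancestor(spec, np.random.default_rng(1))
        for s, c in zip(states, conf):
            if s in "EH":
                assert c >= 7
            else:
                assert c <= 4


class TestEvolution:
    def test_zero_divergence_is_identity(self):
        rng = np.random.default_rng(0)
        child = evolve_sequence("ACDEFGHIKL" * 5, 0.0, rng)
        assert child == "ACDEFGHIKL" * 5

    def test_identity_decay_matches_closed_form(self):
        # with no indels and no loop acceleration, P(site unchanged after
        # Poisson(d) exclusion-substitutions) has a closed form; at small d
        # it is ~exp(-d), at large d it approaches the background collision
        # rate.  Checked by Monte-Carlo at d -> infinity with uniform
        # background: stationary identity = 1/20.
        rng = np.random.default_rng(42)
        n = 10_000
        parent = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        child = evolve_sequence(
            parent, 30.0, rng, ss="E" * n, loop_rate=1.0, background=UNIFORM
        )
        ident = sum(a == b for a, b in zip(parent, child)) / n
        p = 1 / 20
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(ident - p) < 3 * sigma

    def test_small_divergence_changes_about_one_minus_exp(self):
        rng = np.random.default_rng(7)
        n, d = 10_000, 0.3
        parent = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        child = evolve_sequence(
            parent, d, rng, ss="E" * n, loop_rate=1.0, background=UNIFORM
        )
        ident = sum(a == b for a, b in zip(parent, child)) / n
        # P(unchanged) >= exp(-d); back-substitutions add a little
        expected = np.exp(-d)
        assert abs(ident - expected) < 0.02

    def test_seeded_reproducibility(self):
        parent = "ACDEFGHIKL" * 10
        c1 = evolve_sequence(parent, 0.8, np.random.default_rng(3))
        c2 = evolve_sequence(parent, 0.8, np.random.default_rng(3))
        assert c1 == c2

    def test_strand_helix_sites_never_deleted(self):
        rng = np.random.default_rng(11)
        states = "E" * 50 + "C" * 50
        conf = np.full(100, 8, dtype=np.int8)
        for _ in range(20):
            d = evolve_domain("A" * 100, states, conf, 0.5, rng,
                              indel_rate=0.3)
            assert all(d.match[i] is not None for i in range(50))

    def test_negative_divergence_rejected(self):
        with pytest.raises(ValueError):
            evolve_sequence("ACD", -1.0, np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_clan():
    return build_clan(ClanSpec(n_families=3, members_per_family=5, seed=0))


class TestBuildClan:

    def test_truth_row_counts(self, small_clan):
        truth = small_clan.truth
        domains = truth[~truth.is_decoy]
        assert len(domains) == 15
        assert domains.groupby("family_id").size().to_dict() == {
            "F0": 5, "F1": 5, "F2": 5,
        }
        assert (domains.clan_id == "clan0").all()
        decoys = truth[truth.is_decoy]
        assert len(decoys) == 30   # 2x domain-bearing count

    def test_truth_coordinates_index_real_residues(self, small_clan):
        hosts = {m.host_id: m.host_seq for m in small_clan.members}
        for _, row in small_clan.truth[~small_clan.truth.is_decoy].iterrows():
            seq = hosts[row.protein_id]
            assert 1 <= row.start <= row.end <= len(seq)
            member = next(
                m for m in small_clan.members if m.member_id == row.region_id
            )
            assert seq[row.start - 1 : row.end] == member.domain.seq

    def test_divergence_ordering(self, small_clan):
        """Mean pairwise identity: within family > between families."""
        def identity(a, b):
            n = sum(1 for x, y in zip(a, b) if x == y and x not in GAP_CHARS)
            return n / max(len(a), 1)

        within, between = [], []
        fams = small_clan.families
        for fam in fams:
            rows = [
                "".join(r if r else "-" for r in m.domain.match)
                for m in fam.members
            ]
            for i in range(len(rows)):
                for j in range(i + 1, len(rows)):
                    within.append(identity(rows[i], rows[j]))
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                a, b = fams[i].founder_seq, fams[j].founder_seq
                k = min(len(a), len(b))
                between.append(identity(a[:k], b[:k]))
        assert np.mean(within) > np.mean(between)

    def test_structured_columns_more_conserved_than_loops(self, small_clan):
        """E/H columns of family MSAs have lower entropy than C columns -
        the conserved-fold, variable-loop premise."""
        def column_entropy(col):
            col = [c for c in col if c not in GAP_CHARS]
            if not col:
                return 0.0
            _, counts = np.unique(col, return_counts=True)
            p = counts / counts.sum()
            return float(-(p * np.log(p)).sum())

        eh_ent, c_ent = [], []
        for fam in small_clan.families:
            msa = fam.reference_msa()
            for ci, state in enumerate(fam.founder_states):
                column = [row[ci] for _, row in msa.rows]
                (eh_ent if state in "EH" else c_ent).append(
                    column_entropy(column)
                )
        assert np.mean(eh_ent) < np.mean(c_ent)

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        spec = ClanSpec(n_families=2, members_per_family=3, seed=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        build_clan(spec).write(d1)
        build_clan(spec).write(d2)
        for rel in ["hosts.fasta", "decoys.fasta", "truth.tsv", "spec.json"]:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()


class TestContaminatedConstruct:
    def test_donor_rows_cover_less_than_half_of_span(self):
        clan = build_clan(ClanSpec(n_families=2, members_per_family=2, seed=0))
        rng = np.random.default_rng(7000)
        region = "".join(
            rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=180)
        )
        cons = build_contaminated_construct(
            region, clan.families[0], 2, rng
        )
        lo, hi = cons.span
        width = hi - lo + 1
        for name, row in cons.msa.rows[1:]:
            nongap = sum(
                1 for c in row[lo - 1 : hi] if c not in GAP_CHARS
            )
            assert nongap / width < 0.5

    def test_zero_contaminants_is_region_alone(self):
        clan = build_clan(ClanSpec(n_families=2, members_per_family=2, seed=0))
        cons = build_contaminated_construct(
            "A" * 180, clan.families[0], 0, np.random.default_rng(0)
        )
        assert cons.msa.n_rows == 1
        assert cons.span == (0, 0)
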