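import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clanseeker import (
    ChunkPolicy,
    build_profile,
    chunk_protein,
    msa_from_string,
    read_profile,
    write_profile,
)
from clanseeker.profile import ProfileFormatError
from conftest import UNIFORM_BG

from oracle import random_profile


class TestBuildProfile:
    def test_single_row_identity(self):
        msa = msa_from_string(">s\nACD\n")
        p = build_profile(msa, pseudocount_alpha=0.0, background=UNIFORM_BG)
        for i, aa in enumerate("ACD"):
            col = p.column(i + 1)
            assert col.freqs["ACDEFGHIKLMNPQRSTVWY".index(aa)] == 1.0

    def test_equal_counts_split_evenly(self):
        msa = msa_from_string(">a\nA\n>b\nA\n>c\nC\n>d\nC\n")
        p = build_profile(msa, pseudocount_alpha=0.0, background=UNIFORM_BG)
        assert p.freqs[0, 0] == pytest.approx(0.5)   # A
        assert p.freqs[0, 1] == pytest.approx(0.5)   # C

    def test_pseudocount_mixing(self):
        # column {A,A,A,C}, alpha = 1, uniform background:
        # freq(A) = (3 + 0.05) / (4 + 1) = 0.61
        msa = msa_from_string(">a\nA\n>b\nA\n>c\nA\n>d\nC\n")
        p = build_profile(msa, pseudocount_alpha=1.0, background=UNIFORM_BG)
        assert p.freqs[0, 0] == pytest.approx(0.61)

    def test_frequencies_are_convex_combinations(self):
        msa = msa_from_string(">a\nAC\n>b\nAD\n>c\nCD\n")
        p = build_profile(msa, pseudocount_alpha=2.0, background=UNIFORM_BG)
        counts = {"A": 2 / 3, "C": 1 / 3}
        for aa_i in range(20):
            emp = {0: 2 / 3, 1: 1 / 3}.get(aa_i, 0.0)
            lo, hi = min(emp, 0.05), max(emp, 0.05)
            assert lo - 1e-12 <= p.freqs[0, aa_i] <= hi + 1e-12

    def test_absent_ss_means_loop_zero_conf(self):
        msa = msa_from_string(">s\nACD\n")
        p = build_profile(msa, background=UNIFORM_BG)
        assert all(p.column(i + 1).ss_state == "C" for i in range(3))
        assert all(p.column(i + 1).ss_conf == 0 for i in range(3))

    def test_ss_length_mismatch_errors(self):
        msa = msa_from_string(">s\nACD\n")
        with pytest.raises(ValueError, match="match columns"):
            build_profile(msa, ss=[("H", 9)], background=UNIFORM_BG)


class TestChunking:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (150, [(1, 150)]),
            (300, [(1, 200), (101, 300)]),
            (482, [(1, 200), (101, 300), (201, 400), (283, 482)]),
        ],
    )
    def test_window_layout(self, length, expected):
        chunks = chunk_protein("A" * length)
        assert [(c.start, c.end) for c in chunks] == expected

    @given(st.integers(min_value=1, max_value=3000))
    @settings(max_examples=200, deadline=None)
    def test_full_coverage_and_overlap(self, length):
        policy = ChunkPolicy()
        chunks = chunk_protein("A" * length, policy)
        covered = set()
        for c in chunks:
            covered.update(range(c.start, c.end + 1))
        assert covered == set(range(1, length + 1))
        if length >= policy.chunk_size:
            assert all(
                c.end - c.start + 1 == policy.chunk_size for c in chunks
            )
        regular = chunks[:-1] if chunks[-1].start % policy.step != 1 else chunks
        for a, b in zip(regular, regular[1:]):
            assert a.end - b.start + 1 == policy.chunk_size - policy.step

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            chunk_protein("")


class TestPhmmFormat:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(42)
        p = random_profile(rng, 7, id="rt")
        path = tmp_path / "p.phmm"
        write_profile(p, path)
        q = read_profile(path)
        assert q.id == p.id
        assert q.source == p.source
        assert q.n_seqs == p.n_seqs
        assert np.abs(q.freqs - p.freqs).max() < 1e-9
        assert np.array_equal(q.ss, p.ss)
        assert np.array_equal(q.ss_conf, p.ss_conf)

    def test_version_mismatch(self, tmp_path):
        path = tmp_path / "bad.phmm"
        path.write_text("#PHMM/2\n")
        with pytest.raises(ProfileFormatError, match="PHMM/1"):
            read_profile(path)

    def test_truncated_row_reports_line(self, tmp_path):
        rng = np.random.default_rng(1)
        p = random_profile(rng, 3, id="t")
        path = tmp_path / "p.phmm"
        write_profile(p, path)
        lines = path.read_text().splitlines()
        lines[6] = "\t".join(lines[6].split("\t")[:5])
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ProfileFormatError, match=":7"):
            read_profile(path)
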