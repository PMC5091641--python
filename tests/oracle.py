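"""Independent brute-force oracles used by the alignment tests.

The local-alignment oracle enumerates every non-empty local alignment (all
equal-length increasing index subsequences of query and target columns) and
charges affine penalties for the gaps between consecutive aligned pairs -
independent of the dynamic-programming recurrences it checks.
"""

from itertools import combinations

import numpy as np

from clanseeker.profile import ProfileHMM


def affine_gap(d: int, gap_open: float, gap_extend: float) -> float:
    return 0.0 if d == 0 else gap_open + (d - 1) * gap_extend


def oracle_local_score(S: np.ndarray, gap_open: float, gap_extend: float) -> float:
    """Best score over all non-empty local alignments with affine gaps."""
    n, m = S.shape
    best = -np.inf
    for k in range(1, min(n, m) + 1):
        for qi in combinations(range(n), k):
            for tj in combinations(range(m), k):
                s = 0.0
                for x in range(k):
                    s += S[qi[x], tj[x]]
                    if x:
                        s += affine_gap(qi[x] - qi[x - 1] - 1, gap_open, gap_extend)
                        s += affine_gap(tj[x] - tj[x - 1] - 1, gap_open, gap_extend)
                best = max(best, s)
    return best


def random_profile(
    rng: np.random.Generator, n_cols: int, id: str = "p"
) -> ProfileHMM:
    """Random pseudocount-free profile with random SS annotation."""
    freqs = rng.dirichlet(np.full(20, 0.5), size=n_cols)
    return ProfileHMM(
        id=id,
        freqs=freqs,
        ss=rng.integers(0, 3, size=n_cols),
        ss_conf=rng.integers(0, 10, size=n_cols),
        gap_fraction=np.zeros(n_cols),
        source=(id, 1, n_cols),
        n_seqs=1,
    )
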