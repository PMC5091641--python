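"""Profile-profile scoring and local alignment with a secondary-structure
weight, plus the combined ranking score used to order hit lists.

The per-cell score for aligning query column i to target column j is

    S(i, j) = S_aa(i, j) + lamda * S_ss(i, j)

where S_aa is the log2 co-emission odds ratio of the two frequency columns
against the background, and S_ss scores agreement of the predicted 3-state
secondary structure, scaled by both confidences.  lamda defaults to 0.11 so
that sequence information dominates; raising it (e.g. to 0.30) weights shared
fold more heavily, which helps when sequences have diverged past direct
detectability.

The ranking score (``score_aass``, lower = stronger) mixes a log P-value term
with the secondary-structure contribution.  The original form caps the SS
contribution at 0.2*(score-8) bits; the modified form removes the cap so that
structure can carry an alignment whose raw sequence score is modest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._dp import gotoh_local, traceback
from .alphabet import ROBINSON_BACKGROUND, SS_INDEX
from .profile import ProfileColumn, ProfileHMM

NEG_INF = float("-inf")


def _default_background() -> np.ndarray:
    return ROBINSON_BACKGROUND.copy()


@dataclass
class ScoringParams:
    """Engine knobs: SS weight, cap behaviour, affine gap penalties (bits)."""

    lamda: float = 0.11
    ss_cap_enabled: bool = True
    gap_open: float = -3.0
    gap_extend: float = -0.5
    background: np.ndarray = field(default_factory=_default_background)
    ss_match: float = 1.0       # H/H and E/E
    ss_mismatch: float = -2.0   # H/E confusion

    def __post_init__(self) -> None:
        if self.lamda < 0:
            raise ValueError("lamda must be >= 0")
        if not self.gap_open <= self.gap_extend <= 0:
            raise ValueError("require gap_open <= gap_extend <= 0")
        self.background = np.asarray(self.background, dtype=float)

    def ss_matrix(self) -> np.ndarray:
        """3x3 base agreement matrix over (H, E, C) state codes."""
        m = np.zeros((3, 3))
        h, e = SS_INDEX["H"], SS_INDEX["E"]
        m[h, h] = m[e, e] = self.ss_match
        m[h, e] = m[e, h] = self.ss_mismatch
        return m


@dataclass
class AlignmentHit:
    """One query-target local alignment with scores and, once calibrated,
    P-value / E-value and the shared-structure probability prob[SS]."""

    query_id: str
    target_id: str
    score: float                 # sequence+SS DP score, bits
    score_ss: float              # summed SS agreement over aligned columns
    cols: int                    # aligned match-column count (COLs)
    ss_sim: float                # mean per-column SS agreement (2Ssim)
    q_start: int = 0
    q_end: int = 0
    t_start: int = 0
    t_end: int = 0
    pairs: list[tuple[int, int]] = field(default_factory=list)
    q_aln: str = ""
    t_aln: str = ""
    score_aass: float | None = None
    pval: float | None = None
    logPval: float | None = None
    evalue: float | None = None
    prob_ss: float | None = None

    def __post_init__(self) -> None:
        if self.pairs and self.cols != len(self.pairs):
            raise ValueError("cols must equal number of aligned pairs")
        if self.prob_ss is not None and not 0 <= self.prob_ss <= 100:
            raise ValueError("prob_ss must be in [0, 100]")


def co_emission_score(
    cq: ProfileColumn, ct: ProfileColumn, background: np.ndarray | None = None
) -> float:
    """log2 odds that the two columns emit the same residue, vs background.

    S_aa = log2( sum_a cq_a * ct_a / bg_a ).  Symmetric.  Returns -inf when
    the sum vanishes (possible only with zero pseudocounts).
    """
    bg = ROBINSON_BACKGROUND if background is None else np.asarray(background)
    s = float(np.sum(cq.freqs * ct.freqs / bg))
    if s <= 0.0:
        return NEG_INF
    return math.log2(s)


def ss_agreement_score(
    cq: ProfileColumn,
    ct: ProfileColumn,
    params: ScoringParams | None = None,
) -> float:
    """Secondary-structure agreement in [-2, 1].

    +1 for H/H or E/E, -2 for H/E confusion, 0 when either state is loop,
    scaled multiplicatively by the two confidences (conf/9 each).
    """
    p = params or ScoringParams()
    m = p.ss_matrix()
    base = m[SS_INDEX[cq.ss_state], SS_INDEX[ct.ss_state]]
    return float(base * (cq.ss_conf / 9.0) * (ct.ss_conf / 9.0))


def pair_score_matrices(
    q: ProfileHMM, t: ProfileHMM, params: ScoringParams
) -> tuple[np.ndarray, np.ndarray]:
    """(S_aa, S_ss) matrices over all query x target column pairs."""
    bg = params.background
    with np.errstate(divide="ignore"):
        saa = np.log2(q.freqs @ (t.freqs / bg).T)
    # zero co-emission (possible only with alpha = 0) -> large finite penalty
    saa[~np.isfinite(saa)] = -1e15
    m = params.ss_matrix()
    sss = (
        m[q.ss[:, None], t.ss[None, :]]
        * (q.ss_conf[:, None] / 9.0)
        * (t.ss_conf[None, :] / 9.0)
    )
    return saa, sss


def align_local(
    q: ProfileHMM, t: ProfileHMM, params: ScoringParams | None = None
) -> AlignmentHit:
    """Smith-Waterman local alignment of two profiles with affine gaps.

    Per-cell score S_aa + lamda * S_ss; gap_open on opening and gap_extend per
    extension; deterministic traceback (tie order diagonal > up > left).  The
    returned hit is uncalibrated (no P-value / prob[SS]); `score` is the best
    DP cell, `score_ss` the summed SS agreement over the aligned pairs.
    """
    params = params or ScoringParams()
    saa, sss = pair_score_matrices(q, t, params)
    S = saa + params.lamda * sss
    best, bi, bj, pM, pX, pY = gotoh_local(
        np.ascontiguousarray(S), params.gap_open, params.gap_extend
    )
    pairs = traceback(bi, bj, pM, pX, pY)
    cols = len(pairs)
    score_ss = float(sum(sss[i - 1, j - 1] for i, j in pairs))
    ss_sim = score_ss / cols if cols else 0.0
    q_aln, t_aln = _alignment_strings(q, t, pairs)
    return AlignmentHit(
        query_id=q.id,
        target_id=t.id,
        score=float(best),
        score_ss=score_ss,
        cols=cols,
        ss_sim=ss_sim,
        q_start=pairs[0][0] if pairs else 0,
        q_end=pairs[-1][0] if pairs else 0,
        t_start=pairs[0][1] if pairs else 0,
        t_end=pairs[-1][1] if pairs else 0,
        pairs=pairs,
        q_aln=q_aln,
        t_aln=t_aln,
    )


def _alignment_strings(
    q: ProfileHMM, t: ProfileHMM, pairs: list[tuple[int, int]]
) -> tuple[str, str]:
    if not pairs:
        return "", ""
    qc, tc = q.consensus(), t.consensus()
    qa, ta = [], []
    pi, pj = pairs[0]
    qa.append(qc[pi - 1])
    ta.append(tc[pj - 1])
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        for i in range(i0 + 1, i1):
            qa.append(qc[i - 1])
            ta.append("-")
        for j in range(j0 + 1, j1):
            qa.append("-")
            ta.append(tc[j - 1])
        qa.append(qc[i1 - 1])
        ta.append(tc[j1 - 1])
    return "".join(qa), "".join(ta)


def score_aass(
    logPval: float,
    pval: float,
    score: float,
    score_ss: float,
    lamda: float = 0.11,
    ss_cap_enabled: bool = True,
) -> float:
    """Combined ranking score; lower = stronger hit.

    base = logPval if logPval < -10 else ln(-ln(1 - pval))

    capped:   base/0.45 - min(lamda*score_ss, max(0, 0.2*(score-8)))/0.45 - 3
    uncapped: base/0.45 - lamda*score_ss/0.45 - 3
    """
    if logPval < -10.0:
        base = logPval
    else:
        inner = -math.log1p(-pval) if pval < 1.0 else 0.0
        if inner <= 0.0:
            raise ValueError(
                "score_aass undefined: pval >= 1 with logPval >= -10"
            )
        base = math.log(inner)
    if ss_cap_enabled:
        ss_term = min(lamda * score_ss, max(0.0, 0.2 * (score - 8.0)))
    else:
        ss_term = lamda * score_ss
    return base / 0.45 - ss_term / 0.45 - 3.0


# ---------------------------------------------------------------------------
# Hit tables

HIT_COLUMNS = [
    "query_id", "target_id", "prob_ss", "evalue", "pval", "score",
    "score_ss", "score_aass", "cols", "ss_sim",
    "q_start", "q_end", "t_start", "t_end", "q_aln", "t_aln",
]


def sort_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Ascending score_aass (strongest first), ties by target id."""
    key = lambda h: (
        h.score_aass if h.score_aass is not None else float("inf"),
        h.target_id,
    )
    return sorted(hits, key=key)


def write_hit_table(hits: list[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in sort_hits(hits):
            row = [
                h.query_id, h.target_id,
                _fmt(h.prob_ss, "{:.2f}"), _fmt(h.evalue, "{:.4g}"),
                _fmt(h.pval, "{:.6g}"), f"{h.score:.4f}",
                f"{h.score_ss:.4f}", _fmt(h.score_aass, "{:.4f}"),
                str(h.cols), f"{h.ss_sim:.4f}",
                str(h.q_start), str(h.q_end), str(h.t_start), str(h.t_end),
                h.q_aln, h.t_aln,
            ]
            fh.write("\t".join(row) + "\n")


def read_hit_table(path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != HIT_COLUMNS:
            raise ValueError(f"{path}: unexpected hit-table header")
        for line in fh:
            f = dict(zip(HIT_COLUMNS, line.rstrip("\n").split("\t")))
            hits.append(
                AlignmentHit(
                    query_id=f["query_id"], target_id=f["target_id"],
                    score=float(f["score"]), score_ss=float(f["score_ss"]),
                    cols=int(f["cols"]), ss_sim=float(f["ss_sim"]),
                    q_start=int(f["q_start"]), q_end=int(f["q_end"]),
                    t_start=int(f["t_start"]), t_end=int(f["t_end"]),
                    q_aln=f["q_aln"], t_aln=f["t_aln"],
                    prob_ss=_parse(f["prob_ss"]), evalue=_parse(f["evalue"]),
                    pval=_parse(f["pval"]), score_aass=_parse(f["score_aass"]),
                )
            )
    return hits


def _fmt(v, spec: str) -> str:
    return "NA" if v is None else spec.format(v)


def _parse(s: str) -> float | None:
    return None if s == "NA" else float(s)
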