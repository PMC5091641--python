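"""Family graph construction, clan grouping, minimal seed sets, and the
specificity / alignment-length benchmark summaries.

Families become nodes; a strong edge joins two families that hit each other
with prob[SS] at or above the strong threshold (default 85%), and weak edges
record borderline hits (default band 50-85%) that rank above any known false
positive in their hit list.  Connected components over strong (optionally
plus weak) edges are the clan groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .align import AlignmentHit


@dataclass
class FamilyGraph:
    nodes: set[str] = field(default_factory=set)
    strong_edges: list[tuple[str, str, float]] = field(default_factory=list)
    weak_edges: list[tuple[str, str, str]] = field(default_factory=list)
    curated: bool = True   # False when weak edges were taken by band only

    def to_networkx(self, use_weak: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        for a, b, p in self.strong_edges:
            g.add_edge(a, b, kind="strong", prob_ss=p)
        if use_weak:
            for a, b, ev in self.weak_edges:
                if not g.has_edge(a, b):
                    g.add_edge(a, b, kind="weak", evidence=ev)
        return g

    def write_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\tkind\tprob_ss_or_evidence\n")
            for a, b, p in sorted(self.strong_edges):
                fh.write(f"{a}\t{b}\tstrong\t{p:.2f}\n")
            for a, b, ev in sorted(self.weak_edges):
                fh.write(f"{a}\t{b}\tweak\t{ev}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(use_weak=True), path)


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def build_family_graph(
    hits: list[AlignmentHit],
    strong_min: float = 85.0,
    weak_band: tuple[float, float] = (50.0, 85.0),
    truth: dict[tuple[str, str], bool] | None = None,
) -> FamilyGraph:
    """Classify calibrated hits into strong and weak family edges.

    A single hit at prob[SS] >= strong_min makes a strong edge (mutual hits
    are not required).  A hit inside the weak band makes a weak edge only if
    no known-negative hit ranks above it in its query's hit list; without
    truth labels the band alone is used and the graph is flagged uncurated.
    Self-hits never make edges.
    """
    for h in hits:
        if h.prob_ss is None:
            raise ValueError("hits must be calibrated")
    g = FamilyGraph()
    g.nodes = {h.query_id for h in hits} | {h.target_id for h in hits}
    strong: dict[tuple[str, str], float] = {}
    weak: dict[tuple[str, str], str] = {}
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    for q, lst in by_query.items():
        lst.sort(key=lambda h: (h.score_aass, h.target_id))
        seen_negative = False
        for rank, h in enumerate(lst):
            if h.target_id != q:
                key = _canon(h.query_id, h.target_id)
                if h.prob_ss >= strong_min:
                    strong[key] = max(strong.get(key, 0.0), h.prob_ss)
                elif weak_band[0] <= h.prob_ss < weak_band[1]:
                    if truth is None:
                        clean = True
                    else:
                        # a known-negative hit never makes an edge, and no
                        # negative may rank above the candidate in the list
                        clean = not seen_negative and truth.get(
                            (q, h.target_id), True
                        )
                    if clean and key not in weak:
                        weak[key] = f"{q}:rank{rank + 1}"
            if truth is not None and not truth.get((q, h.target_id), True):
                seen_negative = True
    g.strong_edges = sorted((a, b, p) for (a, b), p in strong.items())
    g.weak_edges = sorted(
        (a, b, ev) for (a, b), ev in weak.items() if (a, b) not in strong
    )
    g.curated = truth is not None
    return g


def clan_groups(g: FamilyGraph, use_weak: bool = False) -> list[list[str]]:
    """Connected components, each sorted, ordered by their representatives."""
    comps = [
        sorted(c) for c in nx.connected_components(g.to_networkx(use_weak))
    ]
    return sorted(comps, key=lambda c: c[0])


@dataclass
class DetectionMatrix:
    """Boolean detects(seed, member) table for seed-set selection."""

    seeds: list[str]
    members: list[str]
    detects: np.ndarray   # (n_seeds, n_members) bool

    def __post_init__(self) -> None:
        self.detects = np.asarray(self.detects, dtype=bool)
        if self.detects.shape != (len(self.seeds), len(self.members)):
            raise ValueError("detects shape mismatch")

    def uncoverable(self) -> list[str]:
        cov = self.detects.any(axis=0)
        return [m for m, ok in zip(self.members, cov) if not ok]


def minimal_seed_set(
    m: DetectionMatrix, exact: bool = False
) -> list[str]:
    """Smallest seed subset detecting every member.

    Greedy set cover (largest uncovered gain, ties lexicographic); optional
    exhaustive mode for small seed counts returns a provably optimal cover.
    """
    missing = m.uncoverable()
    if missing:
        raise ValueError(f"uncoverable members: {missing}")
    n_members = len(m.members)
    if exact:
        if len(m.seeds) > 20:
            raise ValueError("exact mode limited to <= 20 seeds")
        order = sorted(range(len(m.seeds)), key=lambda i: m.seeds[i])
        for size in range(1, len(m.seeds) + 1):
            for combo in combinations(order, size):
                if m.detects[list(combo)].any(axis=0).all():
                    return [m.seeds[i] for i in combo]
        raise AssertionError("unreachable: cover exists")
    covered = np.zeros(n_members, dtype=bool)
    chosen: list[str] = []
    remaining = sorted(range(len(m.seeds)), key=lambda i: m.seeds[i])
    while not covered.all():
        best_i, best_gain = None, -1
        for i in remaining:
            gain = int((m.detects[i] & ~covered).sum())
            if gain > best_gain:
                best_i, best_gain = i, gain
        covered |= m.detects[best_i]
        chosen.append(m.seeds[best_i])
        remaining.remove(best_i)
    return chosen


def specificity_curve(
    hits: list[AlignmentHit],
    truth: dict[tuple[str, str], bool],
    bin_width: float = 5.0,
) -> pd.DataFrame:
    """Observed false-hit rate per prob[SS] bin vs the rate the metric
    predicts (1 - prob/100).

    Bins cover [5, 100]; a row per bin with n = 0 where empty.  The result
    frame carries `max_negative_prob` (highest prob[SS] reached by any known
    negative) as an attribute.
    """
    for h in hits:
        if (h.query_id, h.target_id) not in truth:
            raise ValueError(
                f"truth missing label for ({h.query_id}, {h.target_id})"
            )
    edges = np.arange(5.0, 100.0 + bin_width, bin_width)
    rows = []
    max_neg = float("nan")
    negs = [
        h.prob_ss for h in hits if not truth[(h.query_id, h.target_id)]
    ]
    if negs:
        max_neg = max(negs)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = [
            h for h in hits
            if lo <= h.prob_ss < hi or (hi == edges[-1] and h.prob_ss == hi)
        ]
        n = len(sel)
        n_false = sum(
            1 for h in sel if not truth[(h.query_id, h.target_id)]
        )
        rows.append(
            {
                "prob_lo": lo,
                "prob_hi": hi,
                "predicted_error": 1.0 - (lo + hi) / 200.0,
                "observed_false_rate": n_false / n if n else float("nan"),
                "n": n,
                "n_false": n_false,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["max_negative_prob"] = max_neg
    return df


def cols_vs_prob_summary(
    hits: list[AlignmentHit],
    truth: dict[tuple[str, str], bool],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean aligned length (COLs) per prob[SS] centile for true hits, plus
    the individual (prob, cols) points for false hits."""
    trues, falses = [], []
    for h in hits:
        if (h.query_id, h.target_id) not in truth:
            raise ValueError(
                f"truth missing label for ({h.query_id}, {h.target_id})"
            )
        (trues if truth[(h.query_id, h.target_id)] else falses).append(h)
    if trues:
        tdf = pd.DataFrame(
            {
                "centile": [int(np.floor(h.prob_ss)) for h in trues],
                "cols": [h.cols for h in trues],
            }
        )
        true_summary = (
            tdf.groupby("centile")["cols"]
            .agg(mean_cols="mean", n="count")
            .reset_index()
            .sort_values("centile", ignore_index=True)
        )
    else:
        true_summary = pd.DataFrame(columns=["centile", "mean_cols", "n"])
    false_points = pd.DataFrame(
        {
            "query_id": [h.query_id for h in falses],
            "target_id": [h.target_id for h in falses],
            "prob_ss": [h.prob_ss for h in falses],
            "cols": [h.cols for h in falses],
        }
    )
    return true_summary, false_points
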