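"""Search orchestration: library search, thresholded filtering, bidirectional
search, domain-only confirmation and transitive linking.

The pipeline order is fixed: build -> search -> filter -> confirm ->
(optional) transitive -> graph.  Filtering keeps hits with prob[SS] >=
prob_min (default 85%, the near-100%-specificity threshold) and at least
cols_min aligned columns (default 20; shorter hits are typically to a single
structural element).  Confirmation re-aligns just the candidate window of the
query MSA (plus a few flanking columns) against the reference domain, with
secondary-structure annotation removed - the step that eliminates
whole-protein MSA-contamination false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignmentHit, ScoringParams, align_local, sort_hits
from .calibrate import CalibrationModel, calibrate_hit
from .msa import GAP_CHARS, Msa
from .profile import ProfileHMM, build_profile


@dataclass(frozen=True)
class FilterPolicy:
    prob_min: float = 85.0   # percent
    cols_min: int = 20

    def __post_init__(self) -> None:
        if not 0 <= self.prob_min <= 100:
            raise ValueError("prob_min must be in [0, 100]")
        if self.cols_min < 0:
            raise ValueError("cols_min must be >= 0")

    def passes(self, h: AlignmentHit) -> bool:
        if h.prob_ss is None:
            raise ValueError("hit is not calibrated")
        return h.prob_ss >= self.prob_min and h.cols >= self.cols_min


@dataclass
class SearchResult:
    query_id: str
    hits: list[AlignmentHit]
    library_id: str = ""
    params: dict = field(default_factory=dict)


@dataclass
class TransitiveLink:
    query_id: str
    target_id: str
    intermediate_id: str
    leg1: AlignmentHit   # query -> intermediate
    leg2: AlignmentHit   # intermediate -> known target
    combined_prob: float

    def __post_init__(self) -> None:
        expected = min(self.leg1.prob_ss, self.leg2.prob_ss)
        if abs(self.combined_prob - expected) > 1e-9:
            raise ValueError("combined_prob must be min of the leg probs")


def _params_snapshot(params: ScoringParams) -> dict:
    return {
        "lamda": params.lamda,
        "ss_cap_enabled": params.ss_cap_enabled,
        "gap_open": params.gap_open,
        "gap_extend": params.gap_extend,
    }


def search_library(
    q: ProfileHMM,
    lib: list[ProfileHMM],
    params: ScoringParams,
    calib: CalibrationModel,
    library_id: str = "",
) -> SearchResult:
    """Align the query against every target, calibrate, sort by score_aass.

    E-values use the size of the library actually searched.
    """
    if not lib:
        raise ValueError("empty library")
    model = calib.with_library_size(len(lib))
    hits = []
    for t in lib:
        h = align_local(q, t, params)
        calibrate_hit(h, model, params)
        hits.append(h)
    return SearchResult(
        query_id=q.id,
        hits=sort_hits(hits),
        library_id=library_id,
        params=_params_snapshot(params),
    )


def apply_filters(r: SearchResult, policy: FilterPolicy) -> SearchResult:
    """Keep hits meeting both the prob[SS] and COLs thresholds.

    Idempotent and order-preserving.
    """
    return SearchResult(
        query_id=r.query_id,
        hits=[h for h in r.hits if policy.passes(h)],
        library_id=r.library_id,
        params=dict(r.params),
    )


def bidirectional_search(
    region: ProfileHMM,
    known_lib: list[ProfileHMM],
    unknown_lib: list[ProfileHMM],
    params: ScoringParams,
    calib: CalibrationModel,
    policy: FilterPolicy,
) -> tuple[SearchResult, SearchResult, bool]:
    """Search in both directions and check whether they agree on the region.

    Forward emulates known-to-unknown search: each reference family profile
    queries the unknown (chunk) library and hits landing on `region` are
    kept.  Reverse queries the known library with the region's own profile,
    which is typically richer and region-centred - the direction asymmetry
    that makes reverse search more sensitive.  `agreed` is True when the top
    reverse hit passing the policy names a family that forward search also
    found.
    """
    if not any(t.id == region.id for t in unknown_lib):
        raise ValueError(f"region {region.id!r} not present in unknown library")
    forward_hits = []
    for known in known_lib:
        res = search_library(known, unknown_lib, params, calib, "unknown")
        for h in res.hits:
            if h.target_id == region.id and policy.passes(h):
                forward_hits.append(h)
    forward = SearchResult(
        query_id=region.id,
        hits=sort_hits(forward_hits),
        library_id="forward:known->unknown",
        params=_params_snapshot(params),
    )
    reverse = search_library(region, known_lib, params, calib, "known")
    rev_pass = [h for h in reverse.hits if policy.passes(h)]
    agreed = bool(
        rev_pass
        and rev_pass[0].target_id in {h.query_id for h in forward.hits}
    )
    return forward, reverse, agreed


def confirm_domain(
    hit: AlignmentHit,
    q_source_msa: Msa,
    t_domain: ProfileHMM,
    flank: int = 4,
    params: ScoringParams | None = None,
    calib: CalibrationModel | None = None,
    policy: FilterPolicy | None = None,
) -> tuple[bool, AlignmentHit]:
    """Domain-only re-alignment of a passing hit.

    Extracts the query match columns [q_start - flank, q_end + flank]
    (clamped), keeps only MSA rows with >= 50% non-gap residues in that
    window, rebuilds the profile from the sub-MSA with secondary-structure
    annotation deleted, and re-aligns it pairwise against the reference
    domain.  Contaminating rows that only partially overlap the window are
    dropped, so a profile whose domain-like character came from contaminants
    rather than from the region's own sequence no longer produces a hit.
    """
    if not 0 <= flank:
        raise ValueError("flank must be >= 0")
    params = params or ScoringParams()
    policy = policy or FilterPolicy()
    n_match = len(q_source_msa.match_columns)
    if not 1 <= hit.q_start <= hit.q_end <= n_match:
        raise ValueError(
            f"hit window {hit.q_start}-{hit.q_end} outside MSA match columns"
        )
    lo = max(1, hit.q_start - flank)
    hi = min(n_match, hit.q_end + flank)
    sub = q_source_msa.slice_match_columns(lo, hi)
    width = len(sub.match_columns)
    kept = []
    for i in range(sub.n_rows):
        row = sub.match_row(i)
        nongap = sum(1 for c in row if c not in GAP_CHARS)
        if nongap / width >= 0.5:
            kept.append(sub.rows[i])
    if not kept:
        raise ValueError("no rows left in domain window after gap filtering")
    dom_msa = Msa(
        id=f"{q_source_msa.id}/dom{lo}-{hi}",
        rows=kept,
        match_columns=list(sub.match_columns),
    )
    q_dom = build_profile(
        dom_msa, ss=None, background=params.background,
        id=dom_msa.id, source=(q_source_msa.id, lo, hi),
    )
    re_hit = align_local(q_dom, t_domain.strip_ss(), params)
    if calib is not None:
        calibrate_hit(re_hit, calib.with_library_size(1), params)
        confirmed = policy.passes(re_hit)
    else:
        confirmed = False
    return confirmed, re_hit


def transitive_search(
    q: ProfileHMM,
    intermediate_lib: list[ProfileHMM],
    known_lib: list[ProfileHMM],
    params: ScoringParams,
    calib: CalibrationModel,
    policy: FilterPolicy,
) -> list[TransitiveLink]:
    """Two-leg indirect search via an intermediate library.

    For every intermediate hit passing the policy, the intermediate's profile
    searches the known library; links are emitted where both legs pass,
    deduplicated per (query, target) keeping the largest combined
    probability (the min of the two leg probs - a conservative combination).
    """
    if not intermediate_lib or not known_lib:
        raise ValueError("libraries must be non-empty")
    inter_by_id = {p.id: p for p in intermediate_lib}
    leg1_res = apply_filters(
        search_library(q, intermediate_lib, params, calib, "intermediate"),
        policy,
    )
    best: dict[tuple[str, str], TransitiveLink] = {}
    leg2_cache: dict[str, list[AlignmentHit]] = {}
    for leg1 in leg1_res.hits:
        mid = inter_by_id[leg1.target_id]
        if mid.id not in leg2_cache:
            res2 = apply_filters(
                search_library(mid, known_lib, params, calib, "known"),
                policy,
            )
            leg2_cache[mid.id] = res2.hits
        for leg2 in leg2_cache[mid.id]:
            combined = min(leg1.prob_ss, leg2.prob_ss)
            key = (q.id, leg2.target_id)
            if key not in best or combined > best[key].combined_prob:
                best[key] = TransitiveLink(
                    query_id=q.id,
                    target_id=leg2.target_id,
                    intermediate_id=mid.id,
                    leg1=leg1,
                    leg2=leg2,
                    combined_prob=combined,
                )
    return sorted(best.values(), key=lambda l: (l.query_id, l.target_id))
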