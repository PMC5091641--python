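"""Synthetic clans of homologous domain families with known ground truth.

The generator emulates the statistical structure the whole analysis assumes:
a clan of protein-domain families (default fold: seven beta strands plus one
C-terminal helix spanning 100-120 residues) that share a secondary-structure
template but have diverged in sequence - strongly between families, mildly
within them.  Domains are embedded in unrelated flanking sequence inside
fixed-length host proteins, each host carries an MSA of its family siblings
aligned over the domain columns only, and decoy proteins with no domain are
emitted at twice the domain-bearing count.  Indels are confined to loop
(C) positions so the fold template stays alignable: the premise that
structure outlasts sequence.

`make_contaminated_msa` builds the Age1p-style failure mode: an MSA for a
region that contains no domain, padded with genuine domain sequences from a
donor family interleaved across part of the region.  The full-region profile
then resembles the donor family even though the region's own sequence does
not - the false positive that domain-only confirmation must reject.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AMINO_ACIDS, ROBINSON_BACKGROUND
from .msa import Msa


@dataclass
class ClanSpec:
    n_families: int = 6
    members_per_family: int = 8
    domain_len_range: tuple[int, int] = (100, 120)
    ss_template: str | None = None            # default: generated βββββββα fold
    within_family_divergence: float = 0.8     # expected substitutions/site
    between_family_divergence: float = 1.6
    flank_len_range: tuple[int, int] = (40, 160)   # left-flank bounds
    host_length: int = 300
    n_reference_members: int = 8              # per-family reference MSA depth
    n_intermediates: int = 4                  # "related proteome" homologs
    intermediate_divergence: float = 0.4
    decoy_ratio: int = 2
    indel_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.between_family_divergence > self.within_family_divergence > 0:
            raise ValueError("require between > within > 0 divergence")
        lo, hi = self.domain_len_range
        if not 50 <= lo <= hi <= 300:
            raise ValueError("domain_len_range must lie within [50, 300]")
        if self.host_length < hi + 2 * self.flank_len_range[0]:
            raise ValueError("host_length too short for domain plus flanks")

    def to_json(self, path: str | Path) -> None:
        d = dict(self.__dict__)
        d["domain_len_range"] = list(d["domain_len_range"])
        d["flank_len_range"] = list(d["flank_len_range"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)


def fold_template(length: int) -> str:
    """3-state template for the shared fold: 7 strands + C-terminal helix.

    Strand residues take ~48% of the length, the helix ~12% (>= 8), loops
    fill the rest across the nine inter-element slots.
    """
    if length < 50:
        raise ValueError("template needs >= 50 residues")
    helix = max(8, round(0.12 * length))
    strand_total = round(0.48 * length)
    strands = [strand_total // 7] * 7
    for i in range(strand_total - 7 * (strand_total // 7)):
        strands[i] += 1
    loops_total = length - helix - sum(strands)
    loops = [loops_total // 9] * 9
    for i in range(loops_total - 9 * (loops_total // 9)):
        loops[i] += 1
    parts = []
    for i in range(7):
        parts.append("C" * loops[i])
        parts.append("E" * strands[i])
    parts.append("C" * loops[7])
    parts.append("H" * helix)
    parts.append("C" * loops[8])
    return "".join(parts)


def sample_ancestor(
    spec: ClanSpec, rng: np.random.Generator
) -> tuple[str, str, np.ndarray]:
    """Ancestral domain: background-drawn sequence over the fold template.

    Secondary-structure confidences are high (7-9) inside strand/helix
    elements and low (0-4) in loops.
    """
    lo, hi = spec.domain_len_range
    length = int(rng.integers(lo, hi + 1))
    states = spec.ss_template or fold_template(length)
    if len(states) != length:
        length = len(states)
    seq = "".join(
        rng.choice(list(AMINO_ACIDS), size=length, p=ROBINSON_BACKGROUND)
    )
    conf = np.where(
        np.array(list(states)) == "C",
        rng.integers(0, 5, size=length),
        rng.integers(7, 10, size=length),
    ).astype(np.int8)
    return seq, states, conf


@dataclass
class EvolvedDomain:
    """A domain evolved from a parent, with its alignment to the parent.

    `match[c]` is the residue at parent column c+1 (None = deleted);
    `inserts[c]` holds residues inserted after parent column c (0 = before
    the first).  `seq`/`states`/`conf` describe the child itself.
    """

    id: str
    match: list[str | None]
    inserts: dict[int, str]
    seq: str
    states: str
    conf: np.ndarray

    def pos_of_parent_col(self) -> dict[int, int]:
        """Map parent column (1-based) -> position in `seq` (1-based)."""
        out = {}
        pos = len(self.inserts.get(0, ""))
        for c, res in enumerate(self.match, start=1):
            if res is not None:
                pos += 1
                out[c] = pos
            pos += len(self.inserts.get(c, ""))
        return out

    def a3m_row(self) -> str:
        """Row in parent coordinates: match/deletes + lowercase inserts."""
        parts = [self.inserts.get(0, "").lower()]
        for c, res in enumerate(self.match, start=1):
            parts.append(res if res is not None else "-")
            parts.append(self.inserts.get(c, "").lower())
        return "".join(parts)


def _substituted(
    res: str, rng: np.random.Generator, background: np.ndarray
) -> str:
    probs = background.copy()
    probs[AMINO_ACIDS.index(res)] = 0.0
    probs /= probs.sum()
    return str(rng.choice(list(AMINO_ACIDS), p=probs))


def evolve_domain(
    parent_seq: str,
    parent_states: str,
    parent_conf: np.ndarray,
    divergence: float,
    rng: np.random.Generator,
    indel_rate: float = 0.02,
    loop_rate: float = 2.0,
    background: np.ndarray = ROBINSON_BACKGROUND,
    id: str = "",
) -> EvolvedDomain:
    """Evolve a child along one branch of expected length `divergence`.

    Substitution events arrive per site with Poisson(d) counts - so a site
    changes with probability 1 - exp(-d), and at large d its residue
    equilibrates toward the background - each event replacing the residue
    by a background draw excluding the current one.  Loop (C) sites evolve
    `loop_rate` times faster and are additionally subject to indels
    (deletion or short insertion) at `indel_rate` per site; strand/helix
    sites are never deleted.  Faster loops give loop columns visibly higher
    entropy than strand/helix columns in family MSAs - the conserved-fold /
    variable-loop structure that makes SS-weighted scoring informative.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    match: list[str | None] = []
    inserts: dict[int, str] = {}
    seq_parts: list[str] = []
    states_parts: list[str] = []
    conf_parts: list[int] = []
    for c in range(len(parent_seq)):
        res = parent_seq[c]
        state = parent_states[c]
        conf = int(parent_conf[c])
        d_site = divergence * (loop_rate if state == "C" else 1.0)
        for _ in range(rng.poisson(d_site)):
            res = _substituted(res, rng, background)
        deleted = False
        # a zero-length branch accumulates neither substitutions nor indels
        if state == "C" and indel_rate > 0 and divergence > 0:
            if rng.random() < indel_rate:
                if rng.random() < 0.5:
                    deleted = True
                else:
                    ins_len = int(rng.integers(1, 3))
                    ins = "".join(
                        rng.choice(list(AMINO_ACIDS), size=ins_len, p=background)
                    )
                    inserts[c + 1] = ins
        if deleted:
            match.append(None)
        else:
            match.append(res)
            seq_parts.append(res)
            states_parts.append(state)
            conf_parts.append(conf)
        if (c + 1) in inserts:
            ins = inserts[c + 1]
            seq_parts.append(ins)
            states_parts.append("C" * len(ins))
            conf_parts.extend(int(rng.integers(0, 5)) for _ in ins)
    return EvolvedDomain(
        id=id,
        match=match,
        inserts=inserts,
        seq="".join(seq_parts),
        states="".join(states_parts),
        conf=np.array(conf_parts, dtype=np.int8),
    )


def evolve_sequence(
    parent: str,
    divergence: float,
    rng: np.random.Generator,
    ss: str | None = None,
    indel_rate: float = 0.02,
    loop_rate: float = 2.0,
    background: np.ndarray = ROBINSON_BACKGROUND,
) -> str:
    """Child sequence only (see `evolve_domain` for the full record)."""
    states = ss or "C" * len(parent)
    conf = np.zeros(len(parent), dtype=np.int8)
    return evolve_domain(
        parent, states, conf, divergence, rng,
        indel_rate=indel_rate, loop_rate=loop_rate, background=background,
    ).seq


# ---------------------------------------------------------------------------
# Clan assembly


@dataclass
class MemberSim:
    member_id: str
    family_id: str
    domain: EvolvedDomain
    host_id: str
    host_seq: str
    domain_start: int    # 1-based inclusive in host
    domain_end: int
    host_msa: Msa        # host row + siblings over domain columns
    host_ss: list[tuple[str, int]]   # per host position (state, conf)


@dataclass
class FamilySim:
    family_id: str
    founder_seq: str
    founder_states: str
    founder_conf: np.ndarray
    members: list[MemberSim] = field(default_factory=list)
    reference: list[EvolvedDomain] = field(default_factory=list)
    intermediates: list[EvolvedDomain] = field(default_factory=list)

    def _founder_msa(self, doms: list[EvolvedDomain], id: str) -> Msa:
        # founder-coordinate match states only; rare loop inserts are dropped
        rows = [
            (d.id, "".join(r if r is not None else "-" for r in d.match))
            for d in doms
        ]
        return Msa(
            id=id,
            rows=rows,
            match_columns=list(range(1, len(rows[0][1]) + 1)),
        )

    def reference_msa(self) -> Msa:
        """Reference-family MSA in founder coordinates (match states only)."""
        return self._founder_msa(self.reference, f"{self.family_id}_ref")

    def founder_ss(self) -> list[tuple[str, int]]:
        return [
            (s, int(c))
            for s, c in zip(self.founder_states, self.founder_conf)
        ]

    def intermediate_msa(self, k: int) -> Msa:
        """MSA for intermediate k: itself plus the other intermediates."""
        doms = [self.intermediates[k]] + [
            d for i, d in enumerate(self.intermediates) if i != k
        ]
        return self._founder_msa(doms, self.intermediates[k].id)


@dataclass
class ClanData:
    spec: ClanSpec
    clan_id: str
    families: list[FamilySim]
    decoys: list[tuple[str, str]]
    truth: pd.DataFrame

    @property
    def members(self) -> list[MemberSim]:
        return [m for f in self.families for m in f.members]

    def write(self, outdir: str | Path) -> None:
        """Emit hosts/decoys FASTA, per-region A3M MSAs, truth TSV, spec."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "hosts.fasta", "w") as fh:
            for m in self.members:
                fh.write(f">{m.host_id}\n{m.host_seq}\n")
        with open(outdir / "decoys.fasta", "w") as fh:
            for did, seq in self.decoys:
                fh.write(f">{did}\n{seq}\n")
        msa_dir = outdir / "msa"
        msa_dir.mkdir(exist_ok=True)
        for m in self.members:
            with open(msa_dir / f"{m.member_id}.a3m", "w") as fh:
                for name, row in m.host_msa.rows:
                    fh.write(f">{name}\n{row}\n")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.spec.to_json(outdir / "spec.json")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(
        rng.choice(list(AMINO_ACIDS), size=length, p=ROBINSON_BACKGROUND)
    )


def _embed_member(
    spec: ClanSpec,
    fam: FamilySim,
    idx: int,
    dom: EvolvedDomain,
    siblings: list[EvolvedDomain],
    rng: np.random.Generator,
) -> MemberSim:
    host_id = f"prot_{fam.family_id}_{idx}"
    L = spec.host_length
    total_flank = L - len(dom.seq)
    lo = spec.flank_len_range[0]
    hi = min(spec.flank_len_range[1], total_flank - lo)
    left = int(rng.integers(lo, hi + 1))
    right = total_flank - left
    host_seq = _random_seq(left, rng) + dom.seq + _random_seq(right, rng)
    start, end = left + 1, left + len(dom.seq)

    # host-coordinate MSA: full host row + siblings over domain columns
    pos_of = dom.pos_of_parent_col()
    rows = [(host_id, host_seq)]
    for sib in siblings:
        row = ["-"] * L
        for c, res in enumerate(sib.match, start=1):
            if res is not None and c in pos_of:
                row[left + pos_of[c] - 1] = res
        rows.append((sib.id, "".join(row)))
    host_msa = Msa(
        id=f"{fam.family_id}m{idx}",
        rows=rows,
        match_columns=list(range(1, L + 1)),
    )

    host_ss: list[tuple[str, int]] = [
        ("C", int(rng.integers(0, 5))) for _ in range(left)
    ]
    host_ss += [
        (s, int(c)) for s, c in zip(dom.states, dom.conf)
    ]
    host_ss += [("C", int(rng.integers(0, 5))) for _ in range(right)]

    return MemberSim(
        member_id=f"{fam.family_id}m{idx}",
        family_id=fam.family_id,
        domain=dom,
        host_id=host_id,
        host_seq=host_seq,
        domain_start=start,
        domain_end=end,
        host_msa=host_msa,
        host_ss=host_ss,
    )


def build_clan(spec: ClanSpec) -> ClanData:
    """Generate one clan: families, embedded members, decoys, ground truth.

    One ancestral fold is drawn; family founders evolve from it at the
    between-family divergence; members, reference sequences and
    "related-proteome" intermediates evolve from each founder at the within,
    within and intermediate divergences respectively.  Each member is
    embedded mid-host with random flanks; decoy proteins (pure background
    sequence, no domain) are emitted at `decoy_ratio` x the member count.
    """
    rng = np.random.default_rng(spec.seed)
    clan_id = "clan0"
    anc_seq, anc_states, anc_conf = sample_ancestor(spec, rng)
    families: list[FamilySim] = []
    for f in range(spec.n_families):
        fid = f"F{f}"
        founder = evolve_domain(
            anc_seq, anc_states, anc_conf,
            spec.between_family_divergence, rng,
            indel_rate=spec.indel_rate, id=f"{fid}_founder",
        )
        fam = FamilySim(
            family_id=fid,
            founder_seq=founder.seq,
            founder_states=founder.states,
            founder_conf=founder.conf,
        )
        member_doms = [
            evolve_domain(
                fam.founder_seq, fam.founder_states, fam.founder_conf,
                spec.within_family_divergence, rng,
                indel_rate=spec.indel_rate, id=f"{fid}m{i}_dom",
            )
            for i in range(spec.members_per_family)
        ]
        fam.reference = [
            evolve_domain(
                fam.founder_seq, fam.founder_states, fam.founder_conf,
                spec.within_family_divergence, rng,
                indel_rate=spec.indel_rate, id=f"{fid}_ref{i}",
            )
            for i in range(spec.n_reference_members)
        ]
        fam.intermediates = [
            evolve_domain(
                fam.founder_seq, fam.founder_states, fam.founder_conf,
                spec.intermediate_divergence, rng,
                indel_rate=spec.indel_rate, id=f"{fid}_mid{i}",
            )
            for i in range(spec.n_intermediates)
        ]
        for i, dom in enumerate(member_doms):
            siblings = [d for j, d in enumerate(member_doms) if j != i]
            fam.members.append(
                _embed_member(spec, fam, i, dom, siblings, rng)
            )
        families.append(fam)

    n_decoys = spec.decoy_ratio * spec.n_families * spec.members_per_family
    decoys = [
        (f"decoy_{k}", _random_seq(spec.host_length, rng))
        for k in range(n_decoys)
    ]

    rows = []
    for fam in families:
        for m in fam.members:
            rows.append(
                {
                    "region_id": m.member_id,
                    "protein_id": m.host_id,
                    "start": m.domain_start,
                    "end": m.domain_end,
                    "family_id": m.family_id,
                    "clan_id": clan_id,
                    "is_decoy": False,
                    "is_contaminated_construct": False,
                }
            )
    for did, seq in decoys:
        rows.append(
            {
                "region_id": did,
                "protein_id": did,
                "start": 1,
                "end": len(seq),
                "family_id": "",
                "clan_id": "",
                "is_decoy": True,
                "is_contaminated_construct": False,
            }
        )
    truth = pd.DataFrame(rows)
    return ClanData(
        spec=spec, clan_id=clan_id, families=families,
        decoys=decoys, truth=truth,
    )


# ---------------------------------------------------------------------------
# Age1p-style contaminated constructs


@dataclass
class ContaminatedConstruct:
    """A region with no domain whose MSA is padded with genuine donor-family
    sequences across part of the region."""

    region_id: str
    region_seq: str
    msa: Msa
    ss: list[tuple[str, int]]
    span: tuple[int, int]          # region columns the contaminants occupy
    donor_family: str


def build_contaminated_construct(
    region_seq: str,
    donor: FamilySim,
    n_contaminants: int = 2,
    rng: np.random.Generator | None = None,
    region_id: str = "contam",
) -> ContaminatedConstruct:
    """Interleave donor domain sequences across part of a non-domain region.

    Donor residues are distributed so that every contaminated column holds
    exactly one donor residue while each contaminant row covers well under
    half of the span - so the full-region profile is half donor-derived, yet
    any window-restricted sub-MSA drops the contaminant rows under a 50%
    coverage rule, leaving only the region's own (non-homologous) sequence.
    """
    rng = rng or np.random.default_rng(0)
    L = len(region_seq)
    rows = [(region_id, region_seq)]
    ss: list[tuple[str, int]] = [
        ("C", int(rng.integers(0, 5))) for _ in range(L)
    ]
    if n_contaminants == 0:
        msa = Msa(id=region_id, rows=rows, match_columns=list(range(1, L + 1)))
        return ContaminatedConstruct(
            region_id, region_seq, msa, ss, (0, 0), donor.family_id
        )
    donors = [
        donor.reference[i % len(donor.reference)]
        for i in range(n_contaminants)
    ]
    # Alternate the contaminants in contiguous blocks along the donor-founder
    # coordinate (monotone, so the whole span aligns as one thread to the
    # donor profile), separated by short region-only stretches.  Each donor
    # row then covers block/(n*block + sep) < 1/2 of the span.
    block, sep, margin = 20, 6, 5
    n_founder = len(donor.founder_seq)
    # founder positions that fit in the region with the separators included
    per_cycle = n_contaminants * block
    max_cols = L - 2 * margin
    F = n_founder
    while F + sep * ((F + block - 1) // block) > max_cols:
        F -= 1
    span_start = margin + 1
    col = span_start - 1            # 0-based next column to fill
    contam_rows = [["-"] * L for _ in range(n_contaminants)]
    for p in range(1, F + 1):
        k = ((p - 1) // block) % n_contaminants
        d = donors[k]
        res = d.match[p - 1] if p - 1 < len(d.match) else None
        if res is not None:
            contam_rows[k][col] = res
            ss[col] = (
                donor.founder_states[p - 1],
                min(7, int(donor.founder_conf[p - 1])),
            )
        col += 1
        if p % block == 0 and p < F:
            col += sep                 # region-only separator columns
    span_end = col
    for k, d in enumerate(donors):
        rows.append((f"{region_id}_contam_{d.id}", "".join(contam_rows[k])))
    msa = Msa(id=region_id, rows=rows, match_columns=list(range(1, L + 1)))
    return ContaminatedConstruct(
        region_id, region_seq, msa, ss, (span_start, span_end),
        donor.family_id,
    )


def make_contaminated_msa(
    region_seq: str,
    donor: FamilySim,
    n_contaminants: int = 2,
    rng: np.random.Generator | None = None,
    region_id: str = "contam",
) -> Msa:
    """MSA of `build_contaminated_construct` (kept for the narrow contract)."""
    return build_contaminated_construct(
        region_seq, donor, n_contaminants, rng, region_id
    ).msa
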