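"""Profile HMMs with secondary-structure annotation, and proteome chunking.

A :class:`ProfileHMM` is the unit compared by the alignment engine: one row of
pseudocounted amino-acid frequencies per match column, each carrying a
3-state secondary-structure call (H/E/C) with a 0-9 confidence, plus the
source coordinates of the region the profile summarizes.

Chunking implements the overlapping-window library scheme: proteins are cut
into fixed-size windows (default 200 residues stepping by 100) so that search
never needs to know domain boundaries in advance; the final window is
anchored to the protein end so every chunk presents a full-width profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import (
    AMINO_ACIDS,
    N_AA,
    ROBINSON_BACKGROUND,
    SS_INDEX,
    SS_STATES,
    encode_seq,
)
from .msa import GAP_CHARS, Msa


@dataclass
class ProfileColumn:
    """One match column: 20 relative frequencies + SS state and confidence."""

    freqs: np.ndarray
    ss_state: str = "C"
    ss_conf: int = 0
    gap_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (N_AA,):
            raise ValueError("freqs must have length 20")
        if np.any(self.freqs < 0):
            raise ValueError("negative frequency")
        if abs(float(self.freqs.sum()) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if self.ss_state not in SS_STATES:
            raise ValueError(f"bad ss state {self.ss_state!r}")
        if not 0 <= int(self.ss_conf) <= 9:
            raise ValueError("ss_conf must be in 0..9")


@dataclass
class ProfileHMM:
    """Array-backed profile over match columns.

    `source` is (protein_id, start, end) in 1-based inclusive residue
    coordinates of the region the profile was built from.
    """

    id: str
    freqs: np.ndarray                  # (n_cols, 20)
    ss: np.ndarray                     # (n_cols,) int8 codes into SS_STATES
    ss_conf: np.ndarray                # (n_cols,) int8 in 0..9
    gap_fraction: np.ndarray           # (n_cols,) float
    source: tuple[str, int, int] = ("", 1, 1)
    n_seqs: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.ss = np.asarray(self.ss, dtype=np.int8)
        self.ss_conf = np.asarray(self.ss_conf, dtype=np.int8)
        self.gap_fraction = np.asarray(self.gap_fraction, dtype=float)
        n = self.freqs.shape[0]
        if n < 1:
            raise ValueError(f"profile {self.id!r} has no columns")
        if self.freqs.shape != (n, N_AA):
            raise ValueError("freqs must be (n_cols, 20)")
        for arr, name in (
            (self.ss, "ss"),
            (self.ss_conf, "ss_conf"),
            (self.gap_fraction, "gap_fraction"),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{name} length mismatch")
        pid, start, end = self.source
        if end - start + 1 < n:
            raise ValueError(
                f"profile {self.id!r}: source span {start}-{end} shorter "
                f"than {n} columns"
            )
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")

    @property
    def n_cols(self) -> int:
        return int(self.freqs.shape[0])

    def column(self, i: int) -> ProfileColumn:
        """1-based column accessor returning a ProfileColumn view."""
        return ProfileColumn(
            freqs=self.freqs[i - 1],
            ss_state=SS_STATES[self.ss[i - 1]],
            ss_conf=int(self.ss_conf[i - 1]),
            gap_fraction=float(self.gap_fraction[i - 1]),
        )

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[j] for j in self.freqs.argmax(axis=1))

    def strip_ss(self, new_id: str | None = None) -> "ProfileHMM":
        """Copy with all secondary-structure annotation removed (C, conf 0)."""
        n = self.n_cols
        return ProfileHMM(
            id=new_id or self.id,
            freqs=self.freqs.copy(),
            ss=np.full(n, SS_INDEX["C"], dtype=np.int8),
            ss_conf=np.zeros(n, dtype=np.int8),
            gap_fraction=self.gap_fraction.copy(),
            source=self.source,
            n_seqs=self.n_seqs,
        )


def build_profile(
    msa: Msa,
    ss: list[tuple[str, int]] | None = None,
    pseudocount_alpha: float = 1.0,
    background: np.ndarray = ROBINSON_BACKGROUND,
    position_weights: bool = False,
    id: str | None = None,
    source: tuple[str, int, int] | None = None,
) -> ProfileHMM:
    """Build a profile from the match columns of an MSA.

    Per column, freq_a = (count_a + alpha * bg_a) / (n_eff + alpha) where
    n_eff is the (weighted) number of non-gap residues in the column.
    Sequences are weighted uniformly unless `position_weights` turns on
    Henikoff-style position-based weights.  `ss`, when given, supplies one
    (state, confidence) pair per match column; absent SS means (C, 0).
    """
    if pseudocount_alpha < 0:
        raise ValueError("pseudocount_alpha must be >= 0")
    cols = msa.match_columns
    n_cols = len(cols)
    if n_cols == 0:
        raise ValueError(f"MSA {msa.id!r} has no match columns")
    if ss is not None and len(ss) != n_cols:
        raise ValueError(
            f"ss has {len(ss)} entries but MSA has {n_cols} match columns"
        )
    background = np.asarray(background, dtype=float)

    enc = np.stack(
        [encode_seq(msa.match_row(i)) for i in range(msa.n_rows)]
    )  # (n_rows, n_cols); gaps/unknown -> -1

    if position_weights:
        weights = _henikoff_weights(enc)
    else:
        weights = np.full(msa.n_rows, 1.0)

    counts = np.zeros((n_cols, N_AA))
    for r in range(msa.n_rows):
        idx = enc[r]
        ok = idx >= 0
        np.add.at(counts, (np.nonzero(ok)[0], idx[ok]), weights[r])
    n_eff = counts.sum(axis=1)

    denom = n_eff + pseudocount_alpha
    if np.any(denom <= 0):
        raise ValueError(
            "column with no residues and zero pseudocount weight"
        )
    freqs = (counts + pseudocount_alpha * background) / denom[:, None]

    gap_frac = np.array([msa.gap_fraction(c) for c in cols])
    if ss is None:
        ss_codes = np.full(n_cols, SS_INDEX["C"], dtype=np.int8)
        ss_conf = np.zeros(n_cols, dtype=np.int8)
    else:
        ss_codes = np.array([SS_INDEX[s] for s, _ in ss], dtype=np.int8)
        ss_conf = np.array([int(c) for _, c in ss], dtype=np.int8)

    return ProfileHMM(
        id=id or msa.id,
        freqs=freqs,
        ss=ss_codes,
        ss_conf=ss_conf,
        gap_fraction=gap_frac,
        source=source or (msa.id, 1, n_cols),
        n_seqs=msa.n_rows,
    )


def _henikoff_weights(enc: np.ndarray) -> np.ndarray:
    """Position-based sequence weights (Henikoff & Henikoff 1994)."""
    n_rows, n_cols = enc.shape
    w = np.zeros(n_rows)
    for c in range(n_cols):
        col = enc[:, c]
        ok = col >= 0
        if not ok.any():
            continue
        vals, counts = np.unique(col[ok], return_counts=True)
        r = len(vals)
        share = {v: 1.0 / (r * k) for v, k in zip(vals, counts)}
        for i in np.nonzero(ok)[0]:
            w[i] += share[col[i]]
    if w.sum() == 0:
        return np.full(n_rows, 1.0)
    return w * n_rows / w.sum()


# ---------------------------------------------------------------------------
# Chunking


@dataclass(frozen=True)
class ChunkPolicy:
    chunk_size: int = 200
    step: int = 100

    def __post_init__(self) -> None:
        if not 1 <= self.step <= self.chunk_size:
            raise ValueError("require 1 <= step <= chunk_size")


@dataclass(frozen=True)
class Chunk:
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    seq: str


def chunk_protein(
    seq: str, policy: ChunkPolicy = ChunkPolicy(), protein_id: str = ""
) -> list[Chunk]:
    """Cut a protein into overlapping fixed-size windows.

    Windows start at 1, 1+step, ... while a full window fits; if the last
    full window does not reach the C-terminus a tail window anchored at the
    protein end is appended (the whole protein when it is shorter than one
    window).  Every residue is covered and all windows except possibly the
    single window of a short protein have length exactly chunk_size.
    """
    L = len(seq)
    if L == 0:
        raise ValueError("empty sequence")
    size, step = policy.chunk_size, policy.step
    if L < size:
        return [Chunk(protein_id, 1, L, seq)]
    chunks = []
    start = 1
    while start + size - 1 <= L:
        chunks.append(Chunk(protein_id, start, start + size - 1, seq[start - 1 : start + size - 1]))
        start += step
    if chunks[-1].end < L:
        chunks.append(Chunk(protein_id, L - size + 1, L, seq[L - size :]))
    return chunks


# ---------------------------------------------------------------------------
# PHMM/1 on-disk dialect


class ProfileFormatError(ValueError):
    pass


def write_profile(p: ProfileHMM, path: str | Path) -> None:
    """Write a profile in the PHMM/1 TSV dialect.

    Header lines: #PHMM/1, #id, #source, #nseqs; then one row per column:
    index, 20 frequencies, ss_state, ss_conf, gap_fraction.  Frequencies are
    written with 10 decimals so that a write/read round trip reproduces them
    to 1e-9.
    """
    pid, start, end = p.source
    with open(path, "w") as fh:
        fh.write("#PHMM/1\n")
        fh.write(f"#id\t{p.id}\n")
        fh.write(f"#source\t{pid}\t{start}\t{end}\n")
        fh.write(f"#nseqs\t{p.n_seqs}\n")
        for i in range(p.n_cols):
            fields = [str(i + 1)]
            fields += [f"{v:.10f}" for v in p.freqs[i]]
            fields += [
                SS_STATES[p.ss[i]],
                str(int(p.ss_conf[i])),
                f"{p.gap_fraction[i]:.6f}",
            ]
            fh.write("\t".join(fields) + "\n")


def read_profile(path: str | Path) -> ProfileHMM:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != "#PHMM/1":
        got = lines[0] if lines else "<empty>"
        raise ProfileFormatError(f"{path}: expected #PHMM/1 header, got {got!r}")
    pid = ""
    source = ("", 1, 1)
    n_seqs = 1
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if line.startswith("#id"):
            pid = parts[1] if len(parts) > 1 else ""
        elif line.startswith("#source"):
            source = (parts[1], int(parts[2]), int(parts[3]))
        elif line.startswith("#nseqs"):
            n_seqs = int(parts[1])
        elif line.startswith("#"):
            continue
        else:
            if len(parts) != 1 + N_AA + 3:
                raise ProfileFormatError(
                    f"{path}:{ln}: expected {1 + N_AA + 3} fields, got {len(parts)}"
                )
            try:
                freqs = [float(x) for x in parts[1 : 1 + N_AA]]
                state = parts[1 + N_AA]
                conf = int(parts[2 + N_AA])
                gapf = float(parts[3 + N_AA])
            except ValueError as e:
                raise ProfileFormatError(f"{path}:{ln}: {e}") from e
            rows.append((freqs, state, conf, gapf))
    if not rows:
        raise ProfileFormatError(f"{path}: no columns")
    return ProfileHMM(
        id=pid,
        freqs=np.array([r[0] for r in rows]),
        ss=np.array([SS_INDEX[r[1]] for r in rows], dtype=np.int8),
        ss_conf=np.array([r[2] for r in rows], dtype=np.int8),
        gap_fraction=np.array([r[3] for r in rows]),
        source=source,
        n_seqs=n_seqs,
    )
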