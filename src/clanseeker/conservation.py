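"""Per-residue conservation tracks: robust normalization and smoothing.

Raw conservation scores are rescaled so the median is 0 and the
interquartile distance (75th minus 25th centile, linear-interpolation
percentiles) is 1, then smoothed with a centred rolling mean of +/-9
residues (window n = 19, shrinking at the track ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ConservationTrack:
    protein_id: str
    positions: np.ndarray          # 1-based, contiguous
    raw: np.ndarray
    normalized: np.ndarray | None = None
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.positions.shape != self.raw.shape:
            raise ValueError("positions and raw must have equal length")
        if len(self.positions) and not np.array_equal(
            self.positions,
            np.arange(self.positions[0], self.positions[0] + len(self.positions)),
        ):
            raise ValueError("positions must be contiguous")
        for name in ("normalized", "smoothed"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.raw.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)


def normalize_track(t: ConservationTrack) -> ConservationTrack:
    """(raw - median) / IQR with linear-interpolation percentiles."""
    if t.raw.size < 4:
        raise ValueError("need >= 4 values to normalize")
    q25, q50, q75 = np.percentile(t.raw, [25, 50, 75])
    iqr = q75 - q25
    if iqr <= 0:
        raise ValueError("degenerate track: interquartile range is 0")
    return ConservationTrack(
        protein_id=t.protein_id,
        positions=t.positions.copy(),
        raw=t.raw.copy(),
        normalized=(t.raw - q50) / iqr,
    )


def rolling_mean(
    t: ConservationTrack, half_window: int = 9
) -> ConservationTrack:
    """Centred rolling average over [i - hw, i + hw], shrinking at edges."""
    if t.normalized is None:
        raise ValueError("normalize the track before smoothing")
    window = 2 * half_window + 1
    sm = (
        pd.Series(t.normalized)
        .rolling(window=window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return ConservationTrack(
        protein_id=t.protein_id,
        positions=t.positions.copy(),
        raw=t.raw.copy(),
        normalized=t.normalized.copy(),
        smoothed=sm,
    )


def read_track_tsv(path: str | Path, protein_id: str | None = None) -> ConservationTrack:
    df = pd.read_csv(path, sep="\t")
    return ConservationTrack(
        protein_id=protein_id or Path(path).stem,
        positions=df["position"].to_numpy(),
        raw=df["raw"].to_numpy(),
        normalized=df["normalized"].to_numpy() if "normalized" in df else None,
        smoothed=df["smoothed"].to_numpy() if "smoothed" in df else None,
    )


def write_track_tsv(t: ConservationTrack, path: str | Path) -> None:
    df = pd.DataFrame({"position": t.positions, "raw": t.raw})
    if t.normalized is not None:
        df["normalized"] = t.normalized
    if t.smoothed is not None:
        df["smoothed"] = t.smoothed
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
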