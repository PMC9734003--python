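"""Chromatographic fingerprint construction and similarity scoring.

Workflow: detect peaks in each batch trace, match peaks across batches by
retention time, keep the peaks present in every batch ("common peaks"),
summarise them as a reference fingerprint, and score each batch against the
reference with a congruence (cosine) coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Chromatogram",
    "PeakTable",
    "CommonPeakMatrix",
    "detect_peaks",
    "match_common_peaks",
    "reference_fingerprint",
    "similarity",
    "similarity_table",
    "trace_similarity",
]


@dataclass
class Chromatogram:
    """A single-batch detector trace sampled on a strictly increasing time grid."""

    batch_id: str
    time: np.ndarray  # minutes
    intensity: np.ndarray  # detector response (arbitrary units)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("time grid must be a non-empty 1-D vector")
        if self.time.shape != self.intensity.shape:
            raise ValueError("time and intensity must have equal length")
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("chromatogram contains non-finite values")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_min": self.time, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path, batch_id: str | None = None) -> "Chromatogram":
        df = pd.read_csv(path)
        if not {"time_min", "intensity"}.issubset(df.columns):
            raise ValueError(f"{path}: expected columns time_min,intensity")
        return cls(batch_id or Path(path).stem, df["time_min"].to_numpy(), df["intensity"].to_numpy())


@dataclass
class PeakTable:
    """Detected peaks of one batch: apex retention time, height, chord-baseline area, valley bounds."""

    batch_id: str
    peaks: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["apex_rt", "height", "area", "left", "right"]))

    def __post_init__(self) -> None:
        required = ["apex_rt", "height", "area", "left", "right"]
        missing = [c for c in required if c not in self.peaks.columns]
        if missing:
            raise ValueError(f"PeakTable missing columns: {missing}")
        self.peaks = self.peaks.sort_values("apex_rt").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class CommonPeakMatrix:
    """Batches x common-peak area matrix; columns ordered by consensus retention time."""

    peak_ids: list[str]
    consensus_rt: np.ndarray
    areas: pd.DataFrame  # index: batch ids, columns: peak ids

    def __post_init__(self) -> None:
        if len(self.peak_ids) < 1:
            raise ValueError("common-peak matrix needs at least one peak")
        self.consensus_rt = np.asarray(self.consensus_rt, dtype=float)
        if list(self.areas.columns) != list(self.peak_ids):
            raise ValueError("areas columns must match peak_ids")
        if self.areas.isna().any().any():
            raise ValueError("common-peak matrix must be fully populated")

    @property
    def n_batches(self) -> int:
        return len(self.areas.index)

    def to_csv(self, path: str | Path) -> None:
        out = pd.DataFrame({"peak_id": self.peak_ids, "consensus_rt": self.consensus_rt})
        out = pd.concat([out, self.areas.T.reset_index(drop=True)], axis=1)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CommonPeakMatrix":
        df = pd.read_csv(path)
        batches = [c for c in df.columns if c not in ("peak_id", "consensus_rt")]
        areas = df[batches].T
        areas.columns = df["peak_id"].tolist()
        areas.index.name = "batch"
        return cls(df["peak_id"].tolist(), df["consensus_rt"].to_numpy(), areas)


def detect_peaks(
    chrom: Chromatogram,
    min_prominence: float,
    min_width: float = 0.0,
) -> PeakTable:
    """Locate peak apexes, bound each peak at the flanking valleys, and integrate.

    Apexes are local maxima with topographic prominence >= ``min_prominence``
    and full width >= ``min_width`` minutes.  Each peak's bounds are the
    flanking valleys, i.e. the lowest trace samples between it and the
    neighbouring apexes (or the trace ends); its area is the trapezoid integral
    of the trace over [left, right] after subtracting the straight chord
    between the bound points, which serves as the local baseline.
    """
    t, y = chrom.time, chrom.intensity
    dt = float(np.median(np.diff(t)))
    width_samples = max(min_width / dt, 0.0)
    apex_idx, _ = find_peaks(y, prominence=min_prominence, width=width_samples or None)
    if apex_idx.size == 0:
        return PeakTable(chrom.batch_id)

    # valley between two apexes = lowest sample of the trace between them;
    # the outermost bounds come from the stretches to the trace ends
    valleys = np.empty(apex_idx.size + 1, dtype=int)
    valleys[0] = int(np.argmin(y[: apex_idx[0] + 1]))
    for k in range(apex_idx.size - 1):
        lo, hi = apex_idx[k], apex_idx[k + 1]
        valleys[k + 1] = lo + int(np.argmin(y[lo : hi + 1]))
    valleys[-1] = apex_idx[-1] + int(np.argmin(y[apex_idx[-1] :]))

    rows = []
    for k, ai in enumerate(apex_idx):
        li, ri = int(valleys[k]), int(valleys[k + 1])
        seg_t, seg_y = t[li : ri + 1], y[li : ri + 1]
        chord = np.interp(seg_t, [seg_t[0], seg_t[-1]], [seg_y[0], seg_y[-1]])
        area = float(np.trapezoid(seg_y - chord, seg_t))
        if area <= 0:
            continue
        rows.append(
            {
                "apex_rt": float(t[ai]),
                "height": float(y[ai]),
                "area": area,
                "left": float(t[li]),
                "right": float(t[ri]),
            }
        )
    return PeakTable(chrom.batch_id, pd.DataFrame(rows, columns=["apex_rt", "height", "area", "left", "right"]))


def match_common_peaks(
    tables: Sequence[PeakTable],
    rt_tolerance: float = 0.3,
) -> CommonPeakMatrix:
    """Cluster peaks across batches by retention time and keep the clusters
    present in every batch.

    All apexes are pooled and sorted by retention time, then swept greedily:
    a cluster absorbs a peak when |rt - cluster consensus| <= ``rt_tolerance``
    (consensus = running median of member rts).  A cluster holds at most one
    peak per batch; when a batch offers two, the one nearer the consensus
    wins and the loser seeds a new cluster.  Clusters with a member from
    every batch become the common peaks, labelled X1..Xn in rt order.
    """
    if len(tables) < 2:
        raise ValueError("need at least two batches to match common peaks")
    for tab in tables:
        if len(tab) == 0:
            raise ValueError(f"batch {tab.batch_id!r} has an empty peak table")

    batch_ids = [t.batch_id for t in tables]
    pooled = []
    for tab in tables:
        for _, row in tab.peaks.iterrows():
            pooled.append((float(row["apex_rt"]), tab.batch_id, float(row["area"])))
    pooled.sort(key=lambda p: (p[0], p[1]))

    clusters: list[dict[str, tuple[float, float]]] = []

    def consensus(members: dict[str, tuple[float, float]]) -> float:
        return float(np.median([rt for rt, _ in members.values()]))

    for rt, batch, area in pooled:
        placed = False
        for members in reversed(clusters):  # recent clusters are nearest in rt
            c = consensus(members)
            if abs(rt - c) > rt_tolerance:
                continue
            if batch not in members:
                members[batch] = (rt, area)
                placed = True
            elif abs(rt - c) < abs(members[batch][0] - c):
                loser = members[batch]
                members[batch] = (rt, area)
                clusters.append({batch: loser})
                placed = True
            else:
                clusters.append({batch: (rt, area)})
                placed = True
            break
        if not placed:
            clusters.append({batch: (rt, area)})

    common = [m for m in clusters if set(m) == set(batch_ids)]
    if not common:
        raise ValueError("no peak is shared by all batches within the rt tolerance")
    common.sort(key=consensus)

    peak_ids = [f"X{i + 1}" for i in range(len(common))]
    rts = np.array([consensus(m) for m in common])
    data = {
        pid: [members[b][1] for b in batch_ids]
        for pid, members in zip(peak_ids, common)
    }
    areas = pd.DataFrame(data, index=pd.Index(batch_ids, name="batch"))
    return CommonPeakMatrix(peak_ids, rts, areas)


def reference_fingerprint(
    matrix: CommonPeakMatrix, method: Literal["mean", "median"] = "mean"
) -> pd.Series:
    """Consensus area vector ("R" fingerprint): column-wise mean or median."""
    if method == "mean":
        return matrix.areas.mean(axis=0)
    if method == "median":
        return matrix.areas.median(axis=0)
    raise ValueError(f"unknown reference method {method!r}; use 'mean' or 'median'")


def similarity(
    v: Iterable[float],
    ref: Iterable[float],
    method: Literal["cosine", "pearson"] = "cosine",
) -> float:
    """Congruence between a batch's peak-area vector and the reference.

    ``cosine`` is the uncentred congruence coefficient v.ref/(|v||ref|), the
    convention of fingerprint-similarity software for herbal preparations;
    ``pearson`` is the same coefficient after centring both vectors.
    """
    v = np.asarray(list(v), dtype=float)
    ref = np.asarray(list(ref), dtype=float)
    if v.shape != ref.shape or v.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if method == "pearson":
        v = v - v.mean()
        ref = ref - ref.mean()
    elif method != "cosine":
        raise ValueError(f"unknown similarity method {method!r}")
    nv, nr = np.linalg.norm(v), np.linalg.norm(ref)
    if nv == 0 or nr == 0:
        raise ValueError("similarity undefined for a zero-norm vector")
    return float(np.dot(v, ref) / (nv * nr))


def similarity_table(
    matrix: CommonPeakMatrix,
    ref: pd.Series | None = None,
    method: Literal["cosine", "pearson"] = "cosine",
) -> pd.Series:
    """Per-batch similarity against the reference fingerprint (mean by default)."""
    if ref is None:
        ref = reference_fingerprint(matrix)
    return pd.Series(
        {b: similarity(matrix.areas.loc[b], ref, method) for b in matrix.areas.index},
        name="similarity",
    )


def trace_similarity(a: Chromatogram, b: Chromatogram, n_grid: int = 2000) -> float:
    """Whole-trace cosine similarity after resampling both traces to a shared grid."""
    lo = max(a.time[0], b.time[0])
    hi = min(a.time[-1], b.time[-1])
    if hi <= lo:
        raise ValueError("traces do not overlap in time")
    grid = np.linspace(lo, hi, n_grid)
    ya = np.interp(grid, a.time, a.intensity)
    yb = np.interp(grid, b.time, b.intensity)
    return similarity(ya, yb, "cosine")
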