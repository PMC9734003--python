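"""Synthetic data generators with known ground truth.

Raw chromatograms and per-animal tension traces for this kind of study are
rarely deposited; these generators emulate them so that every downstream
stage (peak detection, matching, similarity, bioassay statistics, GRA/PLSR
screening) can be tested against a planted truth.

Conventions: peaks are pure Gaussians (closed-form area h*sigma*sqrt(2*pi));
multiplicative noise on areas and tensions is mean-preserving lognormal so
values stay positive; retention-time jitter is Gaussian.  Every generator
draws from a single numpy Generator seeded from its config, so identical
config + seed reproduces outputs bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bioassay import BioassayRecord
from .fingerprint import Chromatogram, CommonPeakMatrix

__all__ = [
    "PeakDef",
    "BatchSimConfig",
    "BioassaySimConfig",
    "EffectSimTruth",
    "simulate_chromatogram",
    "simulate_batch_set",
    "simulate_bioassay",
    "simulate_spectrum_effect",
    "default_time_grid",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class PeakDef:
    """One Gaussian peak: apex at ``rt`` minutes, ``height`` intensity units,
    standard-deviation width ``sigma`` minutes."""

    id: str
    rt: float
    height: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"peak {self.id}: sigma must be positive")
        if self.height < 0:
            raise ValueError(f"peak {self.id}: height must be non-negative")

    @property
    def area(self) -> float:
        """Closed-form Gaussian area, height * sigma * sqrt(2*pi)."""
        return self.height * self.sigma * _SQRT_2PI


@dataclass(frozen=True)
class BatchSimConfig:
    """Settings for a multi-batch fingerprint simulation.

    Defaults mirror the study design being emulated: 15 batches sharing 20
    common peaks, ~10% batch-to-batch area variation, 0.05 min retention
    jitter, and up to 3 batch-unique peaks per batch.
    """

    n_batches: int = 15
    n_common_peaks: int = 20
    area_cv: float = 0.10
    rt_jitter_sd: float = 0.05
    unique_peaks_range: tuple[int, int] = (0, 3)
    baseline: tuple[float, float] = (0.0, 2.0)  # (drift slope per minute, offset)
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 2:
            raise ValueError("need at least two batches")
        if not 0 <= self.area_cv < 1:
            raise ValueError("area_cv must lie in [0, 1)")
        if self.rt_jitter_sd < 0:
            raise ValueError("rt_jitter_sd must be non-negative")
        lo, hi = self.unique_peaks_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid unique_peaks_range")


@dataclass(frozen=True)
class BioassaySimConfig:
    """Settings for one batch's organ-bath simulation.

    Tension means are in grams; the drug effect follows an Emax-style
    hyperbola from the model tension down towards ``floor`` with midpoint
    ``ic50`` (mg/mL).  Defaults sit in the range of the tensions and doses
    the emulated assay reports (control ~0.45 g, Ach model ~1.25 g, doses
    15/25/35 mg/mL, n = 6 preparations).
    """

    n_animals: int = 6
    control_mean: float = 0.45
    model_mean: float = 1.25
    ic50: float = 12.0
    floor: float = 0.30
    doses: tuple[float, ...] = (15.0, 25.0, 35.0)
    animal_cv: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")
        if not self.model_mean > self.control_mean:
            raise ValueError("model tension must exceed control tension")
        if any(d <= 0 for d in self.doses) or list(self.doses) != sorted(self.doses):
            raise ValueError("doses must be positive and ascending")
        if self.animal_cv < 0:
            raise ValueError("animal_cv must be non-negative")


@dataclass(frozen=True)
class EffectSimTruth:
    """Planted truth for screening-recovery tests: which peaks drive the
    effect and with what signed weight on the z-scored column."""

    active_peak_ids: tuple[str, ...]
    coefficients: tuple[float, ...]
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.active_peak_ids:
            raise ValueError("active set must be non-empty")
        if len(self.active_peak_ids) != len(self.coefficients):
            raise ValueError("one coefficient per active peak")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_time_grid(t_max: float = 100.0, dt: float = 0.02) -> np.ndarray:
    """Uniform acquisition grid in minutes (default 0-100 min at 0.02 min)."""
    return np.arange(0.0, t_max + dt / 2, dt)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def simulate_chromatogram(
    peaks: Sequence[PeakDef],
    grid: np.ndarray,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
    batch_id: str = "sim",
) -> Chromatogram:
    """Sum-of-Gaussians trace plus linear baseline drift and Gaussian noise."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty time grid")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    for p in peaks:
        if not grid[0] <= p.rt <= grid[-1]:
            raise ValueError(f"peak {p.id!r} rt {p.rt} outside grid span "
                             f"[{grid[0]}, {grid[-1]}]")
    slope, offset = baseline
    y = slope * grid + offset
    for p in peaks:
        y = y + p.height * np.exp(-((grid - p.rt) ** 2) / (2.0 * p.sigma**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=grid.size)
    return Chromatogram(batch_id, grid, y)


def _common_peak_panel(cfg: BatchSimConfig, rng: np.random.Generator) -> list[PeakDef]:
    """Shared peak panel: apexes spread over 5-95 min with >= 2 min spacing,
    varied heights and widths (largest peaks ~10x the smallest)."""
    n = cfg.n_common_peaks
    span_lo, span_hi = 5.0, 95.0
    base = np.linspace(span_lo, span_hi, n)
    gap = (span_hi - span_lo) / max(n - 1, 1)
    rts = base + rng.uniform(-0.2 * gap, 0.2 * gap, size=n)
    heights = rng.uniform(30.0, 300.0, size=n)
    sigmas = rng.uniform(0.10, 0.18, size=n)
    return [
        PeakDef(f"P{i + 1:02d}", float(rts[i]), float(heights[i]), float(sigmas[i]))
        for i in range(n)
    ]


def simulate_batch_set(
    cfg: BatchSimConfig,
    grid: np.ndarray | None = None,
) -> tuple[list[Chromatogram], pd.DataFrame]:
    """Generate one multi-batch chromatogram set and its ground-truth table.

    Every batch carries all common peaks, with per-batch lognormal area
    multipliers (CV = ``area_cv``, applied to height so the Gaussian area
    scales identically) and Gaussian rt jitter.  Batch-unique peaks are
    placed at least 1 min away from every common apex and from each other;
    placement is retried up to 100 times before failing.

    Returns the chromatograms (batch ids S1..Sn) and a truth table with
    columns batch, peak_id, rt, area, is_common.
    """
    if grid is None:
        grid = default_time_grid()
    rng = np.random.default_rng(cfg.seed)
    panel = _common_peak_panel(cfg, rng)

    chroms: list[Chromatogram] = []
    truth_rows = []
    lo_u, hi_u = cfg.unique_peaks_range
    for b in range(cfg.n_batches):
        batch_id = f"S{b + 1}"
        mult = _lognormal_factors(rng, cfg.area_cv, cfg.n_common_peaks)
        jitter = (
            rng.normal(0.0, cfg.rt_jitter_sd, size=cfg.n_common_peaks)
            if cfg.rt_jitter_sd > 0
            else np.zeros(cfg.n_common_peaks)
        )
        batch_peaks = []
        for k, p in enumerate(panel):
            rt = float(np.clip(p.rt + jitter[k], grid[0], grid[-1]))
            batch_peaks.append(PeakDef(p.id, rt, p.height * float(mult[k]), p.sigma))

        n_unique = int(rng.integers(lo_u, hi_u + 1)) if hi_u > lo_u else lo_u
        taken = [pk.rt for pk in batch_peaks]
        for u in range(n_unique):
            for attempt in range(100):
                rt = float(rng.uniform(grid[0] + 2.0, grid[-1] - 2.0))
                if all(abs(rt - t) > 1.0 for t in taken):
                    break
            else:
                raise RuntimeError(
                    "could not place a batch-unique peak clear of common peaks "
                    "after 100 attempts"
                )
            taken.append(rt)
            batch_peaks.append(
                PeakDef(
                    f"{batch_id}-U{u + 1}",
                    rt,
                    float(rng.uniform(30.0, 150.0)),
                    float(rng.uniform(0.10, 0.18)),
                )
            )

        noise_seed = int(rng.integers(0, 2**31 - 1))
        chroms.append(
            simulate_chromatogram(
                batch_peaks, grid, baseline=cfg.baseline,
                noise_sd=cfg.noise_sd, seed=noise_seed, batch_id=batch_id,
            )
        )
        for pk in batch_peaks:
            truth_rows.append(
                {"batch": batch_id, "peak_id": pk.id, "rt": pk.rt,
                 "area": pk.area, "is_common": not pk.id.startswith(batch_id)}
            )
    truth = pd.DataFrame(truth_rows, columns=["batch", "peak_id", "rt", "area", "is_common"])
    return chroms, truth


def simulate_bioassay(cfg: BioassaySimConfig, batch_id: str = "S1") -> BioassayRecord:
    """One batch's organ-bath experiment with per-animal tensions.

    Stage means: control and model at their configured values; at dose C the
    drug-group mean is model_mean - (model_mean - floor) * C / (C + ic50).
    Each animal's tension is the stage mean times a mean-1 lognormal factor
    (CV = ``animal_cv``).  Group summaries and per-animal-paired inhibition
    rates are derived from the same draws.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_animals
    stage_means = {"control": cfg.control_mean, "model": cfg.model_mean}
    for c in cfg.doses:
        stage_means[f"dose_{c:g}"] = cfg.model_mean - (
            cfg.model_mean - cfg.floor
        ) * c / (c + cfg.ic50)

    rows = []
    for group, mu in stage_means.items():
        factors = _lognormal_factors(rng, cfg.animal_cv, n)
        for i in range(n):
            rows.append(
                {"group": group, "animal": i + 1, "tension_g": mu * float(factors[i])}
            )
    animals = pd.DataFrame(rows)

    summaries = (
        animals.groupby("group", sort=False)["tension_g"]
        .agg(mean="mean", sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)), n="count")
        .reset_index()
    )

    wide = animals.pivot(index="animal", columns="group", values="tension_g")
    inh_rows = []
    for c in cfg.doses:
        g = f"dose_{c:g}"
        rates = 100.0 * (wide["model"] - wide[g]) / (wide["model"] - wide["control"])
        inh_rows.append(
            {"dose": c, "mean": float(rates.mean()),
             "sem": float(rates.std(ddof=1) / math.sqrt(n))}
        )
    inhibition = pd.DataFrame(inh_rows)
    return BioassayRecord(batch_id, summaries, animals=animals, inhibition=inhibition)


def simulate_spectrum_effect(
    n_batches: int,
    n_peaks: int,
    truth: EffectSimTruth,
) -> tuple[CommonPeakMatrix, np.ndarray]:
    """X/Y pair in which a known peak subset linearly drives the effect.

    X entries are positive (lognormal areas, per-peak scale); the effect is
    Y_i = sum over active peaks of coef * zscore(X column)_i plus
    Normal(0, noise_sd) noise.
    """
    peak_ids = [f"X{i + 1}" for i in range(n_peaks)]
    missing = set(truth.active_peak_ids) - set(peak_ids)
    if missing:
        raise ValueError(f"active peaks not in panel: {sorted(missing)}")
    rng = np.random.default_rng(truth.seed)
    scales = rng.uniform(np.log(10.0), np.log(1000.0), size=n_peaks)
    X = pd.DataFrame(
        rng.lognormal(mean=scales, sigma=0.3, size=(n_batches, n_peaks)),
        index=pd.Index([f"S{i + 1}" for i in range(n_batches)], name="batch"),
        columns=peak_ids,
    )
    y = np.zeros(n_batches)
    for pid, coef in zip(truth.active_peak_ids, truth.coefficients):
        col = X[pid].to_numpy()
        y = y + coef * (col - col.mean()) / col.std(ddof=1)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=n_batches)
    matrix = CommonPeakMatrix(peak_ids, np.arange(1, n_peaks + 1, dtype=float), X)
    return matrix, y
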