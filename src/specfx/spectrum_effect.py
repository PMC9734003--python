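"""Spectrum-effect screening: grey relational analysis, PLS1 regression with
VIP scores, and the three-way active-peak selection rule.

X is the batches x peaks matrix (areas or calibrated contents), Y the
per-batch pharmacological effect (here: inhibition rate of agonist-evoked
contraction).  Peaks that (i) track Y closely in Deng's grey relational
sense (grade > 0.8), (ii) carry above-average weight in the PLS projection
(VIP > 1), and (iii) have a positive standardised regression coefficient are
reported as the putative bioactive constituents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "zscore",
    "zscore_matrix",
    "SpectrumEffectInput",
    "GRAConfig",
    "GRAResult",
    "gra",
    "PLSRModel",
    "plsr_nipals",
    "vip",
    "loo_rmse",
    "ScreeningResult",
    "select_active",
    "screen",
]


def zscore(series: Sequence[float]) -> np.ndarray:
    """Standardise to mean 0 and sample (n-1) standard deviation 1."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("z-score needs at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("z-score undefined for a constant series")
    return (x - x.mean()) / sd


def zscore_matrix(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores; constant columns are dropped with a warning."""
    sds = X.std(ddof=1)
    constant = [c for c in X.columns if not sds[c] > 0]
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    return (X - X.mean()) / X.std(ddof=1)


@dataclass
class SpectrumEffectInput:
    """Aligned X (batches x peaks) and Y (per-batch effect) matrices."""

    X: pd.DataFrame
    y: np.ndarray
    peak_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        if not self.peak_ids:
            self.peak_ids = list(self.X.columns)
        if list(self.X.columns) != self.peak_ids:
            self.X = self.X[self.peak_ids]
        if len(self.X) != self.y.size:
            raise ValueError("X and Y must have the same number of batches")
        if len(self.X) < 3:
            raise ValueError("need at least 3 batches")
        if self.X.isna().any().any() or np.isnan(self.y).any():
            raise ValueError("missing cells are not allowed")


@dataclass(frozen=True)
class GRAConfig:
    """Grey relational analysis settings.

    rho is Deng's resolution coefficient (conventionally 0.5); normalisation
    is applied to Y and every X column before the difference sequences are
    formed (``initial-value`` divides each series by its first element).
    """

    rho: float = 0.5
    normalisation: Literal["zscore", "initial-value", "none"] = "zscore"

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("rho must lie in (0, 1]")


@dataclass
class GRAResult:
    grades: pd.Series          # per peak, in (0, 1]
    ranks: pd.Series           # 1 = highest grade; ties broken by peak label
    coefficients: pd.DataFrame  # per-point relational coefficients, batches x peaks


def _normalise(v: np.ndarray, how: str) -> np.ndarray:
    if how == "zscore":
        return zscore(v)
    if how == "initial-value":
        if v[0] == 0:
            raise ValueError("initial-value normalisation undefined when the first element is 0")
        return v / v[0]
    if how == "none":
        return np.asarray(v, dtype=float)
    raise ValueError(f"unknown normalisation {how!r}")


def gra(inp: SpectrumEffectInput, cfg: GRAConfig = GRAConfig()) -> GRAResult:
    """Deng's grey relational grade of every peak series against the effect.

    After normalisation, Delta_ik = |y_i - x_ik|.  With the two-level
    extrema Delta_min / Delta_max taken over ALL points (i, k), the
    relational coefficient is

        xi_ik = (Delta_min + rho * Delta_max) / (Delta_ik + rho * Delta_max)

    and the grade of peak k is the unweighted mean of xi_ik over batches.
    """
    y = _normalise(inp.y, cfg.normalisation)
    cols = {}
    for pid in inp.peak_ids:
        cols[pid] = _normalise(inp.X[pid].to_numpy(), cfg.normalisation)
    delta = pd.DataFrame(
        {pid: np.abs(y - x) for pid, x in cols.items()}, index=inp.X.index
    )
    dmin = float(delta.to_numpy().min())
    dmax = float(delta.to_numpy().max())
    if dmax == 0:
        warnings.warn("all X columns identical to Y: every grade is 1", stacklevel=2)
        xi = delta * 0.0 + 1.0
    else:
        xi = (dmin + cfg.rho * dmax) / (delta + cfg.rho * dmax)
    grades = xi.mean(axis=0)
    order = sorted(grades.index, key=lambda p: (-grades[p], p))
    ranks = pd.Series({p: i + 1 for i, p in enumerate(order)}, name="rank")
    return GRAResult(grades=grades.rename("grade"), ranks=ranks.loc[grades.index], coefficients=xi)


@dataclass
class PLSRModel:
    """PLS1 fit on autoscaled X and y.

    W, T, P are the per-component weight, score and loading matrices; q the
    response loadings.  ``coef_std`` are regression coefficients on the
    autoscaled (z-score) scale, ``coef_raw``/``intercept_raw`` map back to
    the original units.  ``ssy`` is the response variance captured per
    component, q_a^2 * (t_a . t_a).
    """

    peak_ids: list[str]
    n_components: int
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    coef_std: pd.Series
    coef_raw: pd.Series
    intercept_raw: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    ssy: np.ndarray

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        Xv = X[self.peak_ids].to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return Xv @ self.coef_raw.to_numpy() + self.intercept_raw


def plsr_nipals(
    inp: SpectrumEffectInput,
    n_components: int = 2,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSRModel:
    """NIPALS PLS1 on autoscaled data.

    Per component: w = X'y / ||X'y||, t = Xw, p = X't/(t't), q = y't/(t't);
    X and y are then deflated by t p' and t q.  (With a univariate response
    the NIPALS inner loop converges in one pass, so no iteration is needed;
    ``tol``/``max_iter`` guard the degenerate-deflation checks.)
    Coefficients B = W (P'W)^-1 q on the autoscaled scale are also mapped
    back to original units.
    """
    n, p = inp.X.shape
    a_max = min(n - 1, p)
    if not 1 <= n_components <= a_max:
        raise ValueError(f"n_components must be in [1, {a_max}]")
    x_mean = inp.X.mean().to_numpy()
    x_sd = inp.X.std(ddof=1).to_numpy()
    if np.any(x_sd == 0):
        bad = [pid for pid, s in zip(inp.peak_ids, x_sd) if s == 0]
        raise ValueError(f"constant predictor columns: {bad}")
    y_mean = float(inp.y.mean())
    y_sd = float(inp.y.std(ddof=1))
    if y_sd == 0:
        raise ValueError("constant response")

    Xw = (inp.X.to_numpy() - x_mean) / x_sd
    yw = (inp.y - y_mean) / y_sd

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        xty = Xw.T @ yw
        norm = np.linalg.norm(xty)
        if norm < tol:
            raise ValueError(
                f"no residual covariance between X and y at component {a + 1}"
            )
        w = xty / norm
        t = Xw @ w
        tt = float(t @ t)
        if tt < tol:
            raise ValueError(f"degenerate score vector at component {a + 1}")
        pvec = Xw.T @ t / tt
        qa = float(yw @ t / tt)
        Xw = Xw - np.outer(t, pvec)
        yw = yw - t * qa
        W[:, a], T[:, a], P[:, a], q[a] = w, t, pvec, qa

    b_std = W @ np.linalg.solve(P.T @ W, q)
    coef_std = pd.Series(b_std, index=inp.peak_ids, name="coefficient")
    coef_raw = coef_std * y_sd / x_sd
    intercept = y_mean - float(coef_raw.to_numpy() @ x_mean)
    ssy = q**2 * np.einsum("ia,ia->a", T, T)
    return PLSRModel(
        peak_ids=list(inp.peak_ids), n_components=n_components,
        W=W, T=T, P=P, q=q,
        coef_std=coef_std, coef_raw=coef_raw.rename("coefficient_raw"),
        intercept_raw=intercept,
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd, ssy=ssy,
    )


def vip(model: PLSRModel) -> pd.Series:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a[ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a ),
    where SSY_a is the response variance captured by component a.  The VIPs
    satisfy sum_j VIP_j^2 = p, so VIP > 1 marks an above-average contributor.
    """
    total = model.ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance")
    wnorm = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    p = len(model.peak_ids)
    v = np.sqrt(p * (wnorm**2 @ model.ssy) / total)
    return pd.Series(v, index=model.peak_ids, name="vip")


def loo_rmse(inp: SpectrumEffectInput, n_components: int) -> float:
    """Leave-one-out root-mean-square prediction error for a component count."""
    n = len(inp.X)
    errs = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        sub = SpectrumEffectInput(inp.X.iloc[mask], inp.y[mask], list(inp.peak_ids))
        model = plsr_nipals(sub, n_components=n_components)
        pred = model.predict(inp.X.iloc[[i]])
        errs.append(float(pred[0] - inp.y[i]))
    return float(np.sqrt(np.mean(np.square(errs))))


@dataclass
class ScreeningResult:
    """Per-peak screening report and the selected active set.

    ``selected`` holds the peaks meeting all three criteria (grade, VIP,
    positive coefficient); ``two_of_three`` surfaces borderline peaks that
    meet exactly two, so near-misses are visible rather than silently
    dropped.
    """

    table: pd.DataFrame
    selected: list[str]
    two_of_three: list[str]
    thresholds: dict

    def report_text(self) -> str:
        lines = ["Spectrum-effect screening report", "=" * 34, ""]
        lines.append(
            f"criteria: grade > {self.thresholds['grade']}, "
            f"VIP > {self.thresholds['vip']}, coefficient > 0"
        )
        lines.append("")
        lines.append(self.table.to_string(float_format=lambda x: f"{x:.4f}"))
        lines.append("")
        lines.append(f"selected (all three criteria): {', '.join(self.selected) or 'none'}")
        lines.append(f"borderline (exactly two criteria): {', '.join(self.two_of_three) or 'none'}")
        return "\n".join(lines)


def select_active(
    grades: pd.Series,
    coefficients: pd.Series,
    vips: pd.Series,
    g_thr: float = 0.8,
    v_thr: float = 1.0,
) -> ScreeningResult:
    """Intersection rule: active = grade > g_thr AND VIP > v_thr AND coef > 0."""
    if not (list(grades.index) == list(coefficients.index) == list(vips.index)):
        raise ValueError("grades, coefficients and VIPs must share one peak index")
    table = pd.DataFrame(
        {
            "grade": grades,
            "coefficient": coefficients,
            "vip": vips,
            "pass_grade": grades > g_thr,
            "pass_vip": vips > v_thr,
            "pass_sign": coefficients > 0,
        }
    )
    table["n_criteria"] = table[["pass_grade", "pass_vip", "pass_sign"]].sum(axis=1)
    selected = [p for p in table.index if table.loc[p, "n_criteria"] == 3]
    two = [p for p in table.index if table.loc[p, "n_criteria"] == 2]
    return ScreeningResult(
        table=table, selected=selected, two_of_three=two,
        thresholds={"grade": g_thr, "vip": v_thr},
    )


def screen(
    inp: SpectrumEffectInput,
    gra_cfg: GRAConfig = GRAConfig(),
    n_components: int = 2,
    g_thr: float = 0.8,
    v_thr: float = 1.0,
) -> tuple[ScreeningResult, GRAResult, PLSRModel]:
    """Run the full GRA + PLSR + intersection screening on one X/Y pair."""
    gres = gra(inp, gra_cfg)
    model = plsr_nipals(inp, n_components=n_components)
    vips = vip(model)
    result = select_active(
        gres.grades, model.coef_std, vips, g_thr=g_thr, v_thr=v_thr
    )
    return result, gres, model
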