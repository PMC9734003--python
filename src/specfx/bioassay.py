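"""Organ-bath smooth-muscle bioassay statistics.

An isolated intestine segment is equilibrated (control tension), contracted
with acetylcholine (model tension), then relaxed by cumulative drug doses.
The module computes inhibition rates anchored at the model (0%) and control
(100%) tensions, and significance statistics reconstructed from group
summaries (mean, SEM, n) or from per-animal tensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "BioassayRecord",
    "inhibition_rate",
    "inhibition_from_animals",
    "welch_from_summary",
    "anova_oneway_from_summary",
    "flag_significance",
    "bioassay_stats",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary of one treatment group: mean tension (g), SEM (g), group size."""

    group: str
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")
        if self.n < 2:
            raise ValueError("group size must be at least 2")


@dataclass
class BioassayRecord:
    """One batch's bioassay outcome.

    ``summaries`` is always present (group, mean, sem, n).  ``animals`` holds
    per-animal tensions when available, with columns group, animal, tension_g;
    animal indices pair the same intestine preparation across the cumulative
    dosing stages.  ``inhibition`` has columns dose, mean, sem (percent).
    """

    batch_id: str
    summaries: pd.DataFrame
    animals: pd.DataFrame | None = None
    inhibition: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        need = {"group", "mean", "sem", "n"}
        if not need.issubset(self.summaries.columns):
            raise ValueError(f"summaries must have columns {sorted(need)}")
        if self.animals is not None:
            for grp, sub in self.animals.groupby("group"):
                row = self.summaries.loc[self.summaries["group"] == grp]
                if len(row) and abs(sub["tension_g"].mean() - float(row["mean"].iloc[0])) > 1e-9:
                    raise ValueError(
                        f"summary mean for group {grp!r} inconsistent with per-animal data"
                    )

    def group(self, name: str) -> GroupSummary:
        row = self.summaries.loc[self.summaries["group"] == name]
        if row.empty:
            raise KeyError(f"no group {name!r} in batch {self.batch_id}")
        r = row.iloc[0]
        return GroupSummary(name, float(r["mean"]), float(r["sem"]), int(r["n"]))


def inhibition_rate(t_control: float, t_model: float, t_drug: float) -> float:
    """Percent reversal of the agonist-evoked contraction.

    100 * (T_model - T_drug) / (T_model - T_control): 0% at the model tension,
    100% at the pre-agonist control tension.  Values above 100% occur when the
    drug relaxes the tissue below its control tone.  Invariant to a common
    rescaling of all three tensions.
    """
    if not t_model > t_control:
        raise ValueError("inhibition undefined: model tension must exceed control tension")
    return 100.0 * (t_model - t_drug) / (t_model - t_control)


def inhibition_from_animals(animals: pd.DataFrame, dose_group: str) -> tuple[float, float]:
    """Per-animal inhibition rates paired across stages of the cumulative protocol.

    Each animal's own control and model tensions anchor its rate; the group
    rate is the mean +/- SEM over animals.  This per-animal averaging differs
    from (and with tissue-to-tissue variation, does not equal) the rate
    computed from group means.
    """
    wide = animals.pivot(index="animal", columns="group", values="tension_g")
    for col in ("control", "model", dose_group):
        if col not in wide.columns:
            raise KeyError(f"missing group {col!r} in per-animal data")
    rates = wide.apply(
        lambda r: inhibition_rate(r["control"], r["model"], r[dose_group]), axis=1
    )
    return float(rates.mean()), float(rates.std(ddof=1) / np.sqrt(len(rates)))


def welch_from_summary(
    m1: float, sem1: float, n1: int, m2: float, sem2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test reconstructed from (mean, SEM, n).

    t = (m1 - m2)/sqrt(sem1^2 + sem2^2); degrees of freedom by the
    Welch-Satterthwaite approximation on the squared SEMs; two-sided p from
    the t distribution.
    """
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sem1 == 0 and sem2 == 0:
        raise ValueError("both SEMs are zero; t undefined")
    se2 = sem1**2 + sem2**2
    t = (m1 - m2) / np.sqrt(se2)
    df = se2**2 / (sem1**4 / (n1 - 1) + sem2**4 / (n2 - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def anova_oneway_from_summary(groups: Sequence[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from group summaries.

    Group SDs are recovered as sem * sqrt(n); between/within sums of squares
    follow from means and SDs alone.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups])
    sds = np.array([g.sem * np.sqrt(g.n) for g in groups])
    grand = float(np.sum(ns * means) / np.sum(ns))
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(np.sum((ns - 1) * sds**2))
    df_between = len(groups) - 1
    df_within = int(np.sum(ns)) - len(groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance; F undefined")
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), df_between, df_within, p


def _marker(p: float, symbol: str) -> str:
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value must lie in [0, 1]")
    if p < 0.01:
        return symbol * 2
    if p < 0.05:
        return symbol
    return ""


def flag_significance(p_vs_control: float, p_vs_model: float) -> tuple[str, str]:
    """Significance markers at the 0.05 / 0.01 thresholds (strict inequality).

    Returns ('#' style marker vs control, '*' style marker vs model).
    """
    return _marker(p_vs_control, "#"), _marker(p_vs_model, "*")


def bioassay_stats(record: BioassayRecord, dose_groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Welch tests and markers for every dose group of one batch.

    Each dose group is compared against the model group; the model group is
    compared against the control group.  Output columns: group, t, df, p,
    marker_vs_control, marker_vs_model.
    """
    control = record.group("control")
    model = record.group("model")
    if dose_groups is None:
        dose_groups = [
            g for g in record.summaries["group"] if g not in ("control", "model")
        ]
    rows = []
    t, df, p = welch_from_summary(
        model.mean, model.sem, model.n, control.mean, control.sem, control.n
    )
    rows.append(
        {"group": "model", "t": t, "df": df, "p": p,
         "marker_vs_control": _marker(p, "#"), "marker_vs_model": ""}
    )
    for g in dose_groups:
        grp = record.group(g)
        t, df, p = welch_from_summary(
            grp.mean, grp.sem, grp.n, model.mean, model.sem, model.n
        )
        rows.append(
            {"group": g, "t": t, "df": df, "p": p,
             "marker_vs_control": "", "marker_vs_model": _marker(p, "*")}
        )
    return pd.DataFrame(rows)
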