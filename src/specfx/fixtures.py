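"""Packaged in-study tables and typed accessors.

Four small CSV fixtures ship with the package: the calibration/validation
table (``table4``), the batches x compounds content matrix (``table5``), the
organ-bath group summaries with printed inhibition rates (``table6``), and
the printed grey-relational grades (``table7``).  ``load_fixture`` returns
the raw table; the helpers below convert them into the package's domain
objects.
"""

from __future__ import annotations

from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd

from .bioassay import BioassayRecord
from .quantification import CalibrationCurve

__all__ = [
    "FIXTURE_NAMES",
    "load_fixture",
    "calibration_curves",
    "content_matrix",
    "bioassay_record",
    "bioassay_batches",
    "effect_vector",
    "printed_gra_grades",
]

_FILES = {
    "table4": "table4_calibration.csv",
    "table5": "table5_contents.csv",
    "table6": "table6_bioassay.csv",
    "table7": "table7_gra.csv",
}
FIXTURE_NAMES = tuple(_FILES)

_SCHEMAS = {
    "table4": {"peak", "compound", "slope", "intercept", "r",
               "linear_low_mg_ml", "linear_high_mg_ml"},
    "table5": {"peak", "compound"},
    "table6": {"batch", "group", "mean_g", "sem_g", "n"},
    "table7": {"peak", "grade", "rank"},
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged table by name (``table4`` .. ``table7``)."""
    if name not in _FILES:
        raise ValueError(f"unknown fixture {name!r}; valid names: {', '.join(_FILES)}")
    with resources.files("specfx.data").joinpath(_FILES[name]).open("r") as fh:
        df = pd.read_csv(fh)
    missing = _SCHEMAS[name] - set(df.columns)
    if missing:
        raise ValueError(f"fixture {name} missing columns {sorted(missing)}")
    return df


def calibration_curves() -> dict[str, CalibrationCurve]:
    """The 15 external-standard calibration curves, keyed by peak label."""
    df = load_fixture("table4")
    return {
        row["peak"]: CalibrationCurve(
            compound=row["compound"],
            slope=float(row["slope"]),
            intercept=float(row["intercept"]),
            r=float(row["r"]),
            linear_range=(float(row["linear_low_mg_ml"]), float(row["linear_high_mg_ml"])),
        )
        for _, row in df.iterrows()
    }


def content_matrix() -> pd.DataFrame:
    """Batches x compounds content matrix (mg/g), index S1..S15, columns X1..X19."""
    df = load_fixture("table5")
    batches = [c for c in df.columns if c.startswith("S")]
    out = df.set_index("peak")[batches].T
    out.index.name = "batch"
    out.columns.name = None
    return out.astype(float)


def bioassay_record(batch: str) -> BioassayRecord:
    """One batch's group summaries and printed inhibition rates."""
    df = load_fixture("table6")
    sub = df.loc[df["batch"] == batch]
    if sub.empty:
        raise KeyError(f"no batch {batch!r} in table6")
    summaries = sub.rename(
        columns={"mean_g": "mean", "sem_g": "sem"}
    )[["group", "mean", "sem", "n"]].reset_index(drop=True)
    inh = sub.dropna(subset=["inhibition_pct"])
    inhibition = pd.DataFrame(
        {
            "dose": [float(g.split("_")[1]) for g in inh["group"]],
            "mean": inh["inhibition_pct"].to_numpy(float),
            "sem": inh["inhibition_sem_pct"].to_numpy(float),
        }
    )
    return BioassayRecord(batch, summaries, animals=None, inhibition=inhibition)


def bioassay_batches() -> list[str]:
    df = load_fixture("table6")
    return list(dict.fromkeys(df["batch"]))


def effect_vector(dose: Literal["mean", "25", "35"] = "mean") -> pd.Series:
    """Per-batch effect Y: the printed inhibition rate (%).

    ``mean`` averages the 25 and 35 mg/mL columns (the study names "the
    inhibition rate" without fixing a dose); ``"25"``/``"35"`` pick a single
    dose column.
    """
    df = load_fixture("table6")
    wide = df.dropna(subset=["inhibition_pct"]).pivot(
        index="batch", columns="group", values="inhibition_pct"
    )
    wide = wide.loc[bioassay_batches()]
    if dose == "mean":
        y = wide[["dose_25", "dose_35"]].mean(axis=1)
    elif dose in ("25", "35"):
        y = wide[f"dose_{dose}"]
    else:
        raise ValueError(f"unknown dose selector {dose!r}")
    return y.rename("inhibition_pct")


def printed_gra_grades() -> pd.Series:
    """The published grey-relational grades, indexed by peak, in printed rank order."""
    df = load_fixture("table7").sort_values("rank")
    return pd.Series(df["grade"].to_numpy(float), index=df["peak"].tolist(), name="grade")
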