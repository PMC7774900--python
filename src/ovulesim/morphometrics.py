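"""Quantification of per-ovule measurement tables.

Each measured primordium is treated as a cylinder protruding from the
placenta, characterised by its basal diameter and height (both in µm), its
position along the placenta and the placenta's total length.  The analyses
here are the field's standard descriptive quantifications:

* shape classes — O1 (small bump, height much smaller than basal diameter),
  O2 (dome, height about equal to diameter), O3 (finger, height much larger
  than diameter), operationalised as cuts on the aspect ratio
  ``rho = height / basal_diameter`` (defaults 0.75 and 4/3, symmetric about
  rho = 1 on the log scale);
* the O1 fraction per floral stage (pooled and per placenta);
* ovule density = ovule count / placenta length;
* which third of the placenta (lower / middle / top, base = lower) a
  primordium sits in;
* an alternation index: the fraction of adjacent ovule pairs (ordered from
  the base) whose shape classes differ, capturing the alternating
  large/small arrangement of older and younger primordia.

Tables are plain pandas DataFrames with the documented ``MEASUREMENT_COLUMNS``
schema; stages are strings (``"8"``, ``"9a"``, ``"9b"``, ``"9c"``, ``"10"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

SHAPE_CLASSES = ("O1", "O2", "O3")
THIRDS = ("lower", "middle", "top")

MEASUREMENT_COLUMNS = ["placenta_id", "stage", "order_index",
                       "basal_diameter", "height", "position",
                       "placenta_length"]


class InvalidMeasurementError(ValueError):
    """A measurement violates the table contract (e.g. diameter <= 0)."""


@dataclass(frozen=True)
class ShapeThresholds:
    """Aspect-ratio cuts separating the O1/O2/O3 shape classes."""

    low: float = 0.75      # rho <= low  -> O1
    high: float = 4.0 / 3.0  # rho >= high -> O3

    def __post_init__(self) -> None:
        if not 0.0 < self.low < 1.0 < self.high:
            raise ValueError(
                f"need 0 < low < 1 < high, got low={self.low}, "
                f"high={self.high}")


@dataclass(frozen=True)
class OvuleMeasurement:
    """One measured primordium within a placenta at a floral stage."""

    placenta_id: str
    stage: str
    order_index: int          # 1-based rank from the placenta base
    basal_diameter: float     # µm, > 0
    height: float             # µm, >= 0
    position: float           # µm from the base along the placenta
    placenta_length: float    # µm, > 0

    def __post_init__(self) -> None:
        if self.basal_diameter <= 0:
            raise InvalidMeasurementError(
                f"basal_diameter must be > 0, got {self.basal_diameter}")
        if self.height < 0:
            raise InvalidMeasurementError(
                f"height must be >= 0, got {self.height}")
        if self.placenta_length <= 0:
            raise InvalidMeasurementError(
                f"placenta_length must be > 0, got {self.placenta_length}")
        if not 0.0 <= self.position <= self.placenta_length:
            raise InvalidMeasurementError(
                f"position {self.position} outside [0, "
                f"{self.placenta_length}]")
        if self.order_index < 1:
            raise InvalidMeasurementError("order_index is 1-based")


def classify_shape(measurement: Optional[OvuleMeasurement] = None,
                   thresholds: ShapeThresholds = ShapeThresholds(),
                   *, height: float = None, basal_diameter: float = None
                   ) -> str:
    """O1/O2/O3 class of one primordium from its aspect ratio.

    Accepts an :class:`OvuleMeasurement` or explicit ``height=``/
    ``basal_diameter=`` keywords.  Scale-invariant: multiplying both
    dimensions by the same factor leaves the class unchanged.
    """
    if isinstance(measurement, OvuleMeasurement):
        height, basal_diameter = measurement.height, measurement.basal_diameter
    if basal_diameter is None or height is None:
        raise TypeError("provide an OvuleMeasurement or height= and "
                        "basal_diameter=")
    if basal_diameter <= 0:
        raise InvalidMeasurementError(
            f"basal_diameter must be > 0, got {basal_diameter}")
    rho = height / basal_diameter
    if rho <= thresholds.low:
        return "O1"
    if rho >= thresholds.high:
        return "O3"
    return "O2"


def classify_table(table: pd.DataFrame,
                   thresholds: ShapeThresholds = ShapeThresholds()
                   ) -> pd.DataFrame:
    """Vectorised classification; returns a copy with a ``shape_class`` column."""
    if (table["basal_diameter"] <= 0).any():
        bad = table.index[table["basal_diameter"] <= 0][0]
        raise InvalidMeasurementError(
            f"row {bad}: basal_diameter must be > 0")
    rho = table["height"] / table["basal_diameter"]
    cls = np.where(rho <= thresholds.low, "O1",
                   np.where(rho >= thresholds.high, "O3", "O2"))
    out = table.copy()
    out["shape_class"] = cls
    return out


def o1_ratio(table: pd.DataFrame, stage: str,
             thresholds: ShapeThresholds = ShapeThresholds(),
             per_placenta: bool = False):
    """Fraction of O1 (young, small-bump) primordia at one floral stage.

    Pooled over all measurements by default; with ``per_placenta=True``
    returns ``(mean, sd)`` of the per-placenta fractions, the form shown in
    stage-course summaries.
    """
    sub = table[table["stage"].astype(str) == str(stage)]
    if len(sub) == 0:
        raise ValueError(f"no measurements at stage {stage!r}")
    sub = classify_table(sub, thresholds)
    is_o1 = sub["shape_class"] == "O1"
    if not per_placenta:
        return float(is_o1.mean())
    per = is_o1.groupby(sub["placenta_id"]).mean()
    return float(per.mean()), float(per.std(ddof=1)) if len(per) > 1 else 0.0


def ovule_density(table: pd.DataFrame, placenta_id,
                  allow_empty: bool = False) -> float:
    """Ovule count divided by placenta length (per µm) for one placenta."""
    sub = table[table["placenta_id"] == placenta_id]
    if len(sub) == 0:
        if allow_empty:
            return 0.0
        raise ValueError(f"placenta {placenta_id!r} has no ovules")
    length = float(sub["placenta_length"].iloc[0])
    if not np.isfinite(length) or length <= 0:
        raise ValueError(f"placenta {placenta_id!r} has no valid recorded "
                         f"length (got {length})")
    return len(sub) / length


def position_thirds(measurement: Union[OvuleMeasurement, float],
                    placenta_length: float = None) -> str:
    """Which third of the placenta a primordium occupies (base = lower).

    Thirds are the half-open intervals ``[0, L/3)``, ``[L/3, 2L/3)`` and
    ``[2L/3, L]``.
    """
    if isinstance(measurement, OvuleMeasurement):
        position = measurement.position
        placenta_length = measurement.placenta_length
    else:
        position = measurement
        if placenta_length is None:
            raise TypeError("provide an OvuleMeasurement or position and "
                            "placenta_length")
    if not 0.0 <= position <= placenta_length:
        raise ValueError(f"position {position} outside "
                         f"[0, {placenta_length}]")
    if position < placenta_length / 3.0:
        return "lower"
    if position < 2.0 * placenta_length / 3.0:
        return "middle"
    return "top"


def alternation_index(placenta: Union[pd.DataFrame, Sequence[str]],
                      thresholds: ShapeThresholds = ShapeThresholds()
                      ) -> float:
    """Fraction of adjacent ovule pairs whose shape classes differ.

    1.0 for a strictly alternating arrangement, 0.0 for a uniform one; NaN
    for fewer than two ovules.  Accepts a single-placenta measurement table
    (ordered by ``order_index``) or a plain sequence of class labels.
    """
    if isinstance(placenta, pd.DataFrame):
        sub = placenta.sort_values("order_index")
        if "shape_class" not in sub.columns:
            sub = classify_table(sub, thresholds)
        classes = list(sub["shape_class"])
    else:
        classes = list(placenta)
    if len(classes) < 2:
        return float("nan")
    diffs = sum(1 for u, v in zip(classes, classes[1:]) if u != v)
    return diffs / (len(classes) - 1)


def summarize_placentae(table: pd.DataFrame,
                        thresholds: ShapeThresholds = ShapeThresholds()
                        ) -> pd.DataFrame:
    """Per-placenta summary: counts, length, density, O1 ratio, alternation.

    Rows are ordered by stage then placenta id (deterministic).
    """
    if len(table) == 0:
        return pd.DataFrame(columns=["stage", "placenta_id", "n_ovules",
                                     "placenta_length", "density",
                                     "o1_ratio", "alternation_index"])
    cls = classify_table(table, thresholds)
    rows = []
    for (stage, pid), grp in cls.groupby(["stage", "placenta_id"]):
        length = float(grp["placenta_length"].iloc[0])
        rows.append({
            "stage": stage,
            "placenta_id": pid,
            "n_ovules": len(grp),
            "placenta_length": length,
            "density": len(grp) / length,
            "o1_ratio": float((grp["shape_class"] == "O1").mean()),
            "alternation_index": alternation_index(grp, thresholds),
        })
    out = pd.DataFrame(rows)
    return out.sort_values(["stage", "placenta_id"]).reset_index(drop=True)


def summarize_stage(table: pd.DataFrame,
                    thresholds: ShapeThresholds = ShapeThresholds()
                    ) -> pd.DataFrame:
    """Per-stage report aggregating the per-placenta summaries.

    Columns: stage, n_placentae, ovules mean±s.d., placenta length
    mean±s.d., density mean, O1 ratio mean±s.d., alternation mean.  Rows are
    ordered by stage.
    """
    per = summarize_placentae(table, thresholds)
    if len(per) == 0:
        return pd.DataFrame(columns=[
            "stage", "n_placentae", "n_ovules_mean", "n_ovules_sd",
            "placenta_length_mean", "placenta_length_sd", "density_mean",
            "o1_ratio_mean", "o1_ratio_sd", "alternation_mean"])
    rows = []
    for stage, grp in per.groupby("stage"):
        rows.append({
            "stage": stage,
            "n_placentae": len(grp),
            "n_ovules_mean": float(grp["n_ovules"].mean()),
            "n_ovules_sd": float(grp["n_ovules"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "placenta_length_mean": float(grp["placenta_length"].mean()),
            "placenta_length_sd": float(grp["placenta_length"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "density_mean": float(grp["density"].mean()),
            "o1_ratio_mean": float(grp["o1_ratio"].mean()),
            "o1_ratio_sd": float(grp["o1_ratio"].std(ddof=1)) if len(grp) > 1 else 0.0,
            "alternation_mean": float(grp["alternation_index"].mean()),
        })
    return pd.DataFrame(rows).sort_values("stage").reset_index(drop=True)


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV and check the documented schema."""
    df = pd.read_csv(path, dtype={"stage": str, "placenta_id": str})
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) "
                         f"{sorted(missing)}")
    return df


def write_measurements(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
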