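"""Uncertainty budgets for stereotactic radiosurgery workflows.

A budget is a collection of :class:`UncertaintyComponent` rows — one per
workflow step (MRI distortion, couch positioning, image guidance,
intrafraction motion, ...) — each summarised as signed per-axis mean ± SD in
the Leksell frame plus a 3D *vector mean* ± SD.  Components are classified as
systematic (a shared shift of the dose distribution) or random (per-fraction
blurring) and as Type A (own repeated measurements) or Type B (manufacturer /
published data).  Totals are formed by adding components in quadrature under
the usual assumptions of independence and normality, and the combined total
feeds a sub-threshold probability estimate and literature setup-margin
recipes.

Two conventions matter and are easy to get wrong:

* **Vector mean** is the mean of the per-measurement Euclidean displacement
  norms, *not* the norm of the per-axis means.  The former is what clinical
  summaries report; the latter is systematically smaller (Jensen).
* **Absent axis entries** (a device that only reads out radially) are
  *excluded* from per-axis quadrature, never treated as zero contributions of
  known value — they simply carry no per-axis information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "UncertaintyComponent",
    "UncertaintyBudget",
    "MarginResult",
    "MARGIN_RECIPES",
    "quadrature",
    "vector_mean",
    "combine",
    "prob_below",
    "margin",
    "read_component_table",
    "write_component_table",
    "round_half_up",
]

ErrorType = Literal["systematic", "random", "combined"]

#: Setup-margin recipes as (systematic coefficient, random coefficient):
#: margin = a·Σ + b·σ.  "vanherk" is the classic population recipe ensuring
#: 95% minimum dose for 90% of patients; "stroom" targets 99% mean CTV dose.
MARGIN_RECIPES: dict[str, tuple[float, float]] = {
    "vanherk": (2.5, 0.7),
    "stroom": (2.0, 0.7),
}

_NAN3 = (math.nan, math.nan, math.nan)


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero (report display convention)."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def quadrature(values: Iterable[float]) -> float:
    """Root-sum-square of *values*: sqrt(sum v_i^2).

    Sign-agnostic and never smaller than the largest ``|v_i|``.  Raises
    ``ValueError`` on an empty or non-finite input — absent entries must be
    excluded by the caller, not passed as NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("quadrature of an empty list is undefined")
    if not np.all(np.isfinite(arr)):
        raise ValueError("quadrature requires finite values")
    return float(np.sqrt(np.sum(arr * arr)))


def vector_mean(per_measurement_vectors: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Mean and sample SD of per-measurement Euclidean norms.

    This is the clinical "total vector mean" convention: average the 3D
    displacement magnitude of each individual measurement.  It is *not* the
    norm of the axis-wise means (which it always dominates, by the triangle
    inequality).  With a single measurement the SD is reported as 0.
    """
    arr = np.asarray(per_measurement_vectors, dtype=float)
    if arr.size == 0:
        raise ValueError("vector_mean of an empty set is undefined")
    arr = arr.reshape(-1, 3)
    norms = np.linalg.norm(arr, axis=1)
    mean = float(np.mean(norms))
    sd = float(np.std(norms, ddof=1)) if norms.size > 1 else 0.0
    return mean, sd


@dataclass
class UncertaintyComponent:
    """One budget row: a workflow step's displacement uncertainty summary.

    Axis entries may be absent (NaN) when a device reports only a radial
    readout; ``vector_sd_mm`` may be NaN when it cannot be derived from the
    available summaries.
    """

    name: str
    vector_mean_mm: float
    error_type: ErrorType
    vector_sd_mm: float = math.nan
    axis_mean_mm: tuple[float, float, float] = _NAN3
    axis_sd_mm: tuple[float, float, float] = _NAN3
    n: int | None = None
    uncertainty_class: Literal["A", "B"] | None = "A"

    def __post_init__(self) -> None:
        self.axis_mean_mm = tuple(float(v) for v in self.axis_mean_mm)  # type: ignore[assignment]
        self.axis_sd_mm = tuple(float(v) for v in self.axis_sd_mm)  # type: ignore[assignment]
        if len(self.axis_mean_mm) != 3 or len(self.axis_sd_mm) != 3:
            raise ValueError(f"{self.name}: axis entries must be 3-vectors")
        if not (self.vector_mean_mm >= 0):
            raise ValueError(f"{self.name}: vector mean must be >= 0")
        for sd in (self.vector_sd_mm, *self.axis_sd_mm):
            if not math.isnan(sd) and sd < 0:
                raise ValueError(f"{self.name}: SDs must be >= 0")
        if self.error_type not in ("systematic", "random", "combined"):
            raise ValueError(f"{self.name}: unknown error type {self.error_type!r}")
        if self.uncertainty_class not in ("A", "B", None):
            raise ValueError(f"{self.name}: uncertainty class must be A or B")


def _quad_present(values: Iterable[float]) -> float:
    present = [v for v in values if not math.isnan(v)]
    return quadrature(present) if present else math.nan


def combine(
    components: Sequence[UncertaintyComponent],
    which: Literal["systematic", "random", "all"] = "all",
) -> UncertaintyComponent:
    """Quadrature total over *components*, optionally filtered by error type.

    Per-axis means and SDs are root-sum-squared over the components that
    carry that axis (absent entries are skipped, not zero-filled); the total
    vector mean is the quadrature of component vector means.  The total
    vector SD is NOT derivable from row summaries alone and is reported as
    NaN — compute it from raw per-measurement vectors when you have them.
    """
    if which == "all":
        selected = list(components)
        label, etype = "Total uncertainty", "combined"
    elif which in ("systematic", "random"):
        selected = [c for c in components if c.error_type == which]
        label, etype = f"Total {which}", which
    else:
        raise ValueError(f"unknown filter {which!r}")
    if not selected:
        raise ValueError(f"no components with error type {which!r}")
    axis_mean = tuple(_quad_present(c.axis_mean_mm[j] for c in selected) for j in range(3))
    axis_sd = tuple(_quad_present(c.axis_sd_mm[j] for c in selected) for j in range(3))
    vec_mean = quadrature(c.vector_mean_mm for c in selected)
    return UncertaintyComponent(
        name=label,
        vector_mean_mm=vec_mean,
        vector_sd_mm=math.nan,
        axis_mean_mm=axis_mean,  # type: ignore[arg-type]
        axis_sd_mm=axis_sd,  # type: ignore[arg-type]
        n=None,
        error_type=etype,  # type: ignore[arg-type]
        uncertainty_class=None,
    )


@dataclass
class UncertaintyBudget:
    """Component collection plus the three quadrature totals rows."""

    components: list[UncertaintyComponent]
    totals: dict[str, UncertaintyComponent] = field(default_factory=dict)

    @classmethod
    def from_components(cls, components: Sequence[UncertaintyComponent]) -> "UncertaintyBudget":
        comps = list(components)
        totals = {}
        for which in ("systematic", "random"):
            try:
                totals[which] = combine(comps, which)  # type: ignore[arg-type]
            except ValueError:
                pass  # a budget may legitimately have no rows of one type
        totals["combined"] = combine(comps, "all")
        return cls(components=comps, totals=totals)

    def to_frame(self) -> pd.DataFrame:
        rows = [_component_to_record(c) for c in self.components]
        rows += [_component_to_record(t) for t in self.totals.values()]
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def prob_below(threshold_mm: float, mean_mm: float, sd_mm: float) -> float:
    """P(total displacement <= threshold) under a normal model N(mean, sd).

    Degenerates to a step at *mean* when sd = 0.
    """
    if sd_mm < 0:
        raise ValueError("sd must be >= 0")
    if sd_mm == 0:
        return 1.0 if threshold_mm >= mean_mm else 0.0
    return float(norm.cdf((threshold_mm - mean_mm) / sd_mm))


@dataclass(frozen=True)
class MarginResult:
    recipe: str
    margin_mm: float
    sigma_systematic_mm: float
    sigma_random_mm: float


def margin(recipe: str, sigma_systematic_mm: float, sigma_random_mm: float) -> MarginResult:
    """Setup margin from systematic (Σ) and random (σ) SDs via a named recipe."""
    if recipe not in MARGIN_RECIPES:
        raise ValueError(f"unknown margin recipe {recipe!r}; choose from {sorted(MARGIN_RECIPES)}")
    if sigma_systematic_mm < 0 or sigma_random_mm < 0:
        raise ValueError("margin inputs must be >= 0")
    a, b = MARGIN_RECIPES[recipe]
    return MarginResult(
        recipe=recipe,
        margin_mm=a * sigma_systematic_mm + b * sigma_random_mm,
        sigma_systematic_mm=sigma_systematic_mm,
        sigma_random_mm=sigma_random_mm,
    )


# ---------------------------------------------------------------------------
# Component table CSV I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "name",
    "x_mean", "x_sd", "y_mean", "y_sd", "z_mean", "z_sd",
    "vec_mean", "vec_sd", "n", "error_type", "class",
]


def _component_to_record(c: UncertaintyComponent) -> dict:
    return {
        "name": c.name,
        "x_mean": c.axis_mean_mm[0], "x_sd": c.axis_sd_mm[0],
        "y_mean": c.axis_mean_mm[1], "y_sd": c.axis_sd_mm[1],
        "z_mean": c.axis_mean_mm[2], "z_sd": c.axis_sd_mm[2],
        "vec_mean": c.vector_mean_mm, "vec_sd": c.vector_sd_mm,
        "n": c.n, "error_type": c.error_type, "class": c.uncertainty_class,
    }


def write_component_table(components: Sequence[UncertaintyComponent], path) -> None:
    """Write components as CSV; absent entries become empty cells."""
    df = pd.DataFrame([_component_to_record(c) for c in components], columns=_CSV_COLUMNS)
    df.to_csv(path, index=False)


def read_component_table(path) -> list[UncertaintyComponent]:
    """Read a component CSV (columns per ``write_component_table``)."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"component table {path} missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        n = row["n"]
        out.append(
            UncertaintyComponent(
                name=str(row["name"]),
                vector_mean_mm=float(row["vec_mean"]),
                vector_sd_mm=float(row["vec_sd"]) if pd.notna(row["vec_sd"]) else math.nan,
                axis_mean_mm=tuple(float(row[k]) if pd.notna(row[k]) else math.nan
                                   for k in ("x_mean", "y_mean", "z_mean")),
                axis_sd_mm=tuple(float(row[k]) if pd.notna(row[k]) else math.nan
                                 for k in ("x_sd", "y_sd", "z_sd")),
                n=int(n) if pd.notna(n) else None,
                error_type=str(row["error_type"]),  # type: ignore[arg-type]
                uncertainty_class=str(row["class"]) if pd.notna(row["class"]) else None,  # type: ignore[arg-type]
            )
        )
    return out
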