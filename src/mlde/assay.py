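"""Plate-assay processing: kinetic traces to slopes, slopes to activities.

The screening assay follows substrate depletion photometrically at
340 nm: a well's initial reaction rate is the ordinary-least-squares
slope of its absorbance trace over the initial linear range, reported as
a positive magnitude of decline (dA/min).  Activities are expressed
relative to parent controls measured on the same plate:

    FIOP  = variant initial rate / parent initial rate (same plate)
    FIOWT = product of FIOP values along the variant's parental lineage

Plate-wise normalization by the averaged parent slope removes
multiplicative batch effects between plates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np


@dataclass
class KineticTrace:
    """One well's absorbance-vs-time record (minutes, AU at 340 nm)."""

    times: np.ndarray
    absorbance: np.ndarray
    well: str
    plate: str
    variant_name: str

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must have equal length")
        if self.times.size < 4:
            raise ValueError(f"trace needs >= 4 samples, got {self.times.size}")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ActivityRecord:
    """One well's measurement and its derived activity labels.

    ``slope`` is the initial-rate magnitude in dA/min (positive =
    absorbance decline).  ``fiop`` is filled by plate normalization;
    ``fiowt`` by lineage bookkeeping.  ``flagged`` marks wells whose
    linear range could not be certified.
    """

    variant_name: str
    plate: str
    well: str
    slope: float
    fiop: float | None = None
    fiowt: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope):
            raise ValueError(f"slope must be finite, got {self.slope}")
        for label, value in (("fiop", self.fiop), ("fiowt", self.fiowt)):
            if value is not None and value < 0:
                raise ValueError(f"{label} must be >= 0, got {value}")


@dataclass(frozen=True)
class SlopeFit:
    """Result of linear-range slope estimation for one trace."""

    slope: float          # magnitude of absorbance decline, dA/min
    n_points: int         # samples in the selected prefix window
    r_squared: float      # coefficient of determination of that window
    flagged: bool         # no window met the linearity threshold


def _ols_line(t: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, R^2).

    R^2 is defined as 1 when the fit is exact and the response is
    constant (zero total variation), so a flat trace counts as perfectly
    linear with slope 0.
    """
    beta1, beta0 = np.polyfit(t, a, 1)
    resid = a - (beta0 + beta1 * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    eps = 1e-24 * (float(np.sum(a * a)) + 1.0)  # round-off floor
    if ss_tot <= eps:
        r2 = 1.0 if ss_res <= eps else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(beta1), float(beta0), r2


def estimate_slope(
    trace: KineticTrace,
    min_points: int = 4,
    linearity_threshold: float = 0.99,
) -> SlopeFit:
    """Initial-rate slope over the longest certifiably linear prefix.

    Prefix windows start at the first sample; the longest window with at
    least ``min_points`` samples whose linear fit reaches the linearity
    threshold (R^2) is used.  If no window qualifies, the first
    ``min_points`` samples are used and the result is flagged.
    """
    if min_points < 3:
        raise ValueError(f"min_points must be >= 3, got {min_points}")
    if not 0 < linearity_threshold <= 1:
        raise ValueError("linearity_threshold must be in (0, 1]")
    t, a = trace.times, trace.absorbance
    if t.size < min_points:
        raise ValueError(f"trace has {t.size} samples, fewer than min_points={min_points}")

    for end in range(t.size, min_points - 1, -1):
        beta1, _, r2 = _ols_line(t[:end], a[:end])
        if r2 >= linearity_threshold:
            return SlopeFit(slope=-beta1, n_points=end, r_squared=r2, flagged=False)
    beta1, _, r2 = _ols_line(t[:min_points], a[:min_points])
    return SlopeFit(slope=-beta1, n_points=min_points, r_squared=r2, flagged=True)


def slopes_from_traces(
    traces: Iterable[KineticTrace],
    min_points: int = 4,
    linearity_threshold: float = 0.99,
) -> list[ActivityRecord]:
    """Estimate one activity record per trace."""
    records = []
    for tr in traces:
        fit = estimate_slope(tr, min_points, linearity_threshold)
        records.append(
            ActivityRecord(
                variant_name=tr.variant_name,
                plate=tr.plate,
                well=tr.well,
                slope=fit.slope,
                flagged=fit.flagged,
            )
        )
    return records


@dataclass(frozen=True)
class PlateNormalization:
    """Per-plate parent statistics emitted alongside normalized records."""

    plate: str
    parent_mean_slope: float
    n_parent_wells: int
    n_flagged: int


def normalize_plate(
    records: Sequence[ActivityRecord],
    parent_name: str = "WT",
) -> tuple[list[ActivityRecord], list[PlateNormalization]]:
    """Attach plate-normalized activity labels (FIOP).

    Each record's label is its slope divided by the mean slope of the
    parent-control wells on the same plate; every plate must therefore
    contain at least one well named after the parent.
    """
    plates: dict[str, list[ActivityRecord]] = {}
    for rec in records:
        plates.setdefault(rec.plate, []).append(rec)

    out: list[ActivityRecord] = []
    report: list[PlateNormalization] = []
    for plate in plates:
        group = plates[plate]
        parent_slopes = [r.slope for r in group if r.variant_name == parent_name]
        if not parent_slopes:
            raise ValueError(
                f"plate {plate!r} has no parent ({parent_name!r}) control wells"
            )
        parent_mean = float(np.mean(parent_slopes))
        if parent_mean <= 0:
            raise ValueError(f"plate {plate!r} has non-positive mean parent slope")
        for rec in group:
            out.append(replace(rec, fiop=max(rec.slope / parent_mean, 0.0)))
        report.append(
            PlateNormalization(
                plate=plate,
                parent_mean_slope=parent_mean,
                n_parent_wells=len(parent_slopes),
                n_flagged=sum(r.flagged for r in group),
            )
        )
    return out, report


def fiowt_from_lineage(fiop_chain: Sequence[float]) -> float:
    """Fold-improvement over wild type from a parent-to-child FIOP chain.

    FIOP values compose multiplicatively along a lineage: a variant 2.5x
    better than a parent that is 9x better than wild type is 22.5x better
    than wild type.
    """
    if len(fiop_chain) == 0:
        raise ValueError("lineage chain is empty")
    chain = np.asarray(fiop_chain, dtype=float)
    if np.any(chain <= 0):
        raise ValueError("all lineage FIOP values must be > 0")
    return float(np.prod(chain))


def positive_fraction(records, threshold: float = 1.0) -> float:
    """Fraction of variants at or above parity with wild type.

    The boundary value (FIOWT exactly 1.0 by default) counts positive.
    Accepts activity records carrying ``fiowt`` or a plain sequence of
    fold values.
    """
    values = []
    for item in records:
        if isinstance(item, ActivityRecord):
            if item.fiowt is None:
                raise ValueError(f"record for {item.variant_name!r} has no fiowt")
            values.append(item.fiowt)
        else:
            values.append(float(item))
    if not values:
        raise ValueError("no records to classify")
    arr = np.asarray(values, dtype=float)
    return float(np.mean(arr >= threshold))


def round_down_sig(x: float, figures: int = 2) -> float:
    """Round toward zero to the given number of significant figures.

    Reporting convention for fold-improvement values (22.5 prints as 22).
    """
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x))) - (figures - 1)
    scale = 10.0**exponent
    value = math.floor(abs(x) / scale) * scale
    return math.copysign(value, x)
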