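"""Outlier screening, complete-case filtering and method whitelist.

Records are screened region by region on the two derived emission ratios —
CH4 yield (g/kg DMI) and CH4 intensity (g/kg ECM) — with Tukey fences at
1.5 x IQR.  A record falls if either ratio lies strictly outside the
corresponding fence (union rule).  Screening is single-pass: fences are
computed once on the incoming data and not recomputed after removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .records import CowRecord, NUMERIC_FIELDS, derive_ratios

__all__ = [
    "OutlierFences",
    "ScreenReport",
    "iqr_fences",
    "screen_outliers",
    "complete_cases",
    "method_filter",
    "DEFAULT_COMPLETE_FIELDS",
]

logger = logging.getLogger(__name__)

#: Fields required for the refined complete data set used in selection and
#: cross-validation (response, intake, energy, diet composition, milk,
#: body weight).
DEFAULT_COMPLETE_FIELDS = (
    "ch4", "dmi", "gei", "ge_diet", "cp", "ee", "ndf", "ash",
    "my", "mf", "mp", "bw",
)

#: Fewer than this many records in a region -> screening skipped there
#: (quartiles on 2-3 points are not meaningful fences).
MIN_REGION_N = 4


@dataclass(frozen=True)
class OutlierFences:
    """Tukey fences for one variable: [q1 - k*iqr, q3 + k*iqr]."""

    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float
    k: float = 1.5

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def iqr_fences(values: Sequence[float], k: float = 1.5) -> OutlierFences:
    """Quartiles by linear interpolation (position p*(n-1)) and fences.

    Raises ``ValueError`` on empty or non-finite input.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("iqr_fences requires at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("iqr_fences requires finite values")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    iqr = q3 - q1
    return OutlierFences(q1=float(q1), q3=float(q3), iqr=float(iqr),
                         lower=float(q1 - k * iqr), upper=float(q3 + k * iqr),
                         k=k)


@dataclass
class ScreenReport:
    """Outcome of one screening pass."""

    n_input: int
    n_kept: int
    n_flagged: int
    fences: dict = field(default_factory=dict)   # region -> {"yield":..., "intensity":...}
    flagged: list = field(default_factory=list)  # [(record_id, reason), ...]
    skipped_regions: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "n_flagged": self.n_flagged,
            "fences": {reg: {var: asdict(f) for var, f in d.items()}
                       for reg, d in self.fences.items()},
            "flagged": [{"record_id": rid, "reason": why}
                        for rid, why in self.flagged],
            "skipped_regions": list(self.skipped_regions),
        }


def screen_outliers(
    records: Sequence[CowRecord],
    k: float = 1.5,
    rule: str = "union",
) -> tuple[list[CowRecord], ScreenReport]:
    """Region-wise IQR screen on CH4 yield and intensity.

    Parameters
    ----------
    records : sequence of CowRecord
        Must have region, and computable yield and intensity.
    k : float
        Fence multiplier (1.5 flags "extremes").
    rule : {"union", "sequential"}
        ``union`` flags a record outside either ratio's fences (default).
        ``sequential`` screens on yield first, recomputes intensity fences
        on the survivors, then screens on intensity.

    Returns the kept records (input order preserved) and a report.
    Regions with fewer than four records are skipped with a warning.
    """
    if rule not in ("union", "sequential"):
        raise ValueError(f"unknown screening rule {rule!r}")
    ratios = {}
    for r in records:
        y, i = derive_ratios(r)
        ratios[id(r)] = (y, i)

    by_region: dict[str, list[CowRecord]] = {}
    for r in records:
        by_region.setdefault(r.region, []).append(r)

    report = ScreenReport(n_input=len(records), n_kept=0, n_flagged=0)
    flagged_ids: set[int] = set()

    for region, members in by_region.items():
        if len(members) < MIN_REGION_N:
            logger.warning("region %s has %d records (<%d): screening skipped",
                           region, len(members), MIN_REGION_N)
            report.skipped_regions.append(region)
            continue
        yields = [ratios[id(m)][0] for m in members]
        intens = [ratios[id(m)][1] for m in members]
        if any(v is None for v in yields) or any(v is None for v in intens):
            raise ValueError(
                f"region {region}: yield/intensity not computable for all "
                "records; run complete_cases first")
        fy = iqr_fences(yields, k=k)
        if rule == "union":
            fi = iqr_fences(intens, k=k)
            report.fences[region] = {"yield": fy, "intensity": fi}
            for m, yv, iv in zip(members, yields, intens):
                reasons = []
                if not fy.contains(yv):
                    reasons.append(f"yield {yv:.3g} outside ({fy.lower:.4g}, {fy.upper:.4g})")
                if not fi.contains(iv):
                    reasons.append(f"intensity {iv:.3g} outside ({fi.lower:.4g}, {fi.upper:.4g})")
                if reasons:
                    flagged_ids.add(id(m))
                    report.flagged.append((m.record_id, f"{region}: " + "; ".join(reasons)))
        else:
            for m, yv in zip(members, yields):
                if not fy.contains(yv):
                    flagged_ids.add(id(m))
                    report.flagged.append(
                        (m.record_id,
                         f"{region}: yield {yv:.3g} outside ({fy.lower:.4g}, {fy.upper:.4g})"))
            survivors = [m for m in members if id(m) not in flagged_ids]
            fi = iqr_fences([ratios[id(m)][1] for m in survivors], k=k)
            report.fences[region] = {"yield": fy, "intensity": fi}
            for m in survivors:
                iv = ratios[id(m)][1]
                if not fi.contains(iv):
                    flagged_ids.add(id(m))
                    report.flagged.append(
                        (m.record_id,
                         f"{region}: intensity {iv:.3g} outside ({fi.lower:.4g}, {fi.upper:.4g})"))

    kept = [r for r in records if id(r) not in flagged_ids]
    report.n_kept = len(kept)
    report.n_flagged = len(records) - len(kept)
    return kept, report


def complete_cases(
    records: Sequence[CowRecord],
    required: Sequence[str] = DEFAULT_COMPLETE_FIELDS,
) -> list[CowRecord]:
    """Records with every ``required`` field present, order preserved."""
    required = tuple(required)
    if not required:
        raise ValueError("required field list must be non-empty")
    unknown = [f for f in required if f not in NUMERIC_FIELDS]
    if unknown:
        raise ValueError(f"unknown field name(s): {unknown}")
    return [r for r in records
            if all(getattr(r, f) is not None for f in required)]


def method_filter(records: Sequence[CowRecord]) -> list[CowRecord]:
    """Keep only quality-assured measurement techniques.

    Respiration chamber, GreenFeed and the SF6 tracer are retained;
    anything labelled ``other`` is dropped.
    """
    return [r for r in records if r.ch4_method in ("chamber", "greenfeed", "sf6")]
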