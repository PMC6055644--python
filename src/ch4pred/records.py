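"""Per-cow record schema, derived quantities and validation.

The unit of observation is one animal-period record from a methane
measurement study: feed intake and diet composition, milk production and
composition, body weight, and measured enteric CH4 production, together
with the identifiers (research group, study, region, measurement method)
that drive the hierarchical analysis.

Conventions
-----------
* Percentages are stored in percent units (a milk fat of 4.1 means 4.1 %);
  every formula divides by 100 internally.
* Missing values are first-class: ``None`` on scalar records, ``NaN`` in
  DataFrames.  Derived quantities propagate missingness rather than raise.
* Units: kg for mass, MJ for energy, g/day for CH4 production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CH4_ENERGY_MJ_PER_G",
    "CowRecord",
    "REGIONS",
    "CH4_METHODS",
    "NUMERIC_FIELDS",
    "compute_ecm",
    "compute_ym",
    "derive_ratios",
    "validate_record",
    "validate_dataset",
    "records_to_frame",
    "frame_to_records",
    "read_records_csv",
    "write_records_csv",
]

#: Energy density of methane, MJ per gram.  Fixed physical constant used by
#: the Ym conversion and the IPCC Tier 2 equations; not user-configurable.
CH4_ENERGY_MJ_PER_G = 0.05565

REGIONS = ("EU", "US", "AU", "NZ", "CL")
CH4_METHODS = ("chamber", "greenfeed", "sf6", "other")

#: Numeric measurement fields, in canonical CSV column order.
NUMERIC_FIELDS = (
    "dmi", "gei", "ge_diet", "cp", "ee", "ndf", "ash",
    "my", "mf", "mp", "bw", "ch4",
)

#: Relative mismatch between GEI and DMI x dietary GE density beyond which a
#: consistency warning is raised.  Tolerant by design: measured GEI and
#: book-value diet energy densities legitimately disagree.
GEI_CONSISTENCY_TOL = 0.25


@dataclass
class CowRecord:
    """One animal-period observation.

    All numeric fields are optional (``None`` = not recorded).  Identifiers
    are mandatory.  ``study_id`` must be unique across research groups: the
    same study never appears under two groups.

    Parameters
    ----------
    record_id : str
        Unique record identifier.
    group_id : str
        Research group (laboratory / institute) identifier.
    study_id : str
        Study identifier, nested within ``group_id``.
    region : str
        One of ``EU, US, AU, NZ, CL``.
    ch4_method : str
        Measurement technique: ``chamber``, ``greenfeed``, ``sf6`` or
        ``other``.  ``other`` is representable but excluded by the default
        quality filter.
    dmi, gei, ge_diet, cp, ee, ndf, ash, my, mf, mp, bw, ch4 : float, optional
        Dry matter intake (kg/d), gross energy intake (MJ/d), dietary GE
        density (MJ/kg DM), crude protein / ether extract / NDF / ash
        (% of DM), milk yield (kg/d), milk fat and protein (%), body
        weight (kg) and methane production (g/d).
    """

    record_id: str
    group_id: str
    study_id: str
    region: str
    ch4_method: str = "chamber"
    breed: str | None = None
    dmi: float | None = None
    gei: float | None = None
    ge_diet: float | None = None
    cp: float | None = None
    ee: float | None = None
    ndf: float | None = None
    ash: float | None = None
    my: float | None = None
    mf: float | None = None
    mp: float | None = None
    bw: float | None = None
    ch4: float | None = None

    def get(self, name: str):
        return getattr(self, name)


def _require_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value}")


def compute_ecm(my, mf, mp):
    """Energy-corrected milk (3.5 % fat), kg/day.

    ECM = 12.95 x fat yield + 7.65 x true-protein yield + 0.327 x milk
    yield, with true protein taken as 93 % of milk crude protein.  ``mf``
    and ``mp`` are percentages of milk mass.

    Accepts scalars or arrays; NaN inputs propagate to NaN output.
    """
    my_a = np.asarray(my, dtype=float)
    mf_a = np.asarray(mf, dtype=float)
    mp_a = np.asarray(mp, dtype=float)
    if np.any(my_a[~np.isnan(my_a)] < 0) or np.any(mf_a[~np.isnan(mf_a)] < 0) \
            or np.any(mp_a[~np.isnan(mp_a)] < 0):
        raise ValueError("milk yield and composition must be non-negative")
    ecm = (12.95 * my_a * mf_a / 100.0
           + 7.65 * my_a * mp_a / 100.0 * 0.93
           + 0.327 * my_a)
    if np.ndim(my) == 0 and np.ndim(mf) == 0 and np.ndim(mp) == 0:
        return float(ecm)
    return ecm


def compute_ym(ch4, gei):
    """Methane conversion factor Ym: CH4 energy as a percentage of GEI.

    Ym = 100 x (ch4 [g/d] x 0.05565 [MJ/g]) / gei [MJ/d].
    """
    ch4_a = np.asarray(ch4, dtype=float)
    gei_a = np.asarray(gei, dtype=float)
    if np.any(gei_a[~np.isnan(gei_a)] <= 0):
        raise ValueError("gei must be strictly positive")
    if np.any(ch4_a[~np.isnan(ch4_a)] < 0):
        raise ValueError("ch4 must be non-negative")
    ym = 100.0 * ch4_a * CH4_ENERGY_MJ_PER_G / gei_a
    if np.ndim(ch4) == 0 and np.ndim(gei) == 0:
        return float(ym)
    return ym


def derive_ratios(record: CowRecord) -> tuple[float | None, float | None]:
    """CH4 yield (g/kg DMI) and intensity (g/kg ECM) for one record.

    Missing prerequisites give a missing output, never an error: yield
    needs ch4 and dmi > 0, intensity needs ch4 and a positive ECM.
    """
    yield_ = None
    intensity = None
    if record.ch4 is not None and record.dmi is not None and record.dmi > 0:
        yield_ = record.ch4 / record.dmi
    if (record.ch4 is not None and record.my is not None
            and record.mf is not None and record.mp is not None):
        ecm = compute_ecm(record.my, record.mf, record.mp)
        if ecm > 0:
            intensity = record.ch4 / ecm
    return yield_, intensity


@dataclass
class Violation:
    """A single rule violation found on a record."""

    record_id: str
    field: str
    rule: str
    severity: str = "error"  # "error" or "warning"

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.severity}] {self.record_id}.{self.field}: {self.rule}"


def validate_record(record: CowRecord) -> list[Violation]:
    """Check a single record against the schema invariants.

    Returns an empty list iff the record is clean.  Violations name the
    offending field and the rule.  The GEI ~ DMI x GE consistency check is
    a warning, not an error.
    """
    out: list[Violation] = []
    if record.region not in REGIONS:
        out.append(Violation(record.record_id, "region",
                             f"unknown region {record.region!r}"))
    if record.ch4_method not in CH4_METHODS:
        out.append(Violation(record.record_id, "ch4_method",
                             f"unknown method {record.ch4_method!r}"))
    for name in NUMERIC_FIELDS:
        v = getattr(record, name)
        if v is None:
            continue
        if not math.isfinite(v):
            out.append(Violation(record.record_id, name, "non-finite value"))
        elif v <= 0:
            out.append(Violation(record.record_id, name,
                                 f"must be strictly positive, got {v}"))
    if (record.ch4 is not None and record.gei is not None and record.gei > 0):
        ym = compute_ym(record.ch4, record.gei)
        if not (0 < ym < 15):
            out.append(Violation(record.record_id, "ch4",
                                 f"implied Ym {ym:.2f}% outside (0, 15)"))
    if (record.dmi is not None and record.ge_diet is not None
            and record.gei is not None and record.gei > 0):
        implied = record.dmi * record.ge_diet
        rel = abs(record.gei - implied) / record.gei
        if rel > GEI_CONSISTENCY_TOL:
            out.append(Violation(
                record.record_id, "gei",
                f"GEI {record.gei} inconsistent with DMI x GE = "
                f"{implied:.1f} (relative gap {rel:.2f})",
                severity="warning"))
    return out


def validate_dataset(records: Sequence[CowRecord]) -> list[Violation]:
    """Per-record checks plus the study-within-group uniqueness invariant."""
    out: list[Violation] = []
    study_group: dict[str, str] = {}
    for r in records:
        out.extend(validate_record(r))
        prev = study_group.setdefault(r.study_id, r.group_id)
        if prev != r.group_id:
            out.append(Violation(
                r.record_id, "study_id",
                f"study {r.study_id!r} appears under groups "
                f"{prev!r} and {r.group_id!r}"))
    return out


# ---------------------------------------------------------------------------
# DataFrame / CSV interop

_ID_FIELDS = ("record_id", "group_id", "study_id", "region", "ch4_method", "breed")
_ALL_FIELDS = _ID_FIELDS + NUMERIC_FIELDS


def records_to_frame(records: Iterable[CowRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame (missing -> NaN), canonical columns."""
    df = pd.DataFrame([{f.name: getattr(r, f.name) for f in fields(CowRecord)}
                       for r in records])
    if df.empty:
        df = pd.DataFrame(columns=_ALL_FIELDS)
    for c in NUMERIC_FIELDS:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df[list(_ALL_FIELDS)]


def frame_to_records(df: pd.DataFrame) -> list[CowRecord]:
    """Convert a DataFrame back into records (NaN -> None)."""
    out = []
    for _, row in df.iterrows():
        kw = {}
        for name in _ALL_FIELDS:
            v = row.get(name)
            if name in NUMERIC_FIELDS:
                v = None if pd.isna(v) else float(v)
            elif pd.isna(v):
                v = None
            kw[name] = v
        if kw.get("ch4_method") is None:
            kw["ch4_method"] = "chamber"
        out.append(CowRecord(**kw))
    return out


def read_records_csv(path) -> list[CowRecord]:
    """Read cow records from CSV (header row, empty cell = missing)."""
    df = pd.read_csv(path)
    missing = [c for c in ("record_id", "group_id", "study_id", "region")
               if c not in df.columns]
    if missing:
        raise ValueError(f"CSV lacks required identifier columns: {missing}")
    for c in _ALL_FIELDS:
        if c not in df.columns:
            df[c] = np.nan
    return frame_to_records(df)


def write_records_csv(records: Iterable[CowRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
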