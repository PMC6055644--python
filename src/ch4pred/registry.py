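"""Registry of published CH4 prediction equations and a prediction engine.

Each equation is a linear combination of an intercept and per-predictor
terms, optionally followed by the energy transform (division by the CH4
energy density 0.05565 MJ/g) used by the gross-energy based equations and
the IPCC Tier 2 comparators.  Coefficients and their standard errors are
stored exactly at the precision they were published; the SEs are carried
for reference only and are not propagated into prediction intervals.

Responses:

* ``production_g_d``    — CH4 production, g/day per cow
* ``yield_g_kgDMI``     — CH4 yield, g per kg dry matter intake
* ``intensity_g_kgECM`` — CH4 intensity, g per kg energy-corrected milk

Scopes: ``intercontinental`` (EU + US + AU fits), ``EU``, ``US``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import CH4_ENERGY_MJ_PER_G, CowRecord, compute_ecm

__all__ = [
    "EquationSpec",
    "Term",
    "PredictionResult",
    "MissingInputError",
    "NoEquationError",
    "predict_one",
    "ipcc_tier2",
    "bundled_registry",
    "load_registry",
    "save_registry",
    "best_available",
    "CATEGORY_PREFERENCE",
]

VALID_PREDICTORS = ("dmi", "gei", "cp", "ee", "ndf", "ash",
                    "my", "ecm", "mf", "mp", "bw")
RESPONSES = ("production_g_d", "yield_g_kgDMI", "intensity_g_kgECM")
SCOPES = ("intercontinental", "EU", "US")

#: Category preference for input-availability-aware equation choice, most
#: preferred first.  Ties on predictor count in :func:`best_available` are
#: broken by this order.
CATEGORY_PREFERENCE = (
    "Animal_C", "DMI+Com_C", "DMI+NDF_C", "DMI+EE_C", "DMI_C", "GEI_C",
    "ECM+Com_C", "ECM_C", "MY_C", "Diet_Com_C", "Animal_no_DMI_C",
)


class MissingInputError(KeyError):
    """An equation's predictor is absent from the record."""


class NoEquationError(LookupError):
    """No registry equation is computable from the available inputs."""


@dataclass(frozen=True)
class Term:
    predictor: str
    coef: float
    se: float | None = None


@dataclass(frozen=True)
class EquationSpec:
    """One published prediction equation.

    ``energy_transform`` marks equations whose linear predictor is in MJ of
    CH4 per day and must be divided by 0.05565 MJ/g to give g/day.
    """

    eq_id: str
    response: str
    category: str
    scope: str
    intercept: float
    intercept_se: float | None
    terms: tuple[Term, ...]
    energy_transform: bool = False
    source: str = ""

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise ValueError(f"{self.eq_id}: unknown response {self.response!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"{self.eq_id}: unknown scope {self.scope!r}")
        names = [t.predictor for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.eq_id}: duplicate predictor in terms")
        bad = [n for n in names if n not in VALID_PREDICTORS]
        if bad:
            raise ValueError(f"{self.eq_id}: unknown predictor(s) {bad}")

    @property
    def predictors(self) -> frozenset[str]:
        return frozenset(t.predictor for t in self.terms)


@dataclass(frozen=True)
class PredictionResult:
    value: float
    eq_id: str
    inputs_used: dict


def _record_value(record: CowRecord, predictor: str):
    if predictor == "ecm":
        if record.my is None or record.mf is None or record.mp is None:
            return None
        return compute_ecm(record.my, record.mf, record.mp)
    return getattr(record, predictor)


def predict_one(eq: EquationSpec, record: CowRecord) -> PredictionResult:
    """Evaluate one equation on one record.

    ECM is computed on the fly from milk yield and composition.  A missing
    predictor raises :class:`MissingInputError` naming every gap.
    """
    inputs = {}
    missing = []
    for t in eq.terms:
        v = _record_value(record, t.predictor)
        if v is None:
            missing.append(t.predictor)
        else:
            inputs[t.predictor] = v
    if missing:
        raise MissingInputError(
            f"{eq.eq_id} needs missing input(s): {', '.join(missing)}")
    value = eq.intercept + sum(t.coef * inputs[t.predictor] for t in eq.terms)
    if eq.energy_transform:
        value /= CH4_ENERGY_MJ_PER_G
    return PredictionResult(value=float(value), eq_id=eq.eq_id, inputs_used=inputs)


def ipcc_tier2(gei: float, ym_fraction: float) -> float:
    """IPCC Tier 2 CH4 production, g/day: (Ym x GEI) / 0.05565.

    ``ym_fraction`` is the methane conversion factor as a fraction of gross
    energy (0.065 in the 2006 guidelines, 0.060 in 1997).
    """
    if not (0 < ym_fraction < 0.15):
        raise ValueError(f"ym_fraction {ym_fraction} outside (0, 0.15)")
    if gei < 0:
        raise ValueError("gei must be non-negative")
    return ym_fraction * gei / CH4_ENERGY_MJ_PER_G


# ---------------------------------------------------------------------------
# Bundled equations, transcribed at published precision.
# Tuples: (eq_id, response, category, scope, intercept, intercept_se,
#          [(predictor, coef, se), ...], energy_transform)

_P = "production_g_d"
_Y = "yield_g_kgDMI"
_I = "intensity_g_kgECM"

_BUNDLED = [
    # --- production, intercontinental fits -------------------------------
    ("eq01", _P, "GEI_C", "intercontinental", 7.13, 0.581,
     [("gei", 0.0391, 0.00095)], True),
    ("eq02", _P, "DMI_C", "intercontinental", 124.0, 10.44,
     [("dmi", 13.3, 0.32)], False),
    ("eq03", _P, "DMI+NDF_C", "intercontinental", 33.2, 13.54,
     [("dmi", 13.6, 0.33), ("ndf", 2.43, 0.245)], False),
    ("eq04", _P, "DMI+EE_C", "intercontinental", 163.0, 12.9,
     [("dmi", 13.3, 0.35), ("ee", -11.0, 1.39)], False),
    ("eq05", _P, "DMI+Com_C", "intercontinental", 76.0, 16.14,
     [("dmi", 13.5, 0.35), ("ee", -9.55, 1.390), ("ndf", 2.24, 0.268)], False),
    ("eq06", _P, "Diet_Com_C", "intercontinental", 369.0, 21.9,
     [("ee", -14.7, 1.73), ("ndf", 1.67, 0.339)], False),
    ("eq07", _P, "MY_C", "intercontinental", 299.0, 12.1,
     [("my", 2.73, 0.171)], False),
    ("eq08", _P, "ECM_C", "intercontinental", 259.0, 11.1,
     [("ecm", 3.86, 0.167)], False),
    ("eq09", _P, "ECM+Com_C", "intercontinental", 150.0, 16.1,
     [("ecm", 4.31, 0.172), ("mp", 28.3, 3.20)], False),
    ("eq10", _P, "Animal_C", "intercontinental", -60.5, 17.56,
     [("dmi", 12.4, 0.37), ("ee", -8.78, 1.342), ("ndf", 2.10, 0.256),
      ("mf", 16.1, 1.39), ("bw", 0.148, 0.0143)], False),
    ("eq11", _P, "Animal_no_DMI_C", "intercontinental", -37.0, 22.94,
     [("ee", -12.3, 1.49), ("ndf", 2.24, 0.289), ("ecm", 3.68, 0.191),
      ("mf", 7.81, 1.762), ("mp", 17.7, 3.78), ("bw", 0.284, 0.0148)], False),
    ("eq12", _P, "IPCC_Tier2_2006", "intercontinental", 0.0, None,
     [("gei", 0.065, None)], True),
    ("eq13", _P, "IPCC_Tier2_1997", "intercontinental", 0.0, None,
     [("gei", 0.060, None)], True),
    # --- production, EU fits ---------------------------------------------
    ("eq14", _P, "GEI_C", "EU", 6.20, 0.688,
     [("gei", 0.0425, 0.00118)], True),
    ("eq15", _P, "DMI_C", "EU", 107.0, 12.6,
     [("dmi", 14.5, 0.39)], False),
    ("eq16", _P, "DMI+NDF_C", "EU", -26.0, 16.67,
     [("dmi", 15.3, 0.41), ("ndf", 3.42, 0.309)], False),
    ("eq17", _P, "DMI+EE_C", "EU", 160.0, 14.7,
     [("dmi", 14.2, 0.44), ("ee", -13.5, 1.46)], False),
    ("eq18", _P, "DMI+Com_C", "EU", 11.3, 22.62,
     [("dmi", 14.7, 0.44), ("cp", 2.50, 0.670), ("ee", -10.8, 1.49),
      ("ndf", 3.20, 0.361), ("ash", -2.87, 1.134)], False),
    ("eq19", _P, "Diet_Com_C", "EU", 435.0, 17.4,
     [("ee", -18.7, 1.92)], False),
    ("eq20", _P, "MY_C", "EU", 287.0, 14.1,
     [("my", 3.16, 0.224)], False),
    ("eq21", _P, "ECM_C", "EU", 247.0, 13.1,
     [("ecm", 4.30, 0.215)], False),
    ("eq22", _P, "ECM+Com_C", "EU", 141.0, 18.9,
     [("ecm", 4.75, 0.220), ("mp", 27.4, 3.70)], False),
    ("eq23", _P, "Animal_C", "EU", -52.2, 21.73,
     [("dmi", 13.0, 0.49), ("ee", -10.9, 1.50), ("ndf", 2.80, 0.349),
      ("mf", 7.26, 1.590), ("bw", 0.154, 0.0167)], False),
    ("eq24", _P, "Animal_no_DMI_C", "EU", -44.7, 27.14,
     [("ee", -15.3, 1.63), ("ndf", 2.62, 0.391), ("ecm", 4.34, 0.242),
      ("mp", 21.5, 3.83), ("bw", 0.289, 0.0168)], False),
    # --- production, US fits ---------------------------------------------
    ("eq25", _P, "GEI_C", "US", 7.30, 1.217,
     [("gei", 0.0358, 0.00163)], True),
    ("eq26", _P, "DMI_C", "US", 125.0, 20.5,
     [("dmi", 12.2, 0.55)], False),
    ("eq27", _P, "DMI+NDF_C", "US", 49.5, 27.78,
     [("dmi", 12.1, 0.56), ("ndf", 2.57, 0.450)], False),
    ("eq28", _P, "DMI+EE_C", "US", 136.0, 27.1,
     [("dmi", 12.3, 0.57), ("ee", -2.96, 2.876)], False),
    # eq29 is published identically to eq27 (the DMI+Com selection retained
    # only DMI and NDF); both ids point at the same coefficients.
    ("eq29", _P, "DMI+Com_C", "US", 49.5, 27.78,
     [("dmi", 12.1, 0.56), ("ndf", 2.57, 0.450)], False),
    ("eq30", _P, "Diet_Com_C", "US", 279.0, 51.1,
     [("ndf", 3.53, 0.531)], False),
    ("eq31", _P, "MY_C", "US", 314.0, 33.4,
     [("my", 2.27, 0.278)], False),
    ("eq32", _P, "ECM_C", "US", 270.0, 28.9,
     [("ecm", 3.44, 0.278)], False),
    ("eq33", _P, "ECM+Com_C", "US", 157.0, 37.1,
     [("ecm", 3.53, 0.295), ("mf", 16.1, 3.22), ("mp", 15.3, 6.83)], False),
    ("eq34", _P, "Animal_C", "US", -126.0, 32.7,
     [("dmi", 11.3, 0.59), ("ndf", 2.30, 0.414), ("mf", 28.8, 2.53),
      ("bw", 0.148, 0.0250)], False),
    ("eq35", _P, "Animal_no_DMI_C", "US", -72.4, 42.41,
     [("ndf", 3.15, 0.461), ("ecm", 2.65, 0.270), ("mf", 23.9, 2.79),
      ("bw", 0.290, 0.0257)], False),
    # --- yield, intercontinental fits ------------------------------------
    ("eq36", _Y, "NDF_C", "intercontinental", 13.8, 0.63,
     [("ndf", 0.185, 0.0133)], False),
    ("eq37", _Y, "EE_C", "intercontinental", 21.8, 0.62,
     [("ee", -0.452, 0.0763)], False),
    ("eq38", _Y, "Diet_Com_C", "intercontinental", 15.4, 0.76,
     [("ee", -0.354, 0.0756), ("ndf", 0.173, 0.0145)], False),
    ("eq39", _Y, "MY_C", "intercontinental", 23.5, 0.53,
     [("my", -0.123, 0.0076)], False),
    ("eq40", _Y, "ECM_C", "intercontinental", 22.6, 0.55,
     [("ecm", -0.082, 0.0079)], False),
    ("eq41", _Y, "ECM+Com_C", "intercontinental", 21.1, 0.77,
     [("ecm", -0.105, 0.0081), ("mf", 1.30, 0.077), ("mp", -0.952, 0.1667)],
     False),
    ("eq42", _Y, "Animal_no_DMI_C", "intercontinental", 15.4, 1.08,
     [("ee", -0.291, 0.0733), ("ndf", 0.144, 0.0141), ("ecm", -0.104, 0.0094),
      ("mf", 1.34, 0.087), ("mp", -1.12, 0.187), ("bw", 0.00330, 0.000729)],
     False),
    # --- intensity, intercontinental fits --------------------------------
    ("eq43", _I, "GEI_C", "intercontinental", 15.5, 0.45,
     [("gei", -0.00629, 0.000962)], False),
    ("eq44", _I, "DMI_C", "intercontinental", 15.5, 0.46,
     [("dmi", -0.116, 0.0179)], False),
    ("eq45", _I, "DMI+NDF_C", "intercontinental", 11.3, 0.73,
     [("dmi", -0.103, 0.0190), ("ndf", 0.118, 0.0141)], False),
    ("eq46", _I, "DMI+EE_C", "intercontinental", 17.7, 0.61,
     [("dmi", -0.142, 0.0207), ("ee", -0.462, 0.0820)], False),
    ("eq47", _I, "DMI+Com_C", "intercontinental", 13.2, 0.86,
     [("dmi", -0.127, 0.0207), ("ee", -0.393, 0.0823), ("ndf", 0.114, 0.0156)],
     False),
    # category label stored verbatim as published
    ("eq48", _I, "DMI+Com_Comp_C", "intercontinental", 10.5, 0.71,
     [("ee", -0.364, 0.0825), ("ndf", 0.120, 0.0156)], False),
    ("eq49", _I, "ECM+Com_C", "intercontinental", 3.72, 0.602,
     [("mp", 2.87, 0.147)], False),
    ("eq50", _I, "Animal_C", "intercontinental", -0.101, 1.0980,
     [("dmi", -0.215, 0.0213), ("cp", -0.118, 0.0301), ("ee", -0.323, 0.0760),
      ("ndf", 0.120, 0.0142), ("mf", -0.253, 0.0901), ("mp", 3.44, 0.183),
      ("bw", 0.00947, 0.000836)], False),
    ("eq51", _I, "Animal_no_DMI_C", "intercontinental", -2.85, 1.112,
     [("cp", -0.118, 0.0307), ("ee", -0.289, 0.0784), ("ndf", 0.124, 0.0146),
      ("mp", 3.32, 0.168), ("bw", 0.00605, 0.000762)], False),
]


def _build(entry) -> EquationSpec:
    eq_id, response, category, scope, b0, b0se, terms, transform = entry
    return EquationSpec(
        eq_id=eq_id, response=response, category=category, scope=scope,
        intercept=b0, intercept_se=b0se,
        terms=tuple(Term(p, c, s) for p, c, s in terms),
        energy_transform=transform,
        source="bundled",
    )


def bundled_registry() -> list[EquationSpec]:
    """All bundled main-text equations (production, yield, intensity)."""
    return [_build(e) for e in _BUNDLED]


REGISTRY_SCHEMA_VERSION = 1


def load_registry(path) -> list[EquationSpec]:
    """Load equations from a registry JSON file.

    Schema (version 1)::

        {"schema_version": 1,
         "equations": [{"eq_id": ..., "response": ..., "category": ...,
                        "scope": ..., "intercept": ..., "intercept_se": ...,
                        "energy_transform": bool,
                        "terms": [{"predictor":..., "coef":..., "se":...}]}]}
    """
    with open(path) as fh:
        raw = json.load(fh)
    if isinstance(raw, list):           # bare list also accepted
        entries = raw
    else:
        entries = raw.get("equations", [])
    out = []
    for e in entries:
        try:
            out.append(EquationSpec(
                eq_id=e["eq_id"], response=e["response"],
                category=e.get("category", ""), scope=e["scope"],
                intercept=float(e["intercept"]),
                intercept_se=e.get("intercept_se"),
                terms=tuple(Term(t["predictor"], float(t["coef"]), t.get("se"))
                            for t in e.get("terms", [])),
                energy_transform=bool(e.get("energy_transform", False)),
                source=e.get("source", str(path)),
            ))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(
                f"registry entry {e.get('eq_id', '<no id>')!r} invalid: {exc}"
            ) from exc
    return out


def save_registry(equations: Iterable[EquationSpec], path) -> None:
    payload = {
        "schema_version": REGISTRY_SCHEMA_VERSION,
        "equations": [
            {"eq_id": e.eq_id, "response": e.response, "category": e.category,
             "scope": e.scope, "intercept": e.intercept,
             "intercept_se": e.intercept_se,
             "energy_transform": e.energy_transform,
             "terms": [{"predictor": t.predictor, "coef": t.coef, "se": t.se}
                       for t in e.terms]}
            for e in equations
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def best_available(
    registry: Sequence[EquationSpec],
    available: Iterable[str],
    response: str = "production_g_d",
    scope: str = "intercontinental",
) -> EquationSpec:
    """Most detailed computable equation given the available inputs.

    Among equations of the requested response and scope whose predictors
    are a subset of ``available``, returns the one with the most
    predictors; ties are broken by :data:`CATEGORY_PREFERENCE`.  The
    available set is taken literally — include ``"ecm"`` explicitly to
    admit energy-corrected-milk equations.  IPCC comparator rows are never
    auto-selected.
    """
    if not registry:
        raise ValueError("registry is empty")
    avail = set(available)

    def pref(eq: EquationSpec) -> int:
        try:
            return CATEGORY_PREFERENCE.index(eq.category)
        except ValueError:
            return len(CATEGORY_PREFERENCE)

    candidates = [e for e in registry
                  if e.response == response and e.scope == scope
                  and not e.category.startswith("IPCC")
                  and e.predictors <= avail]
    if not candidates:
        pool = [e for e in registry
                if e.response == response and e.scope == scope
                and not e.category.startswith("IPCC")]
        if not pool:
            raise NoEquationError(
                f"no equations for response={response!r} scope={scope!r}")
        gaps = sorted(min((e.predictors - avail for e in pool),
                          key=lambda s: (len(s), sorted(s))))
        raise NoEquationError(
            f"no equation computable from {sorted(avail)}; smallest missing "
            f"set: {gaps}")
    return max(candidates, key=lambda e: (len(e.predictors), -pref(e)))
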