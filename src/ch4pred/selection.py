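"""All-subsets model selection by BIC with VIF collinearity pruning.

The score for a candidate subset with error sum of squares SSE, sample
size n and p regression coefficients (intercept included) is

    BIC = n * ln(SSE / n) + ln(n) * p        (natural logarithm),

and a smaller BIC is preferred.  By default the SSE comes from an
ordinary-least-squares fit of the subset (the form in which the score is
written); scoring each subset by the conditional residual SSE of the full
mixed model is available with ``engine="lmm"``.

Collinearity among the candidate predictors is handled before the search:
variance inflation factors VIF_j = 1/(1 - R^2_j) — R^2_j from regressing
predictor j on the remaining candidates with an intercept — are computed
iteratively and the single worst offender above the threshold (default 5)
is dropped per round.  Checking VIF on candidates after selection instead
is available via ``vif_order="after"``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mixed_model import MethaneMixedModel
from .records import records_to_frame

__all__ = ["SelectionResult", "bic_score", "vif_scores", "prune_collinear",
           "all_subsets"]

MAX_CANDIDATES = 12


def bic_score(sse: float, n: int, p: int) -> float:
    """n*ln(sse/n) + ln(n)*p; p counts the intercept plus slopes."""
    if sse <= 0:
        raise ValueError("sse must be strictly positive")
    if n <= 0 or p < 1:
        raise ValueError("need n > 0 and p >= 1")
    return n * math.log(sse / n) + math.log(n) * p


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.reset_index(drop=True)
    return records_to_frame(data)


def _design(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))]
                        + [df[c].to_numpy(float) for c in cols])
    return X


def _ols_sse(y: np.ndarray, X: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0])
    return float(np.sum((y - X @ beta) ** 2))


def vif_scores(data, predictors: Sequence[str]) -> dict[str, float]:
    """Variance inflation factor of each predictor against the others.

    Exact collinearity is reported as ``inf``, not raised.
    """
    predictors = list(predictors)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    df = _as_frame(data)
    if len(df) <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    out = {}
    for j, name in enumerate(predictors):
        others = [p for p in predictors if p != name]
        yj = df[name].to_numpy(float)
        X = _design(df, others)
        sse = _ols_sse(yj, X)
        sst = float(np.sum((yj - yj.mean()) ** 2))
        if sst == 0:
            out[name] = math.inf
            continue
        r2 = 1.0 - sse / sst
        out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def prune_collinear(data, predictors: Sequence[str], threshold: float = 5.0
                    ) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop the largest-VIF predictor while any exceeds threshold.

    Ties on the maximum VIF are broken by keeping the earlier predictor in
    the candidate list (the later duplicate is removed).  Returns the
    retained predictors (input order) and the removal log
    ``[(predictor, vif at removal), ...]``.
    """
    retained = list(predictors)
    removed: list[tuple[str, float]] = []
    while len(retained) >= 2:
        vifs = vif_scores(data, retained)
        worst = max(vifs.values())
        if worst <= threshold:
            break
        # among max-VIF ties, drop the one latest in candidate order
        offenders = [p for p in retained if vifs[p] == worst]
        victim = offenders[-1]
        retained.remove(victim)
        removed.append((victim, worst))
    return retained, removed


@dataclass
class SelectionResult:
    """Ranked all-subsets search outcome."""

    candidates: list            # [(tuple of predictors, bic), ...] ranked
    best: tuple
    removed_collinear: list     # [(predictor, vif at removal), ...]
    n: int
    engine: str
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "engine": self.engine,
            "best": list(self.best),
            "removed_collinear": [
                {"predictor": p, "vif": (None if math.isinf(v) else v)}
                for p, v in self.removed_collinear],
            "candidates": [{"predictors": list(s), "bic": b}
                           for s, b in self.candidates],
            "notes": list(self.notes),
        }


def all_subsets(
    data,
    candidates: Sequence[str],
    response: str,
    engine: str = "ols",
    vif_threshold: float = 5.0,
    vif_order: str = "before",
) -> SelectionResult:
    """Score every non-empty predictor subset by BIC.

    Parameters
    ----------
    data : DataFrame or records
        Complete cases for the response and all candidates.
    candidates : sequence of str
        Candidate predictors; at most 12 (2^12 fits).
    engine : {"ols", "lmm"}
        SSE source: plain least squares per subset (default), or the
        conditional residual SSE of the nested mixed model.
    vif_threshold : float
        Collinearity cut-off for pruning.
    vif_order : {"before", "after", "none"}
        Prune candidates before the search (default), check the selected
        subset afterwards, or skip VIF handling.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate predictor")
    if len(candidates) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(candidates)} candidates exceed the 2^{MAX_CANDIDATES} "
            "search bound; prune the list first")
    if engine not in ("ols", "lmm"):
        raise ValueError(f"unknown engine {engine!r}")
    if vif_order not in ("before", "after", "none"):
        raise ValueError(f"unknown vif_order {vif_order!r}")
    df = _as_frame(data)
    if df[[response, *candidates]].isna().any().any():
        raise ValueError("data contains missing values; run complete_cases")
    n = len(df)
    y = df[response].to_numpy(float)

    notes: list[str] = []
    removed: list[tuple[str, float]] = []
    pool = candidates
    if vif_order == "before" and len(candidates) >= 2:
        pool, removed = prune_collinear(df, candidates, vif_threshold)
        if removed:
            notes.append(f"pruned before search: {[p for p, _ in removed]}")

    scored = []
    for k in range(1, len(pool) + 1):
        for subset in itertools.combinations(pool, k):
            if engine == "ols":
                sse = _ols_sse(y, _design(df, subset))
            else:
                fit = MethaneMixedModel(df, response, list(subset)).fit()
                sse = fit.sse_conditional
            scored.append((subset, bic_score(sse, n, len(subset) + 1)))
    scored.sort(key=lambda t: (t[1], len(t[0]), t[0]))
    best = scored[0][0]

    if vif_order == "after" and len(best) >= 2:
        kept, removed = prune_collinear(df, list(best), vif_threshold)
        if removed:
            notes.append(f"pruned from selected subset: {[p for p, _ in removed]}")
            best = tuple(kept)

    return SelectionResult(candidates=scored, best=best,
                           removed_collinear=removed, n=n, engine=engine,
                           notes=notes)
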