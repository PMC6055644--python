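"""Leave-one-study-out cross-validation for grouped emission data.

Folds are the studies themselves (k = number of distinct studies), so a
record is never predicted by a model that saw any record from its own
study.  For each fold the nested mixed model is refitted on the remaining
studies and the held-out study is predicted from the fixed effects alone;
the held-out predictions of all folds are pooled and the error metrics
are computed once on the pooled vectors (not averaged over folds).

A fold whose REML fit fails to converge is refitted by ordinary least
squares and counted in the report rather than aborting the whole CV.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import MetricReport, evaluate
from .mixed_model import LmmSpec, MethaneMixedModel
from .records import records_to_frame

__all__ = ["FoldAssignment", "CvResult", "study_folds", "loso_cv",
           "evaluate_by_scope", "SCOPE_REGIONS"]

logger = logging.getLogger(__name__)

#: Region sets for the named evaluation scopes.
SCOPE_REGIONS = {
    "intercontinental": ("EU", "US", "AU"),
    "EU": ("EU",),
    "US": ("US",),
}


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of record ids into per-study folds."""

    folds: dict  # study_id -> list of record ids
    k: int

    def sizes(self) -> dict:
        return {s: len(m) for s, m in self.folds.items()}


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.reset_index(drop=True)
    return records_to_frame(data)


def study_folds(data) -> FoldAssignment:
    """One fold per distinct study; the folds partition the dataset."""
    df = _as_frame(data)
    if "study_id" not in df.columns or df["study_id"].isna().any():
        raise ValueError("every record needs a study_id")
    folds: dict = {}
    for rid, sid in zip(df["record_id"], df["study_id"]):
        folds.setdefault(sid, []).append(rid)
    k = len(folds)
    if k == 1:
        warnings.warn("single study: leave-one-study-out CV is degenerate",
                      UserWarning, stacklevel=2)
    return FoldAssignment(folds=folds, k=k)


@dataclass
class CvResult:
    """Pooled held-out predictions aligned with the observations."""

    frame: pd.DataFrame  # record_id, observed, predicted, study_id, group_id, region
    spec: LmmSpec
    fold_diagnostics: list = field(default_factory=list)
    n_ols_fallbacks: int = 0

    @property
    def observed(self) -> np.ndarray:
        return self.frame["observed"].to_numpy(float)

    @property
    def predicted(self) -> np.ndarray:
        return self.frame["predicted"].to_numpy(float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _ols_fallback(train: pd.DataFrame, spec: LmmSpec) -> pd.Series:
    y = train[spec.response].to_numpy(float)
    X = np.column_stack([np.ones(len(train))]
                        + [train[p].to_numpy(float) for p in spec.fixed])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(beta, index=["Intercept", *spec.fixed])


def loso_cv(data, spec: LmmSpec) -> CvResult:
    """Leave-one-study-out CV of the nested mixed model.

    Requires at least three studies so every training set retains the two
    studies needed to separate study effects from residual noise.
    """
    df = _as_frame(data)
    studies = df[spec.study_col].unique().tolist()
    if len(studies) < 3:
        raise ValueError("leave-one-study-out CV needs at least 3 studies")

    pred = np.full(len(df), np.nan)
    diagnostics = []
    n_fallback = 0
    for sid in sorted(studies, key=str):
        held = df[spec.study_col] == sid
        train = df.loc[~held]
        test = df.loc[held]
        if train[spec.study_col].nunique() < 2:
            raise ValueError(
                f"training complement of study {sid!r} has fewer than 2 "
                "studies")
        model = MethaneMixedModel(train, spec.response, spec.fixed,
                                  group_col=spec.group_col,
                                  study_col=spec.study_col)
        fit = model.fit()
        if fit.converged:
            yhat = fit.predict(test)
            diagnostics.append({"study_id": sid, "converged": True,
                                "engine": "reml"})
        else:
            n_fallback += 1
            logger.warning("fold %s: REML did not converge; OLS fallback", sid)
            beta = _ols_fallback(train, spec)
            yhat = np.full(len(test), beta["Intercept"])
            for p in spec.fixed:
                yhat = yhat + beta[p] * test[p].to_numpy(float)
            diagnostics.append({"study_id": sid, "converged": False,
                                "engine": "ols"})
        pred[held.to_numpy()] = yhat

    out = pd.DataFrame({
        "record_id": df["record_id"],
        "observed": df[spec.response].to_numpy(float),
        "predicted": pred,
        "study_id": df[spec.study_col],
        "group_id": df[spec.group_col],
        "region": df.get("region", pd.Series(["?"] * len(df))),
    })
    return CvResult(frame=out, spec=spec, fold_diagnostics=diagnostics,
                    n_ols_fallbacks=n_fallback)


def evaluate_by_scope(cv: CvResult, scope) -> MetricReport:
    """Metric suite on the pooled predictions restricted to a region scope.

    ``scope`` is one of the named scopes (``intercontinental``, ``EU``,
    ``US``) or an explicit iterable of region codes.
    """
    if isinstance(scope, str):
        try:
            regions = SCOPE_REGIONS[scope]
        except KeyError:
            raise ValueError(f"unknown scope {scope!r}; use one of "
                             f"{sorted(SCOPE_REGIONS)} or a region set")
    else:
        regions = tuple(scope)
    sub = cv.frame[cv.frame["region"].isin(regions)]
    if sub.empty:
        raise ValueError(f"no records in scope {regions}")
    return evaluate(sub["observed"].to_numpy(float),
                    sub["predicted"].to_numpy(float))
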