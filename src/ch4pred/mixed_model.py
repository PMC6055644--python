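"""Linear mixed model with study-within-research-group random intercepts.

The model for a response Y (CH4 production, yield or intensity) is

    Y = b0 + b1*X1 + ... + bn*Xn + S_i(R_j) + R_j + e,

with independent Gaussian random intercepts for research group R_j and for
study S_i nested within group, plus a within-experiment residual e.
Estimation is by REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`
(random group intercept plus a variance component for study), so the fit
is deterministic given the data.

Out-of-sample prediction for a *new* study uses the fixed effects only —
the random intercepts have expectation zero for units not seen in
training — which mirrors deploying the equation on a new farm.  The BLUP
of a training group's intercept can optionally be reused.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .records import CowRecord, records_to_frame

__all__ = ["LmmSpec", "MethaneMixedModel", "MethaneMixedModelResults",
           "fit_lmm", "predict_fixed"]


@dataclass(frozen=True)
class LmmSpec:
    """Model specification: response, fixed-effect predictors, grouping."""

    response: str
    fixed: tuple[str, ...]
    group_col: str = "group_id"
    study_col: str = "study_id"

    def __post_init__(self):
        if self.response in self.fixed:
            raise ValueError("response cannot also be a fixed predictor")


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data.reset_index(drop=True)
    return records_to_frame(data)


class MethaneMixedModel:
    """Nested random-intercept model for emission responses.

    Parameters
    ----------
    data : DataFrame or sequence of CowRecord
        Complete cases for the response and all predictors.
    response : str
        Column to model (e.g. ``"ch4"``).
    predictors : sequence of str
        Fixed-effect covariate columns.  Empty for an intercept-only model.
    group_col, study_col : str
        Grouping identifiers; studies must nest within groups.

    Examples
    --------
    >>> model = MethaneMixedModel(df, "ch4", ["dmi", "ndf"])
    >>> res = model.fit()
    >>> res.params["dmi"]  # doctest: +SKIP
    """

    def __init__(self, data, response: str, predictors: Sequence[str],
                 group_col: str = "group_id", study_col: str = "study_id"):
        df = _as_frame(data)
        self.spec = LmmSpec(response=response, fixed=tuple(predictors),
                            group_col=group_col, study_col=study_col)
        cols = [response, *predictors, group_col, study_col]
        missing_cols = [c for c in cols if c not in df.columns]
        if missing_cols:
            raise ValueError(f"data lacks columns {missing_cols}")
        df = df[cols].copy()
        if df[[response, *predictors]].isna().any().any():
            raise ValueError(
                "data contains missing values; run complete_cases first")
        nested = df.groupby(study_col)[group_col].nunique()
        if (nested > 1).any():
            bad = nested[nested > 1].index.tolist()
            raise ValueError(f"studies under multiple groups: {bad}")
        self.data = df
        self.n_obs = len(df)
        self.n_studies = df[study_col].nunique()
        self.n_groups = df[group_col].nunique()
        if self.n_studies < 2:
            raise ValueError(
                "a single study cannot separate study effects from the "
                "residual; fit ordinary least squares instead")

    @classmethod
    def from_records(cls, records: Sequence[CowRecord], spec: LmmSpec
                     ) -> "MethaneMixedModel":
        return cls(records_to_frame(records), spec.response, spec.fixed,
                   group_col=spec.group_col, study_col=spec.study_col)

    def fit(self, reml: bool = True, tol: float = 1e-8
            ) -> "MethaneMixedModelResults":
        """Estimate fixed effects and the three variance components.

        A constant response short-circuits to the exact degenerate answer
        (intercept = constant, everything else zero).  Non-convergence is
        reported on the results object, never raised.
        """
        df = self.data
        spec = self.spec
        y = df[spec.response].to_numpy(float)

        if np.ptp(y) == 0.0:
            params = {"Intercept": float(y[0])}
            params.update({p: 0.0 for p in spec.fixed})
            bse = {k: 0.0 for k in params}
            return MethaneMixedModelResults(
                model=self, params=pd.Series(params), bse=pd.Series(bse),
                var_group=0.0, var_study=0.0, var_resid=0.0,
                log_likelihood=np.nan, converged=True,
                identifiable=self.n_obs > self.n_studies, degenerate=True)

        rhs = " + ".join(spec.fixed) if spec.fixed else "1"
        formula = f"{spec.response} ~ {rhs}"
        md = smf.mixedlm(formula, df, groups=df[spec.group_col],
                         re_formula="1",
                         vc_formula={"study": f"0 + C({spec.study_col})"})
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = md.fit(reml=reml, method=["lbfgs", "powell"],
                             maxiter=2000)
                converged = bool(res.converged)
            except Exception:
                res = md.fit(reml=reml, method="nm", maxiter=5000)
                converged = bool(res.converged)

        fe = res.fe_params.copy()
        bse = res.bse_fe.copy()
        var_group = float(max(res.cov_re.iloc[0, 0], 0.0))
        var_study = float(max(res.vcomp[0], 0.0)) if len(res.vcomp) else 0.0
        var_resid = float(res.scale)
        fitted = np.asarray(res.fittedvalues, dtype=float)
        sse_cond = float(np.sum((y - fitted) ** 2))
        return MethaneMixedModelResults(
            model=self, params=fe, bse=bse,
            var_group=var_group, var_study=var_study, var_resid=var_resid,
            log_likelihood=float(res.llf), converged=converged,
            identifiable=self.n_obs > self.n_studies,
            sse_conditional=sse_cond, _sm_results=res)


class MethaneMixedModelResults:
    """Fitted mixed model: coefficients, variance components, diagnostics.

    Attributes
    ----------
    params, bse : pandas.Series
        Fixed-effect estimates and standard errors, indexed by
        ``Intercept`` and the predictor names.
    var_group, var_study, var_resid : float
        Variances of the group intercept, the study-within-group
        intercept, and the residual.
    converged : bool
        REML optimizer convergence flag.
    identifiable : bool
        False when every study has a single record, in which case the
        study and residual variances cannot be separated and their split
        is arbitrary.
    """

    def __init__(self, model, params, bse, var_group, var_study, var_resid,
                 log_likelihood, converged, identifiable,
                 sse_conditional=np.nan, degenerate=False, _sm_results=None):
        self.model = model
        self.params = pd.Series(params)
        self.bse = pd.Series(bse)
        self.var_group = var_group
        self.var_study = var_study
        self.var_resid = var_resid
        self.log_likelihood = log_likelihood
        self.converged = converged
        self.identifiable = identifiable
        self.sse_conditional = sse_conditional
        self.degenerate = degenerate
        self._sm_results = _sm_results
        if not identifiable:
            warnings.warn(
                "one record per study: study and residual variances are "
                "not separately identifiable", UserWarning, stacklevel=2)

    @property
    def n_obs(self):
        return self.model.n_obs

    @property
    def n_studies(self):
        return self.model.n_studies

    @property
    def n_groups(self):
        return self.model.n_groups

    def predict(self, data, reuse_group_effects: bool = False) -> np.ndarray:
        """Predict the response for new records.

        Fixed effects only by default (new-study prediction).  With
        ``reuse_group_effects`` the BLUP of a training group's intercept is
        added for records whose ``group_id`` was seen in training.
        """
        df = _as_frame(data)
        spec = self.model.spec
        missing = [p for p in spec.fixed if p not in df.columns
                   or df[p].isna().any()]
        if missing:
            raise ValueError(f"prediction inputs missing: {missing}")
        yhat = np.full(len(df), self.params["Intercept"], dtype=float)
        for p in spec.fixed:
            yhat += self.params[p] * df[p].to_numpy(float)
        if reuse_group_effects and self._sm_results is not None:
            re = self._sm_results.random_effects
            blup = {g: float(eff.iloc[0]) for g, eff in re.items()}
            yhat += df[spec.group_col].map(blup).fillna(0.0).to_numpy(float)
        return yhat

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        spec = self.model.spec
        lines = [
            "Nested mixed model (REML)",
            f"  response: {spec.response}   n={self.n_obs}  "
            f"studies={self.n_studies}  groups={self.n_groups}",
            f"  converged: {self.converged}   logLik: {self.log_likelihood:.2f}"
            if np.isfinite(self.log_likelihood) else
            f"  converged: {self.converged}",
            "",
            f"  {'coef':<12}{'estimate':>12}{'se':>12}",
        ]
        for name in self.params.index:
            se = self.bse.get(name, np.nan)
            lines.append(f"  {name:<12}{self.params[name]:>12.4g}{se:>12.4g}")
        lines += [
            "",
            f"  var(group)    {self.var_group:>12.4g}",
            f"  var(study)    {self.var_study:>12.4g}",
            f"  var(residual) {self.var_resid:>12.4g}",
        ]
        if not self.identifiable:
            lines.append("  WARNING: study/residual variances not "
                         "separately identifiable (1 record per study)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.model.spec.response,
            "fixed": list(self.model.spec.fixed),
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "var_group": self.var_group,
            "var_study": self.var_study,
            "var_resid": self.var_resid,
            "n_obs": self.n_obs,
            "n_studies": self.n_studies,
            "n_groups": self.n_groups,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "log_likelihood": (None if not np.isfinite(self.log_likelihood)
                               else self.log_likelihood),
            "sse_conditional": (None if not np.isfinite(self.sse_conditional)
                                else self.sse_conditional),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


# Functional aliases -------------------------------------------------------

def fit_lmm(data, spec: LmmSpec, reml: bool = True) -> MethaneMixedModelResults:
    """Fit the nested mixed model; convenience wrapper over the class API."""
    if isinstance(data, pd.DataFrame):
        model = MethaneMixedModel(data, spec.response, spec.fixed,
                                  group_col=spec.group_col,
                                  study_col=spec.study_col)
    else:
        model = MethaneMixedModel.from_records(data, spec)
    return model.fit(reml=reml)


def predict_fixed(fit: MethaneMixedModelResults, data) -> np.ndarray:
    """Fixed-effects-only prediction (random effects at zero)."""
    return fit.predict(data, reuse_group_effects=False)
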