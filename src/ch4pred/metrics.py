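"""Prediction-error metrics: MSPE decomposition, RSR and concordance.

Given paired observed (O) and predicted (P) vectors:

    MSPE = mean((O - P)^2)            RMSPE = sqrt(MSPE)
    MAE  = mean(|O - P|)              RSR   = RMSPE / So
    MB   = (Pbar - Obar)^2            (mean bias)
    SB   = (Sp - r*So)^2              (slope bias)
    CCC  = r * Cb,   Cb = ((v + 1/v + u^2)/2)^-1,
           v = So/Sp, u = (Pbar - Obar)/sqrt(So*Sp)

with So, Sp the standard deviations of observed and predicted values and
r their Pearson correlation.  All SDs use the population (denominator-n)
form: that convention makes the decomposition

    MSPE = MB + SB + (1 - r^2) * So^2

an exact identity, with the last term the random (unexplained) error.

Statistics that are undefined for constant vectors (r, CCC, RSR, ...) are
reported as ``None`` — an explicit undefined state — while the remaining
metrics are still computed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["MetricReport", "evaluate", "rmspe_pct", "decomposition_pct"]


@dataclass(frozen=True)
class MetricReport:
    """The evaluation bundle for one observed/predicted pairing.

    ``None`` marks a statistic that is undefined for the input (e.g. the
    correlation of a constant vector).  ``mb_pct``/``sb_pct`` express the
    bias components as percentages of MSPE, the convention used when
    tabulating model comparisons.
    """

    n: int
    obs_mean: float
    pred_mean: float
    so: float
    sp: float
    r: float | None
    mspe: float
    rmspe: float
    rmspe_pct: float | None
    mae: float
    rsr: float | None
    mb: float
    sb: float | None
    random_error: float | None
    mb_pct: float | None
    sb_pct: float | None
    ccc: float | None
    cb: float | None
    v_scale: float | None
    u_shift: float | None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def summary(self) -> str:
        def f(x, fmt="{:.4g}"):
            return "undefined" if x is None else fmt.format(x)
        return "\n".join([
            f"n             {self.n}",
            f"observed mean {self.obs_mean:.4g}   predicted mean {self.pred_mean:.4g}",
            f"MSPE          {self.mspe:.4g}   RMSPE {self.rmspe:.4g} "
            f"({f(self.rmspe_pct, '{:.2f}')}% of observed mean)",
            f"MAE           {self.mae:.4g}   RSR {f(self.rsr)}",
            f"mean bias     {self.mb:.4g} ({f(self.mb_pct, '{:.1f}')}% of MSPE)",
            f"slope bias    {f(self.sb)} ({f(self.sb_pct, '{:.1f}')}% of MSPE)",
            f"random error  {f(self.random_error)}",
            f"r             {f(self.r)}   Cb {f(self.cb)}   CCC {f(self.ccc)}",
        ])


def evaluate(observed, predicted) -> MetricReport:
    """Compute the full metric suite for paired vectors.

    Parameters
    ----------
    observed, predicted : array-like
        Equal-length (>= 2) finite vectors in the same units.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-D")
    n = obs.size
    if n < 2:
        raise ValueError("need at least two observations")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("inputs must be finite")

    obar = float(obs.mean())
    pbar = float(pred.mean())
    so = float(obs.std(ddof=0))
    sp = float(pred.std(ddof=0))
    err = obs - pred
    mspe = float(np.mean(err ** 2))
    rmspe = math.sqrt(mspe)
    mae = float(np.mean(np.abs(err)))
    mb = (pbar - obar) ** 2

    r = None
    if so > 0 and sp > 0:
        r = float(np.mean((obs - obar) * (pred - pbar)) / (so * sp))
        r = max(-1.0, min(1.0, r))

    sb = (sp - r * so) ** 2 if r is not None else None
    random_error = mspe - mb - sb if sb is not None else None
    rsr = rmspe / so if so > 0 else None
    rp = 100.0 * rmspe / obar if obar != 0 else None

    if mspe > 0 and sb is not None:
        mb_pct = 100.0 * mb / mspe
        sb_pct = 100.0 * sb / mspe
    elif mspe == 0:
        mb_pct, sb_pct = 0.0, 0.0
    else:
        mb_pct = sb_pct = None

    ccc = cb = v = u = None
    if so > 0 and sp > 0:
        v = so / sp
        u = (pbar - obar) / math.sqrt(so * sp)
        cb = ((v + 1.0 / v + u * u) / 2.0) ** -1
        ccc = r * cb

    return MetricReport(
        n=n, obs_mean=obar, pred_mean=pbar, so=so, sp=sp, r=r,
        mspe=mspe, rmspe=rmspe, rmspe_pct=rp, mae=mae, rsr=rsr,
        mb=mb, sb=sb, random_error=random_error,
        mb_pct=mb_pct, sb_pct=sb_pct,
        ccc=ccc, cb=cb, v_scale=v, u_shift=u,
    )


def rmspe_pct(report: MetricReport) -> float:
    """RMSPE as a percentage of the observed mean."""
    if report.obs_mean == 0:
        raise ValueError("undefined: observed mean is zero")
    return 100.0 * report.rmspe / report.obs_mean


def decomposition_pct(report: MetricReport) -> tuple[float, float]:
    """(mean bias, slope bias) as percentages of MSPE; (0, 0) when MSPE=0."""
    if report.mspe == 0:
        return (0.0, 0.0)
    if report.sb is None:
        raise ValueError("slope bias undefined (constant vector)")
    return (100.0 * report.mb / report.mspe, 100.0 * report.sb / report.mspe)
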