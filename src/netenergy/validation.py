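"""Agreement statistics for predicted vs observed net energy.

Implements the mean squared prediction error (MSPE), its percent form,
the bias / slope / disturbance decomposition

    MSPE = (P̄ − Ō)²  +  (Sp − R·So)²  +  (1 − R²)·So²
           ECT            ER                ED

and Lin's concordance correlation coefficient

    CCC = R · Cb,   Cb = 2 / (υ + 1/υ + µ²),
    υ = So/Sp,      µ = (Ō − P̄)/√(So·Sp).

The decomposition and CCC use population (n-denominator) moments
throughout, which is what makes the three components sum to the MSPE
exactly and makes the component form of the CCC equal Lin's direct form
2·cov / (var_o + var_p + (Ō − P̄)²).  Descriptive standard deviations in
the report use the sample (n−1) convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "mspe",
    "pct_error",
    "decompose_mspe",
    "ccc",
    "validate",
    "ValidationReport",
]


def _paired(observed, predicted, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.ndim != 1:
        raise ValueError("observed and predicted must be 1-d arrays of equal length")
    if o.size < min_n:
        raise ValueError(f"need at least {min_n} paired values, got {o.size}")
    return o, p


def mspe(observed, predicted) -> float:
    """Mean squared prediction error, mean of (Oi − Pi)²."""
    o, p = _paired(observed, predicted, 2)
    return float(np.mean((o - p) ** 2))


def pct_error(mspe_value: float, mean_obs: float, *, rmspe: bool = True) -> float:
    """Prediction error as percent of the observed mean.

    With ``rmspe=True`` (default) this is 100·√MSPE/Ō, the root-MSPE
    expressed relative to the observed mean; ``rmspe=False`` uses the
    raw MSPE in the numerator.
    """
    if mean_obs <= 0:
        raise ValueError("mean_obs must be positive")
    if mspe_value < 0:
        raise ValueError("mspe must be non-negative")
    num = math.sqrt(mspe_value) if rmspe else mspe_value
    return 100.0 * num / mean_obs


class MSPEDecomposition(NamedTuple):
    ect: float
    er: float
    ed: float
    ect_pct: float
    er_pct: float
    ed_pct: float


def decompose_mspe(observed, predicted) -> MSPEDecomposition:
    """Split the MSPE into bias (ECT), slope (ER) and disturbance (ED) parts."""
    o, p = _paired(observed, predicted, 3)
    so = float(np.std(o))  # population moments: required for the exact identity
    sp = float(np.std(p))
    if so == 0 or sp == 0:
        raise ValueError("degenerate input: zero variance in observed or predicted")
    r = float(np.corrcoef(o, p)[0, 1])
    ect = float((p.mean() - o.mean()) ** 2)
    er = float((sp - r * so) ** 2)
    ed = float((1.0 - r**2) * so**2)
    total = ect + er + ed
    if total == 0:  # perfect prediction: no error to apportion
        return MSPEDecomposition(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    return MSPEDecomposition(
        ect, er, ed, 100.0 * ect / total, 100.0 * er / total, 100.0 * ed / total
    )


class CCCResult(NamedTuple):
    ccc: float
    r: float
    cb: float
    upsilon: float
    mu: float


def ccc(observed, predicted) -> CCCResult:
    """Lin's concordance correlation with its accuracy/shift components."""
    o, p = _paired(observed, predicted, 3)
    so = float(np.std(o))
    sp = float(np.std(p))
    if so == 0 or sp == 0:
        raise ValueError("degenerate input: zero variance in observed or predicted")
    r = float(np.corrcoef(o, p)[0, 1])
    upsilon = so / sp
    mu = float((o.mean() - p.mean()) / math.sqrt(so * sp))
    cb = 2.0 / (upsilon + 1.0 / upsilon + mu**2)
    return CCCResult(r * cb, r, cb, upsilon, mu)


@dataclass(frozen=True)
class ValidationReport:
    """Full agreement report for one predicted-vs-observed comparison."""

    n: int
    mean_obs: float
    mean_pred: float
    sd_obs: float       # sample (n-1)
    sd_pred: float
    r: float
    mspe: float
    rmspe: float
    pct_error: float
    ect: float
    er: float
    ed: float
    ect_pct: float
    er_pct: float
    ed_pct: float
    ccc: float
    cb: float
    upsilon: float
    mu: float

    def summary(self) -> str:
        f = [
            ("n", f"{self.n}"),
            ("mean observed, kcal/day", f"{self.mean_obs:.2f}"),
            ("mean predicted, kcal/day", f"{self.mean_pred:.2f}"),
            ("sd observed (So)", f"{self.sd_obs:.2f}"),
            ("sd predicted (Sp)", f"{self.sd_pred:.2f}"),
            ("R", f"{self.r:.3f}"),
            ("R^2", f"{self.r**2:.3f}"),
            ("MSPE, kcal^2", f"{self.mspe:.2f}"),
            ("% error", f"{self.pct_error:.2f}"),
            ("ECT, %", f"{self.ect_pct:.2f}"),
            ("ER, %", f"{self.er_pct:.2f}"),
            ("ED, %", f"{self.ed_pct:.2f}"),
            ("CCC", f"{self.ccc:.3f}"),
            ("Cb", f"{self.cb:.3f}"),
            ("upsilon", f"{self.upsilon:.2f}"),
            ("mu", f"{self.mu:.2f}"),
        ]
        width = max(len(k) for k, _ in f)
        return "\n".join(f"{k:<{width}} : {v}" for k, v in f)

    def to_frame(self) -> pd.DataFrame:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return pd.DataFrame({"statistic": list(d), "value": list(d.values())})


def validate(observed, predicted, *, rmspe_pct: bool = True) -> ValidationReport:
    """Compute the complete agreement report for paired vectors (kcal/day)."""
    o, p = _paired(observed, predicted, 3)
    if np.mean(o) <= 0:
        warnings.warn("non-positive observed mean; % error is not meaningful", UserWarning)
    m = mspe(o, p)
    dec = decompose_mspe(o, p)
    c = ccc(o, p)
    return ValidationReport(
        n=int(o.size),
        mean_obs=float(o.mean()),
        mean_pred=float(p.mean()),
        sd_obs=float(np.std(o, ddof=1)),
        sd_pred=float(np.std(p, ddof=1)),
        r=c.r,
        mspe=m,
        rmspe=math.sqrt(m),
        pct_error=pct_error(m, float(o.mean()), rmspe=rmspe_pct) if o.mean() > 0 else math.nan,
        ect=dec.ect,
        er=dec.er,
        ed=dec.ed,
        ect_pct=dec.ect_pct,
        er_pct=dec.er_pct,
        ed_pct=dec.ed_pct,
        ccc=c.ccc,
        cb=c.cb,
        upsilon=c.upsilon,
        mu=c.mu,
    )
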