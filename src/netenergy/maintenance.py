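"""Maintenance-requirement estimation.

Two estimators for the net energy required for maintenance (NEm) and the
efficiency k of metabolizable-energy use:

* :class:`MaintenanceRegression` — ordinary least squares of retained
  energy on metabolizable energy intake across feeding levels,

      RE/W^0.75 = -NEm + k * MEI/W^0.75,

  so k is the slope and NEm the (negated) intercept, both in
  kcal/kg^0.75/day when fitted in metabolic units.

* :class:`FarrellSystem` — the two-feeding-level simultaneous-equation
  technique: the same line is forced through the energy balances observed
  at two intake levels, giving a closed-form 2x2 solve for (k, NEm)
  without replication.

Both return a :class:`MaintenanceFit` results object.  MEm, the
metabolizable energy required for maintenance, is NEm/k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .balance import EnergyBalance

__all__ = [
    "MaintenanceFit",
    "MaintenanceRegression",
    "FarrellSystem",
    "fit_re_on_mei",
    "farrell_solve",
    "build_farrell_inputs",
    "mem_from",
]


def mem_from(nem_coef: float, k: float) -> float:
    """Metabolizable energy for maintenance, MEm = NEm / k (kcal/kg^0.75/day)."""
    if k <= 0:
        raise ValueError("k must be positive")
    return nem_coef / k


@dataclass
class MaintenanceFit:
    """Result of a maintenance estimation.

    ``nem_coef`` is NEm per unit metabolic weight (kcal/kg^0.75/day) —
    the negated intercept of the regression line, or the coefficient `a`
    of the two-level solve.  ``mem_coef`` is derived as ``nem_coef / k``
    so the identity MEm·k = NEm holds exactly.
    """

    diet_id: str
    method: str                      # "regression" | "farrell"
    k: float
    nem_coef: float
    n_points: int
    r2: float = math.nan
    k_se: float = math.nan
    nem_se: float = math.nan
    flags: list[str] = field(default_factory=list)

    @property
    def mem_coef(self) -> float:
        return mem_from(self.nem_coef, self.k)

    def equation(self) -> str:
        """Render the fitted line the way regression tables print it."""
        return f"RE={-self.nem_coef:.2f}+{self.k:.2f}·MEI"

    def predict_re(self, mei) -> np.ndarray | float:
        """Retained energy on the fitted line at the given intake (same units as the fit)."""
        return self.k * np.asarray(mei, dtype=float) - self.nem_coef

    def summary(self) -> str:
        lines = [
            f"Maintenance fit ({self.method})" + (f" — diet {self.diet_id}" if self.diet_id else ""),
            f"  {self.equation()}   (n = {self.n_points})",
            f"  k    = {self.k:.4f}" + ("" if math.isnan(self.k_se) else f"  (se {self.k_se:.4f})"),
            f"  NEm  = {self.nem_coef:.2f} kcal/kg^0.75/day"
            + ("" if math.isnan(self.nem_se) else f"  (se {self.nem_se:.2f})"),
            f"  MEm  = {self.mem_coef:.2f} kcal/kg^0.75/day",
        ]
        if not math.isnan(self.r2):
            lines.append(f"  R^2  = {self.r2:.3f}")
        for flag in self.flags:
            lines.append(f"  warning: {flag}")
        return "\n".join(lines)

    def to_row(self) -> dict:
        return {
            "diet_id": self.diet_id,
            "method": self.method,
            "equation": self.equation(),
            "nem_coef_kcal_kg075_day": self.nem_coef,
            "mem_coef_kcal_kg075_day": self.mem_coef,
            "k": self.k,
            "r2": self.r2,
            "n_points": self.n_points,
            "flags": ";".join(self.flags),
        }


class MaintenanceRegression:
    """OLS of retained energy on metabolizable energy intake.

    Parameters
    ----------
    mei, re
        Paired observations.  If ``w_meta`` is given they are raw
        kcal/day values and are divided by metabolic weight point-wise;
        otherwise they must already be in metabolic units
        (kcal/kg^0.75/day) when ``metabolic=True``.
    metabolic
        Fit in metabolic units (the convention under which k and NEm are
        reported).  Set False for a whole-animal fit for comparison.
    """

    def __init__(
        self,
        mei: Sequence[float],
        re: Sequence[float],
        *,
        w_meta: Sequence[float] | None = None,
        diet_id: str = "",
        metabolic: bool = True,
    ) -> None:
        mei = np.asarray(mei, dtype=float)
        re = np.asarray(re, dtype=float)
        if mei.shape != re.shape or mei.ndim != 1:
            raise ValueError("mei and re must be 1-d arrays of equal length")
        if mei.size < 2:
            raise ValueError("at least two (MEI, RE) points are required")
        if w_meta is not None and metabolic:
            w = np.asarray(w_meta, dtype=float)
            mei = mei / w
            re = re / w
        if np.ptp(mei) == 0:
            raise ValueError("degenerate design: all MEI values equal (singular fit)")
        self.mei = mei
        self.re = re
        self.diet_id = diet_id
        self.metabolic = metabolic

    @classmethod
    def from_balances(
        cls, balances: Sequence[EnergyBalance], diet_id: str = "", **kwargs
    ) -> "MaintenanceRegression":
        """Build from energy balances (metabolic units taken from each balance)."""
        if diet_id:
            balances = [b for b in balances if b.diet_id == diet_id]
        if not balances:
            raise ValueError("no balances for the requested diet")
        return cls(
            [b.mei for b in balances],
            [b.re for b in balances],
            w_meta=[b.w_meta for b in balances],
            diet_id=diet_id or balances[0].diet_id,
            **kwargs,
        )

    def fit(self) -> MaintenanceFit:
        X = sm.add_constant(self.mei)
        res = sm.OLS(self.re, X).fit()
        intercept, slope = res.params
        flags = []
        if intercept >= 0:
            flags.append("non-negative intercept implies NEm <= 0")
        if not 0 < slope < 1:
            flags.append(f"k = {slope:.3f} outside (0, 1)")
        return MaintenanceFit(
            diet_id=self.diet_id,
            method="regression",
            k=float(slope),
            nem_coef=float(-intercept),
            n_points=int(self.mei.size),
            r2=float(res.rsquared),
            k_se=float(res.bse[1]),
            nem_se=float(res.bse[0]),
            flags=flags,
        )


def fit_re_on_mei(points: Sequence[tuple[float, float]], diet_id: str = "") -> MaintenanceFit:
    """Functional wrapper: fit from (MEI/W^0.75, RE/W^0.75) pairs."""
    pts = np.asarray(points, dtype=float)
    return MaintenanceRegression(pts[:, 0], pts[:, 1], diet_id=diet_id).fit()


@dataclass
class FarrellSystem:
    """Two-level simultaneous-equation model for (k, NEm).

    ``eq_high``/``eq_low`` are (MEI/W^0.75, RE/W^0.75) pairs, both in
    kcal/kg^0.75/day, at the higher and lower feeding level.  ``fit``
    solves

        re_high = -a + k * me_high
        re_low  = -a + k * me_low

    for X = k and Y = -a.
    """

    eq_high: tuple[float, float]
    eq_low: tuple[float, float]
    diet_id: str = ""

    def fit(self) -> MaintenanceFit:
        (m1, r1), (m2, r2) = self.eq_high, self.eq_low
        if m1 == m2:
            raise ValueError("singular system: the two MEI/W^0.75 values are equal")
        A = np.array([[m1, 1.0], [m2, 1.0]])
        b = np.array([r1, r2])
        x, y = np.linalg.solve(A, b)
        k, nem_coef = float(x), float(-y)
        flags = []
        if not 0 < k < 1:
            flags.append(f"k = {k:.3f} outside (0, 1)")
        if nem_coef <= 0:
            flags.append(f"a = {nem_coef:.3f} is non-positive")
        return MaintenanceFit(
            diet_id=self.diet_id,
            method="farrell",
            k=k,
            nem_coef=nem_coef,
            n_points=2,
            flags=flags,
        )


def farrell_solve(
    eq_high: tuple[float, float], eq_low: tuple[float, float], diet_id: str = ""
) -> MaintenanceFit:
    """Closed-form 2x2 solve of the two-level maintenance system."""
    return FarrellSystem(eq_high, eq_low, diet_id=diet_id).fit()


def build_farrell_inputs(
    balance_high: EnergyBalance, balance_low: EnergyBalance
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Metabolic-unit (MEI, RE) pairs for the two-level solve.

    The two balances must come from the same diet at distinct feeding
    levels; the higher-intake balance supplies the first equation.
    """
    if balance_high.diet_id != balance_low.diet_id:
        raise ValueError("both balances must come from the same diet")
    if balance_high.feeding_level == balance_low.feeding_level:
        raise ValueError("the two balances must come from distinct feeding levels")
    if balance_high.feeding_level < balance_low.feeding_level:
        balance_high, balance_low = balance_low, balance_high
    eq = lambda b: (b.mei / b.w_meta, b.re / b.w_meta)
    return eq(balance_high), eq(balance_low)


def fit_table(fits: Sequence[MaintenanceFit]) -> pd.DataFrame:
    """Tidy frame of fits, one row per diet, mirroring a regression table."""
    return pd.DataFrame([f.to_row() for f in fits])
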