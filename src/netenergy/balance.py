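"""Energy-partition bookkeeping for comparative-slaughter feeding trials.

A trial record (one replicate pen) carries body weights and whole-body
combustible energies at the start and end of the period plus feed intake
and the diet's metabolizable energy (ME).  From these the classical
partition of metabolizable energy intake (MEI) follows:

    RE  = (body energy end - body energy start) / period     retained energy
    HP  = MEI - RE                                           heat production
    NEm = nem_coef * W^0.75                                  maintenance
    HI  = HP - NEm                                           heat increment
    NE  = NEm + RE                                           net energy

All energies are kcal/day per bird, masses kg, intakes g dry matter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PenRecord",
    "EnergyBalance",
    "ImplausibleRecordWarning",
    "compute_bwg",
    "compute_avg_weight",
    "metabolic_weight",
    "me_n_corrected",
    "compute_mei",
    "compute_re",
    "compute_hp",
    "compute_hi",
    "compute_ne",
    "balance_pen",
    "balance_table",
    "summarize_partition",
    "KCAL_PER_G_RETAINED_N",
    "KCAL_PER_G_PROTEIN",
    "KCAL_PER_G_LIPID",
]

#: Energy equivalent of retained nitrogen used in the N-corrected apparent
#: ME calculation (Hill & Anderson convention), kcal per g retained N.
KCAL_PER_G_RETAINED_N = 8.22

#: Combustion equivalents used to split retained energy into its protein
#: and lipid fractions, kcal per g of tissue gained.
KCAL_PER_G_PROTEIN = 5.66
KCAL_PER_G_LIPID = 9.35


class ImplausibleRecordWarning(UserWarning):
    """A record or derived quantity is physiologically implausible but usable."""


@dataclass(frozen=True)
class PenRecord:
    """Raw measurements for one replicate pen, expressed per bird.

    ``bw_start``/``bw_end`` are live weights (kg) at the start and end of
    the balance period; ``re_start``/``re_end`` are whole-body combustible
    energies (kcal) at the same ages; ``feed_intake_total`` is cumulative
    dry-matter intake (g) over the period.  ``n_birds`` records pen size;
    quantities entered as pen totals can be normalised per bird via
    :func:`balance_pen` with ``pen_totals=True``.
    """

    diet_id: str
    feeding_level: float
    replicate_id: str
    bw_start: float
    bw_end: float
    n_birds: int
    feed_intake_total: float
    me_diet: float
    re_start: float
    re_end: float
    period_days: float = 14.0
    protein_gain: float | None = None
    lipid_gain: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.feeding_level <= 1.0:
            raise ValueError(f"feeding_level must lie in (0, 1], got {self.feeding_level}")
        if not 0.0 < self.bw_start < self.bw_end:
            raise ValueError(
                f"body weights must satisfy 0 < bw_start < bw_end, got "
                f"({self.bw_start}, {self.bw_end})"
            )
        if self.feed_intake_total <= 0:
            raise ValueError("feed_intake_total must be positive")
        if self.period_days <= 0:
            raise ValueError("period_days must be positive")
        if self.n_birds < 1:
            raise ValueError("n_birds must be at least 1")
        if self.me_diet <= 0:
            raise ValueError("me_diet must be positive")
        if self.re_end < self.re_start:
            # Negative retention occurs below maintenance; keep the record
            # but flag it so downstream users notice.
            warnings.warn(
                f"pen {self.diet_id}/{self.replicate_id}: re_end < re_start "
                "(negative energy retention)",
                ImplausibleRecordWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class EnergyBalance:
    """Derived per-bird daily energy partition for one pen or group.

    ``nem``, ``hi``, ``ne`` and the percent-of-MEI ratios require a
    maintenance coefficient (kcal/kg^0.75/day) and are NaN until one is
    supplied (see :func:`balance_pen`).
    """

    diet_id: str
    feeding_level: float
    replicate_id: str
    bwg: float          # g/day
    w_avg: float        # kg
    w_meta: float       # kg^0.75
    fi: float           # g DM/day
    mei: float          # kcal/day
    re: float           # kcal/day
    hp: float           # kcal/day
    nem: float = math.nan
    hi: float = math.nan
    ne: float = math.nan
    re_protein: float = math.nan
    re_lipid: float = math.nan

    @property
    def ratios(self) -> dict[str, float]:
        """Each partition component as percent of MEI."""
        return {
            "re_pct": 100.0 * self.re / self.mei,
            "hp_pct": 100.0 * self.hp / self.mei,
            "nem_pct": 100.0 * self.nem / self.mei,
            "hi_pct": 100.0 * self.hi / self.mei,
            "ne_pct": 100.0 * self.ne / self.mei,
        }

    def with_maintenance(self, nem_coef: float) -> "EnergyBalance":
        """Complete the partition given a maintenance coefficient (kcal/kg^0.75/day)."""
        nem = nem_coef * self.w_meta
        return replace(
            self,
            nem=nem,
            hi=compute_hi(self.hp, nem),
            ne=compute_ne(nem, self.re),
        )


def compute_bwg(bw_start: float, bw_end: float, period_days: float) -> float:
    """Body-weight gain, g/day, from start/end weights in kg."""
    if period_days <= 0:
        raise ValueError("period_days must be positive")
    if bw_end <= bw_start:
        raise ValueError("bw_end must exceed bw_start for a growing bird")
    return 1000.0 * (bw_end - bw_start) / period_days


def compute_avg_weight(bw_start: float, bw_end: float) -> float:
    """Mean of start and end body weight, kg."""
    if bw_start <= 0 or bw_end <= 0:
        raise ValueError("body weights must be positive")
    return 0.5 * (bw_start + bw_end)


def metabolic_weight(w: float) -> float:
    """Metabolic body weight W^0.75, the standard allometric scaling."""
    w = np.asarray(w, dtype=float) if not np.isscalar(w) else w
    if np.any(np.asarray(w) <= 0):
        raise ValueError("body weight must be positive")
    return w ** 0.75


def me_n_corrected(
    ge_intake: float,
    ge_excreta: float,
    n_retained: float,
    feed_intake: float,
    c_n: float = KCAL_PER_G_RETAINED_N,
) -> float:
    """Nitrogen-corrected apparent ME of the diet, kcal/g DM.

    ``ge_intake`` and ``ge_excreta`` are gross energies (kcal) of feed
    consumed and excreta voided over the collection period; ``n_retained``
    is g of nitrogen retained, charged at ``c_n`` kcal/g.
    """
    if feed_intake <= 0:
        raise ValueError("feed_intake must be positive")
    if not ge_intake >= ge_excreta >= 0:
        raise ValueError("require ge_intake >= ge_excreta >= 0")
    me = (ge_intake - ge_excreta - c_n * n_retained) / feed_intake
    if me < 0:
        warnings.warn(
            "nitrogen correction drove apparent ME negative; record implausible",
            ImplausibleRecordWarning,
            stacklevel=2,
        )
    return me


def compute_mei(me_diet: float, fi: float) -> float:
    """Metabolizable energy intake, kcal/day = diet ME (kcal/g DM) x intake (g DM/day)."""
    if me_diet <= 0 or fi <= 0:
        raise ValueError("me_diet and fi must be positive")
    return me_diet * fi


def compute_re(re_start: float, re_end: float, period_days: float) -> float:
    """Retained energy, kcal/day, from whole-body energies at the two slaughters."""
    if period_days <= 0:
        raise ValueError("period_days must be positive")
    re = (re_end - re_start) / period_days
    if re < 0:
        warnings.warn(
            "negative retained energy (below-maintenance feeding)",
            ImplausibleRecordWarning,
            stacklevel=2,
        )
    return re


def compute_hp(mei: float, re: float) -> float:
    """Heat production, kcal/day: the MEI not retained in tissue."""
    return mei - re


def compute_hi(hp: float, nem: float) -> float:
    """Heat increment, kcal/day: heat production in excess of maintenance."""
    return hp - nem


def compute_ne(nem: float, re: float) -> float:
    """Net energy, kcal/day: maintenance plus retention."""
    return nem + re


def balance_pen(
    pen: PenRecord,
    nem_coef: float | None = None,
    *,
    pen_totals: bool = False,
    protein_kcal: float = KCAL_PER_G_PROTEIN,
    lipid_kcal: float = KCAL_PER_G_LIPID,
) -> EnergyBalance:
    """Derive the energy partition for one pen record.

    Parameters
    ----------
    pen
        The raw record.  Weights are always per bird; with
        ``pen_totals=True`` intake, carcass energies and tissue gains are
        treated as pen totals and divided by ``pen.n_birds``.
    nem_coef
        Maintenance coefficient, kcal per kg^0.75 per day.  When omitted
        the maintenance-dependent fields (NEm, HI, NE) are NaN; they can
        be filled later with :meth:`EnergyBalance.with_maintenance` once a
        maintenance fit is available.
    """
    scale = 1.0 / pen.n_birds if pen_totals else 1.0
    fi_total = pen.feed_intake_total * scale
    re_start = pen.re_start * scale
    re_end = pen.re_end * scale

    bwg = compute_bwg(pen.bw_start, pen.bw_end, pen.period_days)
    w_avg = compute_avg_weight(pen.bw_start, pen.bw_end)
    w_meta = metabolic_weight(w_avg)
    fi = fi_total / pen.period_days
    mei = compute_mei(pen.me_diet, fi)
    re = compute_re(re_start, re_end, pen.period_days)
    hp = compute_hp(mei, re)

    re_protein = math.nan
    re_lipid = math.nan
    if pen.protein_gain is not None:
        re_protein = protein_kcal * pen.protein_gain * scale / pen.period_days
    if pen.lipid_gain is not None:
        re_lipid = lipid_kcal * pen.lipid_gain * scale / pen.period_days

    bal = EnergyBalance(
        diet_id=pen.diet_id,
        feeding_level=pen.feeding_level,
        replicate_id=pen.replicate_id,
        bwg=bwg,
        w_avg=w_avg,
        w_meta=w_meta,
        fi=fi,
        mei=mei,
        re=re,
        hp=hp,
        re_protein=re_protein,
        re_lipid=re_lipid,
    )
    if nem_coef is not None:
        bal = bal.with_maintenance(nem_coef)
    return bal


def balance_table(
    pens: Iterable[PenRecord],
    nem_coefs: Mapping[str, float] | float | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Energy balances for many pens as a tidy frame (one row per pen).

    ``nem_coefs`` may be a single coefficient, a mapping diet_id -> coefficient,
    or None (maintenance columns left NaN).
    """
    rows = []
    for pen in pens:
        if nem_coefs is None:
            coef = None
        elif isinstance(nem_coefs, Mapping):
            coef = nem_coefs.get(pen.diet_id)
        else:
            coef = float(nem_coefs)
        bal = balance_pen(pen, coef, **kwargs)
        row = {
            "diet_id": bal.diet_id,
            "feeding_level": bal.feeding_level,
            "replicate_id": bal.replicate_id,
            "bwg_g_day": bal.bwg,
            "w_avg_kg": bal.w_avg,
            "w_meta_kg075": bal.w_meta,
            "fi_g_day": bal.fi,
            "mei_kcal_day": bal.mei,
            "re_kcal_day": bal.re,
            "hp_kcal_day": bal.hp,
            "nem_kcal_day": bal.nem,
            "hi_kcal_day": bal.hi,
            "ne_kcal_day": bal.ne,
            "rep_kcal_day": bal.re_protein,
            "rel_kcal_day": bal.re_lipid,
        }
        rows.append(row)
    if not rows:
        raise ValueError("no pen records supplied")
    return pd.DataFrame(rows)


_SUMMARY_QUANTITIES = ("mei", "re", "hp", "nem", "hi", "ne")


def summarize_partition(balances: Sequence[EnergyBalance]) -> pd.DataFrame:
    """Across-group summary of the partition, long format.

    Absolute quantities (kcal/day) are averaged across groups; the
    percent-of-MEI ratios are computed per group first and then averaged
    (mean of ratios, not ratio of means) with their range reported.
    Returns columns ``quantity``, ``statistic``, ``value``.
    """
    balances = list(balances)
    if not balances:
        raise ValueError("summarize_partition requires at least one balance")
    rows = []
    for q in _SUMMARY_QUANTITIES:
        vals = np.array([getattr(b, q) for b in balances], dtype=float)
        rows.append({"quantity": f"{q}_kcal_day", "statistic": "mean", "value": vals.mean()})
    for q in _SUMMARY_QUANTITIES:
        if q == "mei":
            continue
        pct = np.array([100.0 * getattr(b, q) / b.mei for b in balances])
        rows.append({"quantity": f"{q}_pct_mei", "statistic": "mean", "value": pct.mean()})
        rows.append({"quantity": f"{q}_pct_mei", "statistic": "min", "value": pct.min()})
        rows.append({"quantity": f"{q}_pct_mei", "statistic": "max", "value": pct.max()})
    return pd.DataFrame(rows)
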