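"""Bundled reference fixtures (published trial tables, hand-transcribed).

See ``data/fixtures/README.md`` for provenance notes.  All loaders
return fresh DataFrames.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_table3",
    "load_table4",
    "load_table5",
    "load_table6",
    "load_table7",
    "load_farrell_system",
]

def _load(name: str) -> pd.DataFrame:
    with resources.files("netenergy").joinpath(f"data/fixtures/{name}").open() as fh:
        return pd.read_csv(fh)


def load_table3() -> pd.DataFrame:
    """Per-diet RE-on-MEI regression results (NEm, MEm, k, R^2)."""
    return _load("table3.csv")


def load_table4() -> pd.DataFrame:
    """Ad-libitum energy partition per diet (experiment 1)."""
    return _load("table4.csv")


def load_table5() -> pd.DataFrame:
    """Basal-diet partition by feeding level, incl. protein/lipid RE split."""
    return _load("table5.csv")


def load_table6() -> pd.DataFrame:
    """Determined (observed) energy values per diet (experiment 2)."""
    return _load("table6.csv")


def load_table7() -> pd.DataFrame:
    """Validation table: predicted vs determined NE per diet."""
    return _load("table7.csv")


def load_farrell_system() -> tuple[tuple[float, float], tuple[float, float]]:
    """The published two-level metabolic-unit system for the basal diet.

    Returns ``(eq_high, eq_low)`` pairs of (MEI/W^0.75, RE/W^0.75),
    kcal/kg^0.75/day, at ad libitum and 70 % of ad libitum.
    """
    df = _load("farrell_system.csv").sort_values("feeding_level", ascending=False)
    high, low = df.iloc[0], df.iloc[1]
    return (
        (float(high["mei_per_w075_kcal_kg075_day"]), float(high["re_per_w075_kcal_kg075_day"])),
        (float(low["mei_per_w075_kcal_kg075_day"]), float(low["re_per_w075_kcal_kg075_day"])),
    )
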