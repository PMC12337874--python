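"""CSV and config I/O.

Input pen-record CSVs use the raw field names of
:class:`~netenergy.balance.PenRecord`; all output CSVs carry explicit
unit suffixes in their headers.  Files are comma-separated UTF-8 with
'.' as the decimal separator and a mandatory header row.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .balance import PenRecord
from .simulate import DietSpec, TrialDesign

__all__ = [
    "ParseError",
    "read_pen_records",
    "write_pen_records",
    "read_balance_table",
    "read_design",
]

_REQUIRED = (
    "diet_id",
    "feeding_level",
    "replicate_id",
    "bw_start",
    "bw_end",
    "n_birds",
    "feed_intake_total",
    "me_diet",
    "re_start",
    "re_end",
)
_OPTIONAL = ("period_days", "protein_gain", "lipid_gain")


class ParseError(ValueError):
    """A CSV cell or header could not be interpreted."""


def read_pen_records(path: str | Path) -> list[PenRecord]:
    """Read one PenRecord per row; empty optional cells become defaults/None."""
    try:
        # round_trip parsing keeps re-read outputs bit-identical to what was written
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty or headerless CSV") from exc
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ParseError(f"{path}: no data rows")
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col in _REQUIRED + tuple(c for c in _OPTIONAL if c in df.columns):
            val = row[col]
            if col in ("diet_id", "replicate_id"):
                kwargs[col] = str(val)
                continue
            if pd.isna(val):
                if col in _OPTIONAL:
                    continue
                raise ParseError(f"{path}: row {idx + 2}, column '{col}' is empty")
            try:
                kwargs[col] = int(val) if col == "n_birds" else float(val)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: row {idx + 2}, column '{col}': non-numeric value {val!r}"
                ) from exc
        try:
            records.append(PenRecord(**kwargs))
        except ValueError as exc:
            raise ParseError(f"{path}: row {idx + 2}: {exc}") from exc
    return records


def write_pen_records(pens: Sequence[PenRecord], path: str | Path) -> None:
    rows = []
    for p in pens:
        row = {c: getattr(p, c) for c in _REQUIRED + _OPTIONAL}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_balance_table(path: str | Path) -> pd.DataFrame:
    """Read an energy-balance CSV written by the balance stage."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("diet_id", "feeding_level", "mei_kcal_day", "re_kcal_day", "w_meta_kg075"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column '{col}'")
    return df


def read_design(path: str | Path) -> TrialDesign:
    """Read a trial design from a YAML key-value config.

    Top-level keys are TrialDesign fields; ``diets`` is a list of
    mappings with DietSpec fields.
    """
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "diets" not in cfg:
        raise ParseError(f"{path}: design config must be a mapping with a 'diets' list")
    diets = tuple(DietSpec(**d) for d in cfg.pop("diets"))
    fl = cfg.pop("feeding_levels", None)
    kwargs = dict(cfg)
    if fl is not None:
        kwargs["feeding_levels"] = tuple(fl)
    try:
        return TrialDesign(diets=diets, **kwargs)
    except TypeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
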