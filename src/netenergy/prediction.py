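"""The net-energy requirement prediction model NE = a·W^0.75 + RE.

``a`` is the maintenance coefficient (kcal per kg^0.75 per day), usually
obtained from the two-level simultaneous-equation solve on the basal
diet; RE is the retained energy measured (or simulated) for the group
whose requirement is being predicted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maintenance import MaintenanceFit

__all__ = ["NetEnergyModel", "PredictionTable"]


@dataclass(frozen=True)
class NetEnergyModel:
    """NE = a·W^0.75 + RE with provenance of the coefficient ``a``.

    ``k`` (the efficiency the same fit produced) is carried along for
    provenance and reporting; it does not enter the prediction.
    """

    a: float
    k: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("maintenance coefficient a must be positive")
        if not 0 < self.k < 1:
            raise ValueError("efficiency k must lie in (0, 1)")

    @classmethod
    def from_fit(cls, fit: MaintenanceFit, source: str | None = None) -> "NetEnergyModel":
        return cls(a=fit.nem_coef, k=fit.k, source=source or f"{fit.method} fit ({fit.diet_id or 'unnamed'})")

    @classmethod
    def from_config(cls, path: str | Path) -> "NetEnergyModel":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(a=float(cfg["a"]), k=float(cfg["k"]), source=str(cfg.get("source", "")))

    def to_config(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump({"a": float(self.a), "k": float(self.k), "source": self.source})
        )

    def predict_nem(self, w_meta):
        """Maintenance requirement a·W^0.75, kcal/day."""
        w = np.asarray(w_meta, dtype=float)
        if np.any(w <= 0):
            raise ValueError("metabolic weight must be positive")
        out = self.a * w
        return float(out) if out.ndim == 0 else out

    def predict_ne(self, w_meta, re):
        """Net-energy requirement a·W^0.75 + RE, kcal/day."""
        out = self.predict_nem(w_meta) + np.asarray(re, dtype=float)
        return float(out) if np.ndim(out) == 0 else out

    def prediction_table(self, rows: pd.DataFrame) -> "PredictionTable":
        """Predict for each row of a frame with columns diet_id, w_meta, re[, ne_obs]."""
        if len(rows) == 0:
            raise ValueError("prediction_table requires at least one row")
        w = rows["w_meta"].to_numpy(dtype=float)
        re = rows["re"].to_numpy(dtype=float)
        nem = self.predict_nem(w)
        ne = nem + re
        frame = pd.DataFrame(
            {
                "diet_id": rows["diet_id"].to_numpy(),
                "w_meta_kg075": w,
                "nem_pred_kcal_day": nem,
                "re_kcal_day": re,
                "ne_pred_kcal_day": ne,
            }
        )
        if "ne_obs" in rows.columns:
            frame["ne_obs_kcal_day"] = rows["ne_obs"].to_numpy(dtype=float)
        return PredictionTable(model=self, frame=frame)


@dataclass
class PredictionTable:
    """Per-group predictions plus the mean ± sample-sd summary block."""

    model: NetEnergyModel
    frame: pd.DataFrame

    @property
    def mean_pred(self) -> float:
        return float(self.frame["ne_pred_kcal_day"].mean())

    @property
    def sd_pred(self) -> float:
        # sample sd (n-1); undefined for a single row
        return float(self.frame["ne_pred_kcal_day"].std(ddof=1)) if len(self.frame) > 1 else math.nan

    @property
    def mean_obs(self) -> float:
        if "ne_obs_kcal_day" not in self.frame:
            return math.nan
        return float(self.frame["ne_obs_kcal_day"].mean())

    @property
    def sd_obs(self) -> float:
        if "ne_obs_kcal_day" not in self.frame or len(self.frame) < 2:
            return math.nan
        return float(self.frame["ne_obs_kcal_day"].std(ddof=1))

    def summary(self) -> str:
        lines = [
            f"NE = {self.model.a:.2f}·W^0.75 + RE   (k = {self.model.k:.2f}"
            + (f", from {self.model.source})" if self.model.source else ")"),
            f"  n groups       : {len(self.frame)}",
            f"  predicted NE   : {self.mean_pred:.2f} ± {self.sd_pred:.2f} kcal/day",
        ]
        if not math.isnan(self.mean_obs):
            lines.append(f"  observed  NE   : {self.mean_obs:.2f} ± {self.sd_obs:.2f} kcal/day")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()
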