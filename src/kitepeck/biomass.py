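"""Biomass estimation for prey deliveries.

Each delivered prey item contributes an estimated mass in grams: the
observer's visual estimate when one was recorded, otherwise a per-category
mean whole-item mass scaled by the delivered fraction (whole, half, quarter).
Daily delivered biomass is the sum over a brood-day's deliveries.

Category mean masses are a required configuration input (``weights.yaml``):
the field data behind them (prey weighed at nest controls) are not part of
this package, so no default masses are shipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import VALID_CATEGORIES
from .errors import ConfigError

_CLASSIFIED = tuple(c for c in VALID_CATEGORIES if c != "unclassified")


@dataclass(frozen=True)
class CategoryWeightTable:
    """Mean whole-item mass in grams per prey category.

    ``unclassified`` may be omitted from the input mapping, in which case it
    defaults to the unweighted mean of the classified categories.
    """

    weights: dict

    def __post_init__(self):
        w = dict(self.weights)
        missing = [c for c in _CLASSIFIED if c not in w]
        if missing:
            raise ConfigError(f"weight table missing categories: {missing}")
        if "unclassified" not in w:
            w["unclassified"] = float(np.mean([w[c] for c in _CLASSIFIED]))
        bad = [c for c, v in w.items() if not v > 0]
        if bad:
            raise ConfigError(f"weight table has non-positive masses: {bad}")
        object.__setattr__(self, "weights", w)

    def __getitem__(self, category: str) -> float:
        try:
            return float(self.weights[category])
        except KeyError:
            raise ConfigError(f"category {category!r} missing from weight table")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CategoryWeightTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: float(v) for k, v in self.weights.items()}, fh, sort_keys=True
            )


def estimate_delivery_mass(
    category: str,
    fraction: float,
    observer_mass_g: float | None,
    weights: CategoryWeightTable,
) -> float:
    """Grams for one delivery: observer estimate first, else category mean x fraction."""
    if observer_mass_g is not None and not (
        isinstance(observer_mass_g, float) and np.isnan(observer_mass_g)
    ):
        return float(observer_mass_g)
    return weights[category] * float(fraction)


def daily_biomass_table(
    deliveries: pd.DataFrame, weights: CategoryWeightTable
) -> pd.DataFrame:
    """Summed estimated grams per brood-day with >= 1 delivery.

    Returns columns ``brood_id, date, biomass_g``; brood-days with no
    deliveries are simply absent (callers fill 0).
    """
    if deliveries.empty:
        return pd.DataFrame(columns=["brood_id", "date", "biomass_g"])
    df = deliveries.copy()
    cat_mass = df["category"].map(weights.weights).astype(float)
    df["est_g"] = np.where(
        df["observer_mass_g"].notna(),
        df["observer_mass_g"].astype(float),
        cat_mass * df["fraction"].astype(float),
    )
    out = (
        df.groupby(["brood_id", "date"], as_index=False)["est_g"]
        .sum()
        .rename(columns={"est_g": "biomass_g"})
    )
    return out


def daily_biomass(
    deliveries: pd.DataFrame,
    brood_id: str,
    date,
    weights: CategoryWeightTable,
) -> float:
    """Grams delivered to one brood on one date (0 when none recorded)."""
    sel = deliveries[
        (deliveries["brood_id"] == brood_id) & (deliveries["date"] == date)
    ]
    total = 0.0
    for _, row in sel.iterrows():
        total += estimate_delivery_mass(
            row["category"], row["fraction"], row["observer_mass_g"], weights
        )
    return total
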