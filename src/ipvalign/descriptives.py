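"""Descriptive screening: missingness, weighted prevalence, any-item prevalence.

Prevalence is the weighted mean of a binary response over non-missing rows,
with a linearization standard error for the ratio estimator
``p = sum(w y) / sum(w)``:  ``se^2 = sum(w_i^2 (y_i - p)^2) / (sum w)^2``.

"Any-item" prevalence follows standard composite-indicator construction for
partially missing rows: a row counts as positive if any observed item is 1,
negative only if all listed items are observed and 0, and is excluded
otherwise (so partial missingness cannot bias the indicator downward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_survey import ItemResponseTable


@dataclass
class PrevalenceTable:
    """Per-group weighted item prevalences, any-item prevalence, missingness."""

    item_prevalence: pd.DataFrame  # rows: group; columns: items (weighted share)
    item_se: pd.DataFrame
    any_prevalence: pd.DataFrame  # columns: estimate, se; index: group
    missingness: pd.DataFrame  # rows: group + "overall"; columns: items
    item_set: str = "custom"

    @property
    def range_across_groups(self) -> pd.DataFrame:
        """Min/max of each item's prevalence (and 'any') across groups."""
        combined = self.item_prevalence.copy()
        combined["any"] = self.any_prevalence["estimate"]
        return pd.DataFrame({"min": combined.min(axis=0), "max": combined.max(axis=0)}).T


def _weighted_mean_se(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    p = float(np.sum(w * y) / sw)
    se = float(np.sqrt(np.sum(w**2 * (y - p) ** 2)) / sw)
    return p, se


def item_missingness(table: ItemResponseTable) -> pd.DataFrame:
    """Fraction of missing responses per item, by group and overall."""
    if table.data.empty:
        raise ValueError("empty table")
    rows = {}
    for g in table.groups:
        rows[g] = np.isnan(table.responses(g)).mean(axis=0)
    rows["overall"] = np.isnan(table.responses()).mean(axis=0)
    return pd.DataFrame(rows, index=table.items).T


def weighted_prevalence(table: ItemResponseTable, item: str) -> pd.DataFrame:
    """Per-group weighted endorsement share with linearization SE.

    Groups in which the item is entirely missing are flagged (``NaN`` estimate
    and ``all_missing=True``) rather than silently dropped.
    """
    if item not in table.items:
        raise KeyError(f"unknown item {item!r}")
    records = []
    for g in table.groups:
        sub = table.group_data(g)
        y = sub[item].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        if not obs.any():
            records.append({"group": g, "estimate": np.nan, "se": np.nan, "all_missing": True})
            continue
        p, se = _weighted_mean_se(y[obs], w[obs])
        records.append({"group": g, "estimate": p, "se": se, "all_missing": False})
    return pd.DataFrame(records).set_index("group")


def any_prevalence(table: ItemResponseTable, items: list[str] | None = None) -> pd.DataFrame:
    """Per-group weighted prevalence of endorsing at least one listed item."""
    items = list(table.items) if items is None else list(items)
    if not items:
        raise ValueError("empty item list")
    unknown = [i for i in items if i not in table.items]
    if unknown:
        raise KeyError(f"unknown items {unknown}")
    records = []
    for g in table.groups:
        sub = table.group_data(g)
        y = sub[items].to_numpy(dtype=float)
        w = sub["weight"].to_numpy(dtype=float)
        any_pos = np.nansum(y == 1.0, axis=1) > 0
        all_obs_neg = (~np.isnan(y)).all(axis=1) & ~any_pos
        keep = any_pos | all_obs_neg
        if not keep.any():
            records.append({"group": g, "estimate": np.nan, "se": np.nan, "all_missing": True})
            continue
        p, se = _weighted_mean_se(any_pos[keep].astype(float), w[keep])
        records.append({"group": g, "estimate": p, "se": se, "all_missing": False})
    return pd.DataFrame(records).set_index("group")


def describe(table: ItemResponseTable) -> PrevalenceTable:
    """Full descriptive screen: item and any-item prevalence plus missingness."""
    per_item = {i: weighted_prevalence(table, i) for i in table.items}
    prev = pd.DataFrame({i: d["estimate"] for i, d in per_item.items()})
    se = pd.DataFrame({i: d["se"] for i, d in per_item.items()})
    return PrevalenceTable(
        item_prevalence=prev,
        item_se=se,
        any_prevalence=any_prevalence(table),
        missingness=item_missingness(table),
        item_set=table.item_set,
    )
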