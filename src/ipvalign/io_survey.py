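"""Tabular I/O, validation and pipeline configuration.

Respondent-level data travel as :class:`ItemResponseTable`: one row per
respondent with a group label, a positive sampling weight and binary
(0/1/missing) responses to a named item set.  Files are plain CSV with a
mandatory header; missing responses are empty cells or the token ``NA``.
"""

from __future__ import annotations

import dataclasses
import json
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

#: Standard item sets of the domestic-violence survey module this package
#: emulates: seven lifetime physical-violence acts and five controlling
#: behaviours.  Short names keyed by what each item asks about.
ITEM_SETS: dict[str, list[str]] = {
    "physical_ipv": ["push", "slap", "punch", "kick", "choke", "weapon", "twist"],
    "controlling": ["jealous", "accuse", "friends", "family", "whereabouts"],
}

_MISSING_TOKENS = ["", "NA"]


class SchemaError(ValueError):
    """Input file does not have the expected columns."""


class ValidationError(ValueError):
    """Input values violate the response-table contract."""


class ConfigError(ValueError):
    """Configuration value outside its valid range."""


@dataclass
class ItemResponseTable:
    """Respondents x items binary matrix with group labels and weights.

    Parameters
    ----------
    data:
        DataFrame with columns ``group``, ``weight`` and one column per item.
        Responses are floats in {0.0, 1.0, NaN}.
    items:
        Item column names, in declared order.
    item_set:
        Label of the item set (``physical_ipv``, ``controlling`` or custom).
    """

    data: pd.DataFrame
    items: list[str]
    item_set: str = "custom"

    def __post_init__(self) -> None:
        missing_cols = [c for c in ["group", *self.items] if c not in self.data.columns]
        if missing_cols:
            raise SchemaError(f"missing required columns: {missing_cols}")
        if "weight" not in self.data.columns:
            self.data = self.data.copy()
            self.data["weight"] = 1.0
        w = self.data["weight"].to_numpy(dtype=float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            bad = np.flatnonzero(~(np.isfinite(w) & (w > 0)))
            raise ValidationError(f"non-positive or missing weights at rows {bad[:10].tolist()}")
        resp = self.data[self.items].to_numpy(dtype=float)
        ok = np.isnan(resp) | (resp == 0.0) | (resp == 1.0)
        if not ok.all():
            rows, cols = np.nonzero(~ok)
            detail = [
                (int(r), self.items[c], resp[r, c]) for r, c in zip(rows[:10], cols[:10])
            ]
            raise ValidationError(
                f"responses must be 0, 1 or missing; offending (row, item, value): {detail}"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def groups(self) -> list[str]:
        """Distinct group labels, sorted."""
        return sorted(self.data["group"].astype(str).unique())

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_data(self, group: str) -> pd.DataFrame:
        sub = self.data[self.data["group"].astype(str) == str(group)]
        if sub.empty:
            raise KeyError(f"unknown group {group!r}")
        return sub

    def responses(self, group: str | None = None) -> np.ndarray:
        """(n, J) float response matrix (NaN = missing)."""
        df = self.data if group is None else self.group_data(group)
        return df[self.items].to_numpy(dtype=float)

    def weights(self, group: str | None = None) -> np.ndarray:
        df = self.data if group is None else self.group_data(group)
        return df["weight"].to_numpy(dtype=float)

    def subset_groups(self, groups: Sequence[str]) -> "ItemResponseTable":
        keep = self.data["group"].astype(str).isin([str(g) for g in groups])
        return ItemResponseTable(
            self.data[keep].reset_index(drop=True).copy(), list(self.items), self.item_set
        )

    def require_multigroup(self) -> None:
        if self.n_groups < 2:
            raise ValidationError("at least 2 distinct groups required for multi-group analysis")


def _resolve_items(item_set: str | Sequence[str]) -> tuple[list[str], str]:
    if isinstance(item_set, str):
        if item_set not in ITEM_SETS:
            raise SchemaError(
                f"unknown item set {item_set!r}; known: {sorted(ITEM_SETS)} "
                "(or pass an explicit list of item names)"
            )
        return list(ITEM_SETS[item_set]), item_set
    return list(item_set), "custom"


def read_response_table(path: str | Path, item_set: str | Sequence[str]) -> ItemResponseTable:
    """Read a respondent-level CSV into a validated :class:`ItemResponseTable`.

    Missing responses must be empty cells or ``NA``; any other non-0/1 value
    raises :class:`ValidationError` listing offending rows.
    """
    items, label = _resolve_items(item_set)
    df = pd.read_csv(path, na_values=_MISSING_TOKENS, keep_default_na=False)
    return ItemResponseTable(df, items, label)


def write_table(table: ItemResponseTable, path: str | Path) -> None:
    """Write a response table to CSV (round-trips losslessly with read)."""
    cols = ["group", "weight", *table.items]
    out = table.data[cols].copy()
    out.to_csv(path, index=False, na_rep="NA")


# -- pipeline configuration ----------------------------------------------------


@dataclass
class PipelineConfig:
    """Thresholds, estimator settings and seed for the full workflow.

    Defaults encode the adequacy benchmarks used throughout: minimum
    standardized loading 0.35, RMSEA at most 0.08, CFI and TLI at least 0.95,
    and at most 25% non-invariant parameters for a trustworthy alignment.
    """

    min_loading: float = 0.35
    max_rmsea: float = 0.08
    min_cfi: float = 0.95
    min_tli: float = 0.95
    max_noninvariant_fraction: float = 0.25
    link: str = "probit"
    quadrature_points: int = 21
    alignment_epsilon: float = 0.01
    flag_alpha: float = 0.01
    ladder_alpha: float = 0.05
    ci_level: float = 0.999
    align_starts: int = 10
    mc_replications: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "max_noninvariant_fraction": self.max_noninvariant_fraction,
            "max_rmsea": self.max_rmsea,
            "min_cfi": self.min_cfi,
            "min_tli": self.min_tli,
            "flag_alpha": self.flag_alpha,
            "ladder_alpha": self.ladder_alpha,
            "ci_level": self.ci_level,
        }
        for name, val in fractions.items():
            if not (isinstance(val, numbers.Real) and 0.0 <= float(val) <= 1.0):
                raise ConfigError(f"{name}={val!r} outside [0, 1]")
        if not 0.0 < self.min_loading < 1.0:
            raise ConfigError(f"min_loading={self.min_loading!r} outside (0, 1)")
        if self.link not in ("probit", "logit"):
            raise ConfigError(f"link must be 'probit' or 'logit', got {self.link!r}")
        if int(self.quadrature_points) < 3:
            raise ConfigError("quadrature_points must be >= 3")
        if self.alignment_epsilon <= 0:
            raise ConfigError("alignment_epsilon must be > 0")
        if int(self.align_starts) < 1 or int(self.mc_replications) < 0:
            raise ConfigError("align_starts >= 1 and mc_replications >= 0 required")


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML key/value config; unspecified keys keep their defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


# -- report serialization ------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if isinstance(obj, set)] if isinstance(
            obj, set
        ) else [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split", index=False))
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def write_report(results: Any, path: str | Path) -> None:
    """Serialize any stage output to a structured JSON document.

    DataFrames and dataclasses serialize recursively; non-finite floats map to
    null.  Tabular stage outputs additionally expose their own ``to_csv``.
    """
    payload = _jsonable(results)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
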