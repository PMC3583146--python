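"""Per-column generalization (recoding) of quasi-identifier values.

Generalization coarsens a quasi-identifier — a date of birth to a year of
birth, a six-character postal code to its three-character prefix, an exact
age to a ten-year band — which merges equivalence classes and thereby lowers
uniqueness.  Three rule kinds are supported:

* :class:`DatePrecisionRule` — reduce a date to day/month/year/decade
  precision.  Dates are parsed as ISO-8601 by default; a ``strptime`` format
  string may be supplied for other layouts.
* :class:`PrefixRule` — truncate a string to its first *k* characters.
* :class:`NumericBinRule` — bin a numeric value into half-open intervals of a
  given width and origin.

Each rule applies independently per column.  Generalization never increases
the number of equivalence classes and never shrinks a class: a generalized
class is the union of the classes it merges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, date
from math import floor
from typing import Optional, Sequence, Tuple

from .exceptions import ConfigurationError, GeneralizationError, ParameterError
from .frequency import MicrodataTable

__all__ = [
    "DatePrecisionRule",
    "PrefixRule",
    "NumericBinRule",
    "generalize",
    "rule_from_config",
]

_DATE_PRECISIONS = ("day", "month", "year", "decade")
_ERROR_POLICIES = ("fail", "pass")


@dataclass(frozen=True)
class DatePrecisionRule:
    """Reduce date precision: day -> month -> year -> decade.

    ``decade`` is the floored decade of the year, e.g. 1962 -> "1960".
    ``on_error='pass'`` leaves unparseable values verbatim instead of raising.
    """

    precision: str
    fmt: Optional[str] = None
    on_error: str = "fail"

    def __post_init__(self):
        if self.precision not in _DATE_PRECISIONS:
            raise ConfigurationError(
                f"date precision must be one of {_DATE_PRECISIONS}, got {self.precision!r}"
            )
        if self.on_error not in _ERROR_POLICIES:
            raise ConfigurationError(f"on_error must be one of {_ERROR_POLICIES}")

    def _parse(self, value: str) -> date:
        if self.fmt is not None:
            return datetime.strptime(value, self.fmt).date()
        return date.fromisoformat(value)

    def apply(self, value) -> str:
        raw = str(value)
        try:
            d = self._parse(raw)
        except (ValueError, TypeError):
            if self.on_error == "pass":
                return raw
            raise GeneralizationError(f"cannot parse date value {raw!r}") from None
        if self.precision == "day":
            return d.isoformat()
        if self.precision == "month":
            return f"{d.year:04d}-{d.month:02d}"
        if self.precision == "year":
            return f"{d.year:04d}"
        return f"{(d.year // 10) * 10:04d}"  # decade


@dataclass(frozen=True)
class PrefixRule:
    """Keep the first ``length`` characters of a string value."""

    length: int

    def __post_init__(self):
        if self.length < 0:
            raise ConfigurationError("prefix length must be >= 0")

    def apply(self, value) -> str:
        return str(value)[: self.length]


@dataclass(frozen=True)
class NumericBinRule:
    """Bin a numeric value into half-open intervals ``[origin + k*width, ...)``."""

    width: float
    origin: float = 0.0
    on_error: str = "fail"

    def __post_init__(self):
        if self.width <= 0:
            raise ParameterError("bin width must be positive")
        if self.on_error not in _ERROR_POLICIES:
            raise ConfigurationError(f"on_error must be one of {_ERROR_POLICIES}")

    def apply(self, value) -> str:
        raw = str(value)
        try:
            v = float(raw)
        except ValueError:
            if self.on_error == "pass":
                return raw
            raise GeneralizationError(f"cannot parse numeric value {raw!r}") from None
        lo = self.origin + self.width * floor((v - self.origin) / self.width)
        return f"[{lo:g},{lo + self.width:g})"


def generalize(table: MicrodataTable, rules: Sequence[Tuple[str, object]]) -> MicrodataTable:
    """Apply ``(column, rule)`` pairs to a table; record count and column order unchanged.

    Multiple rules naming the same column are applied in order.
    """
    for column, rule in rules:
        table.column_index(column)  # validates
        if not hasattr(rule, "apply"):
            raise ConfigurationError(f"rule for {column!r} has no apply() method")
    if not rules:
        return table
    records = [list(r) for r in table.records]
    for column, rule in rules:
        i = table.column_index(column)
        for rec in records:
            rec[i] = rule.apply(rec[i])
    return MicrodataTable(table.qi_names, [tuple(r) for r in records])


def rule_from_config(cfg: dict):
    """Build a rule from a config mapping (keys: column, kind, kind-specific params)."""
    kind = cfg.get("kind")
    if kind == "date":
        return DatePrecisionRule(
            precision=cfg.get("precision", "year"),
            fmt=cfg.get("format"),
            on_error=cfg.get("on_error", "fail"),
        )
    if kind == "prefix":
        if "length" not in cfg:
            raise ConfigurationError("prefix rule requires a 'length' key")
        return PrefixRule(length=int(cfg["length"]))
    if kind == "bin":
        if "width" not in cfg:
            raise ConfigurationError("bin rule requires a 'width' key")
        return NumericBinRule(
            width=float(cfg["width"]),
            origin=float(cfg.get("origin", 0.0)),
            on_error=cfg.get("on_error", "fail"),
        )
    raise ConfigurationError(f"unknown generalization kind {kind!r}")
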