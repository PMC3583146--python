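"""Equivalence classes, frequency spectra and exact uniqueness metrics.

A *quasi-identifier* is a variable an adversary could plausibly know from a
public or semi-public registry (age, sex, postal code, dates) and use to match
records.  All records sharing identical values on the quasi-identifiers form
an *equivalence class*; a record is *unique* when its class has size one.

Three exact metrics are defined when both the disclosed sample and the
population file (e.g. a voter registration list) are available:

* ``lambda1`` — P(population unique | sample unique): among sample-unique
  records, the fraction whose equivalence class is also unique in the
  population.
* ``lambda2`` — the fraction of *all* sample records that are unique in both
  files; this is the share of the disclosed data set actually at risk of a
  certain match.
* ``lambda3`` — the fraction of population records that are population-unique;
  the quantity the sample-based estimators in :mod:`uniqrisk.estimators`
  target.

Values are opaque atoms: comparison is exact string equality after parsing
and optional generalization.  No fuzzy matching is performed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ContainmentError, InputError, ParameterError

__all__ = [
    "MicrodataTable",
    "EquivalenceClassTable",
    "FrequencySpectrum",
    "RiskMetrics",
    "build_equivalence_classes",
    "spectrum",
    "lambda1",
    "lambda2",
    "lambda3",
    "srswor_sample",
]


class MicrodataTable:
    """Raw records restricted to quasi-identifier columns.

    Parameters
    ----------
    qi_names
        Ordered column identifiers.
    records
        Sequence of value tuples, one value per quasi-identifier.  Values are
        treated as opaque atoms (typically strings after CSV parsing).
    """

    __slots__ = ("qi_names", "records")

    def __init__(self, qi_names: Sequence[str], records: Iterable[Sequence]):
        names = tuple(str(c) for c in qi_names)
        if not names:
            raise ConfigurationError("at least one quasi-identifier is required")
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate quasi-identifier names")
        recs = []
        for i, r in enumerate(records):
            t = tuple(r)
            if len(t) != len(names):
                raise InputError(
                    f"record {i} has {len(t)} values, expected {len(names)}"
                )
            recs.append(t)
        self.qi_names = names
        self.records = tuple(recs)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MicrodataTable)
            and self.qi_names == other.qi_names
            and self.records == other.records
        )

    def __repr__(self) -> str:
        return f"MicrodataTable(qi_names={self.qi_names}, n={len(self)})"

    def column_index(self, name: str) -> int:
        try:
            return self.qi_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"unknown quasi-identifier {name!r}; available: {list(self.qi_names)}"
            ) from None

    def project(self, qi_subset: Sequence[str]) -> "MicrodataTable":
        """Restrict to a subset of the quasi-identifiers (order given by caller)."""
        if not qi_subset:
            raise ConfigurationError("qi_subset must be non-empty")
        idx = [self.column_index(c) for c in qi_subset]
        return MicrodataTable(qi_subset, [tuple(r[i] for i in idx) for r in self.records])

    # -- interchange -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, quasi_identifiers: Optional[Sequence[str]] = None) -> "MicrodataTable":
        cols = list(quasi_identifiers) if quasi_identifiers is not None else list(df.columns)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ConfigurationError(f"columns not in data: {missing}")
        if len(df) == 0:
            raise InputError("table has no records")
        sub = df[cols].astype(str)
        return cls(cols, (tuple(row) for row in sub.itertuples(index=False, name=None)))

    @classmethod
    def read_csv(cls, path, quasi_identifiers: Optional[Sequence[str]] = None) -> "MicrodataTable":
        """Read an RFC-4180 CSV (header row required); every cell kept as a string."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_dataframe(df, quasi_identifiers)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.records), columns=list(self.qi_names))

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class EquivalenceClassTable:
    """Map from quasi-identifier value combination to its count.

    The count of class *i* is ``f_i`` when the table describes a sample and
    ``F_i`` when it describes a population; ``total`` is ``n`` (or ``N``) and
    ``num_classes`` is ``u`` (or ``K``).
    """

    __slots__ = ("classes",)

    def __init__(self, classes: Mapping):
        cleaned = {}
        for key, count in classes.items():
            c = int(count)
            if c < 1 or c != count:
                raise InputError(f"class {key!r} has invalid count {count!r}")
            cleaned[key] = c
        if not cleaned:
            raise InputError("equivalence-class table has no classes")
        self.classes = cleaned

    @property
    def total(self) -> int:
        return sum(self.classes.values())

    @property
    def num_classes(self) -> int:
        return len(self.classes)

    def class_sizes(self) -> list:
        return list(self.classes.values())

    def num_uniques(self) -> int:
        return sum(1 for c in self.classes.values() if c == 1)

    def __repr__(self) -> str:
        return f"EquivalenceClassTable(total={self.total}, num_classes={self.num_classes})"


@dataclass(frozen=True)
class FrequencySpectrum:
    """Frequency-of-frequencies: number of equivalence classes of each size.

    Sufficient statistic for every estimator in :mod:`uniqrisk.estimators`:
    permuting records or relabelling classes never changes it.
    """

    counts_by_size: Mapping[int, int]
    total: int
    num_classes: int

    def __post_init__(self):
        cbs = {int(j): int(c) for j, c in self.counts_by_size.items()}
        if not cbs or any(j < 1 or c < 1 for j, c in cbs.items()):
            raise InputError("spectrum entries must be positive")
        if sum(j * c for j, c in cbs.items()) != self.total:
            raise InputError("spectrum total does not match sum of j*count(j)")
        if sum(cbs.values()) != self.num_classes:
            raise InputError("spectrum num_classes does not match sum of counts")
        object.__setattr__(self, "counts_by_size", cbs)

    @classmethod
    def from_class_sizes(cls, sizes: Iterable[int]) -> "FrequencySpectrum":
        c = Counter(int(s) for s in sizes)
        return cls(dict(c), sum(j * k for j, k in c.items()), sum(c.values()))

    @property
    def num_singletons(self) -> int:
        """Number of size-1 classes (u1)."""
        return self.counts_by_size.get(1, 0)

    def sizes_and_counts(self) -> tuple[np.ndarray, np.ndarray]:
        js = np.array(sorted(self.counts_by_size), dtype=np.int64)
        cs = np.array([self.counts_by_size[int(j)] for j in js], dtype=np.int64)
        return js, cs


@dataclass(frozen=True)
class RiskMetrics:
    """Exact uniqueness metrics; ``lambda1`` is ``None`` when the sample has no uniques."""

    lambda1: Optional[float]
    lambda2: float
    lambda3: float

    def __post_init__(self):
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise InputError(f"{name}={v} outside [0, 1]")
        if self.lambda1 is not None and self.lambda2 > self.lambda1 + 1e-12:
            raise InputError("lambda2 cannot exceed lambda1")


def build_equivalence_classes(table: MicrodataTable, qi_subset: Optional[Sequence[str]] = None) -> EquivalenceClassTable:
    """Group records by their projected quasi-identifier values.

    ``qi_subset`` defaults to all columns of the table.
    """
    if len(table) == 0:
        raise InputError("table has no records")
    t = table if qi_subset is None or tuple(qi_subset) == table.qi_names else table.project(qi_subset)
    return EquivalenceClassTable(Counter(t.records))


def spectrum(ect: EquivalenceClassTable) -> FrequencySpectrum:
    """Frequency-of-frequencies of an equivalence-class table."""
    return FrequencySpectrum.from_class_sizes(ect.class_sizes())


def _check_containment(pop: EquivalenceClassTable, sample: EquivalenceClassTable) -> None:
    for key, f in sample.classes.items():
        F = pop.classes.get(key)
        if F is None:
            raise ContainmentError(f"sample class {key!r} absent from population")
        if f > F:
            raise ContainmentError(
                f"sample class {key!r} has count {f} > population count {F}"
            )


def lambda1(pop: EquivalenceClassTable, sample: EquivalenceClassTable) -> Optional[float]:
    """P(population unique | sample unique); ``None`` when the sample has no uniques."""
    _check_containment(pop, sample)
    u1 = 0
    both = 0
    for key, f in sample.classes.items():
        if f == 1:
            u1 += 1
            if pop.classes[key] == 1:
                both += 1
    if u1 == 0:
        return None
    return both / u1


def lambda2(pop: EquivalenceClassTable, sample: EquivalenceClassTable) -> float:
    """Fraction of all sample records unique in both the sample and the population."""
    _check_containment(pop, sample)
    both = sum(
        1 for key, f in sample.classes.items() if f == 1 and pop.classes[key] == 1
    )
    return both / sample.total


def lambda3(pop: EquivalenceClassTable) -> float:
    """Fraction of population records that are population-unique."""
    return pop.num_uniques() / pop.total


def risk_metrics(pop: EquivalenceClassTable, sample: EquivalenceClassTable) -> RiskMetrics:
    """All three exact metrics for a (population, contained sample) pair."""
    return RiskMetrics(lambda1(pop, sample), lambda2(pop, sample), lambda3(pop))


def sample_size_for_fraction(fraction: float, population_size: int) -> int:
    """Sample size implied by a sampling fraction: round(pi*N) to nearest, minimum 1."""
    if not (0.0 < fraction <= 1.0):
        raise ParameterError(f"sampling fraction must be in (0, 1], got {fraction}")
    if population_size < 1:
        raise InputError("population must have at least one record")
    m = int(math.floor(fraction * population_size + 0.5))
    return max(1, min(m, population_size))


def srswor_sample(pop: MicrodataTable, fraction: float, seed: int) -> MicrodataTable:
    """Simple random sample of records without replacement, order-preserving.

    The sample size is ``round(fraction * N)`` (minimum 1).  Identical
    ``(pop, fraction, seed)`` always yields the identical sample.
    """
    n = sample_size_for_fraction(fraction, len(pop))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pop), size=n, replace=False))
    return MicrodataTable(pop.qi_names, [pop.records[i] for i in idx])
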