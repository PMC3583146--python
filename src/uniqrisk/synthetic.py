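"""Seeded synthetic populations with controllable uniqueness.

The evaluation and the estimator oracles need populations whose true
uniqueness (lambda3) is known exactly.  Three generators are provided:

* :func:`generate_crp_population` — class sizes drawn from the two-parameter
  Chinese restaurant process, the partition law matching the Pitman model;
  this is the oracle substrate for the Pitman estimator.
* :func:`generate_snb_population` — class sizes drawn i.i.d. from the slide
  negative binomial law; the self-consistency substrate for the SNB
  estimator.
* :func:`generate_qi_population` — demographic-like microdata with
  independent quasi-identifier columns (categorical levels, integer ranges,
  day-resolution date windows), so that generalization ladders can steer the
  realized uniqueness into low (<10%), medium (10–50%) or high (>50%) tiers.

Ground truth is always the *realized* population's lambda3, computed exactly
from the generated class sizes — never the superpopulation expectation.
Every generator is deterministic given its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, ParameterError
from .frequency import EquivalenceClassTable, MicrodataTable, build_equivalence_classes, lambda3
from .generalization import DatePrecisionRule, PrefixRule, generalize
from .simulation import classify_uniqueness_tier

__all__ = [
    "crp_class_sizes",
    "generate_crp_population",
    "generate_snb_population",
    "CategoricalColumn",
    "IntUniformColumn",
    "DateUniformColumn",
    "generate_qi_population",
    "TierSearchResult",
    "tune_to_tier",
    "make_tiered_populations",
    "DEFAULT_TIER_LADDER",
]


# ---------------------------------------------------------------------------
# Chinese restaurant process
# ---------------------------------------------------------------------------

def crp_class_sizes(N: int, alpha: float, theta: float, seed: int) -> List[int]:
    """Class-size multiset of a two-parameter CRP seating of N customers.

    Customer n+1 joins an existing class of size s with probability
    (s - alpha)/(n + theta) and opens a new class with probability
    (theta + K*alpha)/(n + theta).  The existing-class choice is drawn in
    O(1) amortized time by proposing a uniformly random earlier customer's
    class and accepting with probability (s - alpha)/s.
    """
    if N < 1:
        raise ParameterError("N must be >= 1")
    if not (0.0 <= alpha < 1.0):
        raise ParameterError(f"need 0 <= alpha < 1, got {alpha}")
    if alpha == 0.0:
        if theta < 0.0:
            raise ParameterError("need theta >= 0 when alpha = 0")
    elif theta <= -alpha:
        raise ParameterError(f"need theta > -alpha, got theta={theta}, alpha={alpha}")

    rnd = random.Random(seed)
    rand = rnd.random
    table_of = [0] * N
    sizes = [1]
    for i in range(1, N):
        K = len(sizes)
        if rand() * (i + theta) < theta + K * alpha:
            table_of[i] = K
            sizes.append(1)
        else:
            while True:
                t = table_of[int(rand() * i)]
                s = sizes[t]
                if alpha == 0.0 or rand() * s < s - alpha:
                    break
            sizes[t] = s + 1
            table_of[i] = t
    return sizes


def generate_crp_population(N: int, alpha: float, theta: float, seed: int) -> EquivalenceClassTable:
    """A population equivalence-class table with CRP(alpha, theta) class sizes."""
    sizes = crp_class_sizes(N, alpha, theta, seed)
    return EquivalenceClassTable({f"class{i}": s for i, s in enumerate(sizes)})


# ---------------------------------------------------------------------------
# Slide negative binomial populations
# ---------------------------------------------------------------------------

def generate_snb_population(num_classes: int, k: float, p: float, seed: int) -> EquivalenceClassTable:
    """Population with ``num_classes`` i.i.d. slide-negative-binomial class sizes.

    F = 1 + NegBin(k, p); P(F=1) = p^k is the expected uniqueness share of
    classes (not of records).
    """
    if num_classes < 1:
        raise ParameterError("num_classes must be >= 1")
    if k <= 0 or not (0.0 < p < 1.0):
        raise ParameterError("need k > 0 and 0 < p < 1")
    rng = np.random.default_rng(seed)
    sizes = 1 + stats.nbinom.rvs(k, p, size=num_classes, random_state=rng)
    return EquivalenceClassTable({f"class{i}": int(s) for i, s in enumerate(sizes)})


# ---------------------------------------------------------------------------
# Quasi-identifier tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoricalColumn:
    """Categorical quasi-identifier with optional level probabilities."""

    name: str
    levels: Tuple[str, ...]
    probs: Optional[Tuple[float, ...]] = None

    def draw(self, N: int, rng: np.random.Generator) -> List[str]:
        if not self.levels:
            raise ConfigurationError(f"column {self.name!r} has no levels")
        p = None if self.probs is None else np.asarray(self.probs) / np.sum(self.probs)
        return list(rng.choice(list(self.levels), size=N, p=p))


@dataclass(frozen=True)
class IntUniformColumn:
    """Integer quasi-identifier uniform on [low, high] (e.g. age in years)."""

    name: str
    low: int
    high: int

    def draw(self, N: int, rng: np.random.Generator) -> List[str]:
        if self.high < self.low:
            raise ConfigurationError(f"column {self.name!r}: high < low")
        return [str(v) for v in rng.integers(self.low, self.high + 1, size=N)]


@dataclass(frozen=True)
class DateUniformColumn:
    """Day-resolution date quasi-identifier uniform on [start, end] (ISO strings)."""

    name: str
    start: str
    end: str

    def draw(self, N: int, rng: np.random.Generator) -> List[str]:
        d0 = date.fromisoformat(self.start)
        d1 = date.fromisoformat(self.end)
        span = (d1 - d0).days
        if span < 0:
            raise ConfigurationError(f"column {self.name!r}: end before start")
        offs = rng.integers(0, span + 1, size=N)
        return [(d0 + timedelta(days=int(o))).isoformat() for o in offs]


def generate_qi_population(columns: Sequence, N: int, seed: int) -> MicrodataTable:
    """N records with independently drawn column values from the given marginals."""
    if not columns:
        raise ConfigurationError("schema must declare at least one column")
    if N < 1:
        raise ParameterError("N must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [c.draw(N, rng) for c in columns]
    names = [c.name for c in columns]
    return MicrodataTable(names, list(zip(*cols)))


# ---------------------------------------------------------------------------
# Tier tuning by generalization ladder
# ---------------------------------------------------------------------------

@dataclass
class TierSearchResult:
    """Outcome of walking a generalization ladder toward a uniqueness tier.

    ``achieved`` is False when no rung reaches the target tier; the closest
    inspection trail is kept in ``trace`` either way.
    """

    target_tier: str
    achieved: bool
    table: Optional[MicrodataTable]
    lambda3: Optional[float]
    rung_index: Optional[int]
    trace: List[Tuple[int, float, str]] = field(default_factory=list)


def tune_to_tier(table: MicrodataTable, tier: str, ladder: Sequence[Sequence[Tuple[str, object]]]) -> TierSearchResult:
    """Walk rule sets from finest to coarsest until the realized lambda3 hits the tier.

    Each rung is an independent rule set applied to the *original* table.
    Returns the first qualifying version; an unreachable tier is reported
    honestly, never raised.
    """
    if tier not in ("low", "medium", "high"):
        raise ConfigurationError(f"unknown tier {tier!r}")
    trace: List[Tuple[int, float, str]] = []
    for i, rules in enumerate(ladder):
        candidate = generalize(table, list(rules))
        l3 = lambda3(build_equivalence_classes(candidate))
        achieved_tier = classify_uniqueness_tier(l3)
        trace.append((i, l3, achieved_tier))
        if achieved_tier == tier:
            return TierSearchResult(tier, True, candidate, l3, i, trace)
    return TierSearchResult(tier, False, None, None, None, trace)


#: Ladder rungs from finest to coarsest for the default demographic schema:
#: day-resolution birth date, then month, then month with region collapsed.
DEFAULT_TIER_LADDER: Tuple[Tuple[Tuple[str, object], ...], ...] = (
    (),
    (("dob", DatePrecisionRule("month")),),
    (("dob", DatePrecisionRule("month")), ("region", PrefixRule(1))),
)


def default_schema() -> List[object]:
    """Demographic-like schema: 25-year day-resolution birth window, sex, region."""
    return [
        DateUniformColumn("dob", "1980-01-01", "2004-12-31"),
        CategoricalColumn("sex", ("M", "F")),
        CategoricalColumn("region", ("R1", "R2", "R3")),
    ]


def make_tiered_populations(
    N: int, seed: int, tiers: Sequence[str] = ("low", "medium", "high")
) -> Dict[str, TierSearchResult]:
    """One synthetic population per requested uniqueness tier.

    Draws a base population from the default schema and walks the default
    generalization ladder per tier.  Tiers a ladder cannot reach are
    reported with ``achieved=False`` rather than fabricated.
    """
    base = generate_qi_population(default_schema(), N, seed)
    return {tier: tune_to_tier(base, tier, DEFAULT_TIER_LADDER) for tier in tiers}
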