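"""Shared fixtures and independent oracles for the test suite."""

from collections import Counter

import pytest
from hypothesis import HealthCheck, settings

from uniqrisk import MicrodataTable

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def brute_force_class_sizes(records):
    """Independent grouping oracle: double loop counting matching records."""
    sizes = []
    seen = [False] * len(records)
    for i, r in enumerate(records):
        if seen[i]:
            continue
        count = 0
        for j, s in enumerate(records):
            if s == r:
                count += 1
                seen[j] = True
        sizes.append(count)
    return sorted(sizes)


def linkage_example_tables():
    """A 14-record disclosed sample and a containing registry.

    The sample has 9 sample-unique records; exactly 2 of them (a man born
    1962, a woman born 1966) are also unique in the registry.  So
    lambda1 = 2/9 and lambda2 = 2/14.
    """
    qi = ("sex", "yob")
    singles = [
        ("M", "1962"), ("F", "1966"), ("M", "1950"), ("F", "1951"),
        ("M", "1952"), ("F", "1953"), ("M", "1954"), ("F", "1955"), ("M", "1956"),
    ]
    sample_records = singles + [("M", "1970")] * 3 + [("F", "1971")] * 2
    pop_records = list(sample_records)
    pop_records += singles[2:]  # duplicate 7 of the 9 uniques in the registry
    pop_records += [("M", "1980")] * 20 + [("F", "1981")] * 6
    return MicrodataTable(qi, pop_records), MicrodataTable(qi, sample_records)


def large_sample_example_tables():
    """A 1000-record sample with exactly two records unique in both files."""
    qi = ("code", "flag")
    pairs = []
    for i in range(499):
        pairs += [(f"P{i}", "x")] * 2
    sample_records = pairs + [("U1", "a"), ("U2", "b")]
    assert len(sample_records) == 1000
    pop_records = sample_records + [("Z", "z")] * 10
    return MicrodataTable(qi, pop_records), MicrodataTable(qi, sample_records)


@pytest.fixture
def linkage_example():
    return linkage_example_tables()


@pytest.fixture
def large_sample_example():
    return large_sample_example_tables()
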