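"""Composite cognitive scores from raw neuropsychological test batteries.

Four cognitive components are modeled: long-term memory (LTM) and
short-term memory (STM) under the memory domain, and semantic retrieval
and manipulation under the executive domain.  Each component's composite
is the mean of the z-normalized scores of its associated tests, computed
per subject; higher scores indicate better performance.  Any raw test
scored in the opposite direction must be negated by the caller before
composite construction.

Missing data are handled by listwise exclusion per component: a subject
lacking any of a component's tests (or imaging) is dropped from that
component's sample, which is why the effective sample size ``n_subjects``
differs across components.  Normalization statistics are computed on the
analyzed subsample itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default test batteries per cognitive component.
DEFAULT_BATTERIES: dict[str, tuple[str, ...]] = {
    "LTM": (
        "cvlt_long_free_recall",
        "cvlt_long_free_vs_list5",
        "cvlt_long_free_vs_short_free",
    ),
    "STM": (
        "cvlt_short_free_recall",
        "cvlt_list_a1",
        "cvlt_total_recall",
    ),
    "SemanticRetrieval": (
        "boston_naming",
        "category_fluency",
    ),
    "Manipulation": (
        "alpha_span",
        "digit_backwards",
    ),
}

DOMAINS = tuple(DEFAULT_BATTERIES)

#: Covariate columns expected in a score table alongside the tests.
COVARIATE_COLUMNS = ("age", "sex", "icv")


@dataclass(frozen=True)
class TestBattery:
    """Ordered set of neuropsychological tests defining one component."""

    domain: str
    tests: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tests", tuple(self.tests))
        if len(self.tests) == 0:
            raise ValueError("battery must contain at least one test")
        if len(set(self.tests)) != len(self.tests):
            raise ValueError("test names must be unique within a battery")

    @classmethod
    def default(cls, domain: str) -> "TestBattery":
        if domain not in DEFAULT_BATTERIES:
            raise ValueError(f"unknown domain {domain!r}; known: {DOMAINS}")
        return cls(domain=domain, tests=DEFAULT_BATTERIES[domain])


@dataclass
class CompositeScores:
    """Composite score (z-units) per subject for one component."""

    domain: str
    scores: pd.Series  # index: subject_id, values: composite in z-units

    @property
    def n_subjects(self) -> int:
        return int(len(self.scores))

    @property
    def subject_ids(self) -> list:
        return list(self.scores.index)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def normalize_test(raw: pd.Series | np.ndarray) -> pd.Series:
    """z-score a raw test column over its non-missing subjects.

    Uses the sample standard deviation (n-1 denominator).  Requires at
    least two observed values and nonzero variance; missing entries stay
    missing.
    """
    s = pd.Series(raw, dtype=float)
    observed = s.dropna()
    if len(observed) < 2:
        raise ValueError(f"need >= 2 non-missing values to normalize, got {len(observed)}")
    sd = observed.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot normalize a zero-variance test column")
    return (s - observed.mean()) / sd


def composite_score(table: pd.DataFrame, battery: TestBattery) -> CompositeScores:
    """Mean normalized score across a battery's tests, per subject.

    ``table`` must carry one column per test (indexed by subject id or with
    a ``subject_id`` column).  Subjects missing any of the battery's tests
    are excluded before normalization, so z-statistics are computed on the
    complete-case subsample — the component-specific analyzed sample.
    """
    df = table
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    missing_cols = [t for t in battery.tests if t not in df.columns]
    if missing_cols:
        raise KeyError(f"score table lacks test columns: {missing_cols}")

    complete = df.loc[df[list(battery.tests)].notna().all(axis=1)]
    if len(complete) == 0:
        raise ValueError(f"no subjects with complete data for domain {battery.domain!r}")

    z = pd.DataFrame({t: normalize_test(complete[t]) for t in battery.tests})
    comp = z.mean(axis=1)
    comp.name = battery.domain
    return CompositeScores(domain=battery.domain, scores=comp)


def read_score_table(path) -> pd.DataFrame:
    """Read a subject score table (CSV or TSV, header row required)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "subject_id" not in df.columns:
        raise ValueError("score table must have a subject_id column")
    return df
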