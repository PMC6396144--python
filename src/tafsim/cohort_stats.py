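"""Cohort summaries and telomere-intensity comparisons.

The mouse — not the cell — is the statistical unit throughout: per-mouse
means and TAF-positive fractions are computed first, and cohort summaries
report mean ± SEM across mice within each age group, matching how such
cohorts are conventionally reported.

``mann_whitney`` implements the two-sample rank test from first principles:
the U statistic with half-credit for ties, an exact two-sided p-value from
the full null distribution of U when both samples are small and tie-free,
and otherwise the normal approximation with tie-corrected variance and
continuity correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

from .synthetic import CohortDataset, IntensityDataset

__all__ = [
    "AgeSummary",
    "TestResult",
    "summarize_cohort",
    "percent_signal_loss",
    "mann_whitney",
]


@dataclass(frozen=True)
class AgeSummary:
    """Mean ± SEM (across mice) of TAF observables at one age."""

    age_months: float
    mean_taf: float
    sem_taf: float
    frac_positive: float
    sem_frac: float
    mean_total_foci: float
    n_mice: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "normal-approximation" | "permutation"
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value must lie in [0, 1]")


def _sem(values: np.ndarray) -> float:
    if values.size <= 1:
        return 0.0
    return float(values.std(ddof=1) / math.sqrt(values.size))


def summarize_cohort(dataset: CohortDataset) -> list[AgeSummary]:
    """Per-age summaries with the mouse as the unit of replication."""
    by_age: dict[float, list] = {}
    for s in dataset.samples:
        if s.n_cells == 0:
            warnings.warn(
                f"mouse {s.mouse_id} has no cells and is excluded", stacklevel=2
            )
            continue
        by_age.setdefault(s.age_months, []).append(s)

    out = []
    for age in sorted(by_age):
        # stable order so summaries are exactly invariant to input ordering
        mice = sorted(by_age[age], key=lambda m: m.mouse_id)
        means = np.array([m.mean_taf for m in mice])
        fracs = np.array([m.frac_positive for m in mice])
        totals = np.array([float(m.total_foci_counts.mean()) for m in mice])
        out.append(
            AgeSummary(
                age_months=age,
                mean_taf=float(means.mean()),
                sem_taf=_sem(means),
                frac_positive=float(fracs.mean()),
                sem_frac=_sem(fracs),
                mean_total_foci=float(totals.mean()),
                n_mice=len(mice),
            )
        )
    return out


def summaries_to_frame(summaries: list[AgeSummary]):
    import pandas as pd

    return pd.DataFrame([s.__dict__ for s in summaries])


def percent_signal_loss(
    reference: IntensityDataset | np.ndarray,
    test: IntensityDataset | np.ndarray,
    statistic: str = "median",
) -> float:
    """Percentage drop in telomere FISH signal of ``test`` vs ``reference``.

    ``100 * (1 - stat(test) / stat(reference))``; negative when the test
    set is brighter.  Median by default (robust to the long upper tail of
    intensity distributions); a mean-based variant is available.
    """
    ref = reference.intensities if isinstance(reference, IntensityDataset) else np.asarray(reference, dtype=float)
    tst = test.intensities if isinstance(test, IntensityDataset) else np.asarray(test, dtype=float)
    if ref.size == 0 or tst.size == 0:
        raise ValueError("both intensity sets must be nonempty")
    stat = np.median if statistic == "median" else np.mean
    if statistic not in ("median", "mean"):
        raise ValueError("statistic must be 'median' or 'mean'")
    denom = float(stat(ref))
    if denom <= 0:
        raise ValueError("reference signal statistic must be positive")
    return 100.0 * (1.0 - float(stat(tst)) / denom)


@lru_cache(maxsize=None)
def _exact_u_counts(n1: int, n2: int) -> tuple:
    """Null distribution of U as counts over u = 0..n1*n2 (no ties).

    Standard counting recurrence: c(n1, n2, u) = c(n1-1, n2, u-n2) +
    c(n1, n2-1, u), i.e. the number of ways the largest observation belongs
    to sample 1 (contributing n2 wins) or sample 2.
    """
    if n1 == 0 or n2 == 0:
        return (1,)
    a = _exact_u_counts(n1 - 1, n2)
    b = _exact_u_counts(n1, n2 - 1)
    counts = [0] * (n1 * n2 + 1)
    for u, c in enumerate(a):
        counts[u + n2] += c
    for u, c in enumerate(b):
        counts[u] += c
    return tuple(counts)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: wins over y, ties counted half."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks for ties
    r1 = ranks[: x.size].sum()
    return float(r1 - x.size * (x.size + 1) / 2.0)


def mann_whitney(x, y, method: str = "auto", exact_threshold: int = 8) -> TestResult:
    """Two-sided Mann–Whitney U test.

    ``method`` is ``"exact"`` (full null distribution of U; requires no
    ties), ``"normal"`` (tie-corrected normal approximation with continuity
    correction), or ``"auto"``: exact when both samples have at most
    ``exact_threshold`` observations and the pooled data are tie-free.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    u = _u_statistic(x, y)

    if method == "auto":
        method = (
            "exact"
            if (n1 <= exact_threshold and n2 <= exact_threshold and not has_ties)
            else "normal"
        )
    if method == "exact":
        if has_ties:
            raise ValueError("exact method requires tie-free data")
        counts = _exact_u_counts(n1, n2)
        total = sum(counts)
        mid = n1 * n2 / 2.0
        dev = abs(u - mid)
        p = sum(c for v, c in enumerate(counts) if abs(v - mid) >= dev - 1e-12) / total
        return TestResult(u, min(1.0, p), "exact", n1, n2)
    if method != "normal":
        raise ValueError(f"unknown method {method!r}")

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:  # all observations identical
        return TestResult(u, 1.0, "normal-approximation", n1, n2)
    # continuity correction shrinks the deviation by 1/2
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * norm.sf(z)
    return TestResult(u, min(1.0, p), "normal-approximation", n1, n2)
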