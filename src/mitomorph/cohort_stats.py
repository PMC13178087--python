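"""Cohort-level statistics: Me [Q1; Q3] summaries, Mann–Whitney U, ROC AUC.

Conventions

* Quartiles use the Tukey inclusive-median (hinge) rule: each half of the
  sorted sample includes the median when n is odd.  Statistical packages
  differ here (SPSS's default weighted-average rule gives slightly different
  hinges); the rule is fixed and tested so summaries are reproducible.
* The Mann–Whitney test is two-sided with midranks for ties.  ``mode="exact"``
  enumerates the null for small tie-free samples and falls back to a seeded
  Monte-Carlo permutation null when ties make the closed-form tabulation
  invalid; ``mode="asymptotic"`` uses the normal approximation with tie
  correction and continuity correction.
* ROC AUC is computed by the rank (Mann–Whitney) formulation with midranks,
  so the identity ``AUC · n0 · n1 = U`` holds exactly for the matching
  orientation.  The reported AUC is oriented to be ≥ 0.5 and carries an
  explicit direction flag, since a predictor may be *lower* in the positive
  class (as the total index is in atrial fibrillation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "CohortComparison",
    "summarize",
    "tukey_quartiles",
    "mann_whitney",
    "roc_auc",
    "roc_points",
    "compare_cohort",
    "comparison_table",
    "PARAMETERS",
]

#: patient-level parameters compared between outcome groups
PARAMETERS = ("taim_pct", "oimr_pct", "total_index")

#: largest combined sample for which the exact null is enumerated by default
EXACT_N_LIMIT = 25


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float

    def __str__(self) -> str:
        return f"{self.median:g} [{self.q1:g}; {self.q3:g}] (n={self.n})"


@dataclass(frozen=True)
class TestResult:
    u_statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class CohortComparison:
    parameter: str
    summary_g0: GroupSummary
    summary_g1: GroupSummary
    u_statistic: float
    p_value: float
    auc: float
    auc_direction: str


def tukey_quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """(q1, median, q3) by Tukey's inclusive-median hinge rule."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")
    med = float(np.median(x))
    half = (n + 1) // 2  # lower half includes the median position when n odd
    q1 = float(np.median(x[:half]))
    q3 = float(np.median(x[n - half:]))
    return q1, med, q3


def summarize(values: Sequence[float]) -> GroupSummary:
    """Median and interquartile range, the study's summary convention."""
    q1, med, q3 = tukey_quartiles(values)
    return GroupSummary(n=len(np.asarray(values)), median=med, q1=q1, q3=q3)


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(
    g0: Sequence[float],
    g1: Sequence[float],
    mode: str = "auto",
    n_permutations: int = 100_000,
    seed: int | None = 0,
) -> TestResult:
    """Two-sided Mann–Whitney U test between two independent samples.

    Returns U for the first sample (so ``U + U' = n0·n1``).  ``mode``:

    * ``"auto"`` — exact when ``n0+n1 <= EXACT_N_LIMIT`` and tie-free,
      normal approximation otherwise;
    * ``"exact"`` — exact enumeration; with ties, a seeded Monte-Carlo
      permutation null (``n_permutations`` draws);
    * ``"asymptotic"`` — normal approximation with tie and continuity
      correction.
    """
    x0 = np.asarray(g0, dtype=float)
    x1 = np.asarray(g1, dtype=float)
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both groups must be nonempty")
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")

    pooled = np.concatenate([x0, x1])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both groups; p = 1")
        return TestResult(len(x0) * len(x1) / 2.0, 1.0, "degenerate")

    ties = _has_ties(pooled)
    small = len(pooled) <= EXACT_N_LIMIT
    if mode == "auto":
        mode = "exact" if (small and not ties) else "asymptotic"

    if mode == "exact" and ties:
        rng = np.random.default_rng(seed)
        res = stats.permutation_test(
            (x0, x1),
            lambda a, b, axis=-1: stats.mannwhitneyu(
                a, b, axis=axis, method="asymptotic"
            ).statistic,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=n_permutations,
            rng=rng,
        )
        return TestResult(float(res.statistic), float(res.pvalue), "permutation")

    method = "exact" if mode == "exact" else "asymptotic"
    res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), method)


def roc_auc(predictor: Sequence[float], outcome: Sequence[int]) -> tuple[float, str]:
    """AUC of ``predictor`` for the binary ``outcome`` via the rank formulation.

    Returns ``(auc, direction)`` with ``auc >= 0.5``; ``direction`` is
    ``"higher_predicts_positive"`` or ``"lower_predicts_positive"``.  The
    unoriented AUC (probability that a random positive case has the higher
    predictor value, ties counting ½) satisfies ``auc_raw · n0 · n1 = U`` with
    U from :func:`mann_whitney` of positives vs negatives.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("outcome must contain both classes 0 and 1")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    ranks = stats.rankdata(x)  # midranks
    u1 = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    auc_raw = u1 / (n0 * n1)
    if auc_raw >= 0.5:
        return float(auc_raw), "higher_predicts_positive"
    return float(1.0 - auc_raw), "lower_predicts_positive"


def roc_points(predictor: Sequence[float], outcome: Sequence[int]) -> pd.DataFrame:
    """Empirical ROC curve points (fpr, tpr, threshold) for plotting.

    The convention "predictor ≥ threshold ⇒ positive" is used; flip the
    predictor sign first when the lower value predicts the positive class.
    """
    x = np.asarray(predictor, dtype=float)
    y = np.asarray(outcome)
    order = np.argsort(-x, kind="stable")
    x, y = x[order], y[order]
    n1 = (y == 1).sum()
    n0 = (y == 0).sum()
    # step only at distinct thresholds
    distinct = np.r_[np.diff(x) != 0, True]
    tpr = np.cumsum(y == 1)[distinct] / n1
    fpr = np.cumsum(y == 0)[distinct] / n0
    return pd.DataFrame(
        {
            "threshold": np.r_[np.inf, x[distinct]],
            "fpr": np.r_[0.0, fpr],
            "tpr": np.r_[0.0, tpr],
        }
    )


def compare_cohort(
    results,
    parameters: Sequence[str] = PARAMETERS,
    mode: str = "auto",
    seed: int | None = 0,
) -> dict[str, CohortComparison]:
    """Group comparison of each morphometry parameter against the outcome.

    ``results`` is a DataFrame (or a list of per-patient result objects) with
    a binary ``group_label`` column; each parameter gets a Me [Q1; Q3]
    summary per group, a two-sided Mann–Whitney test and an oriented ROC AUC.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame(
            [
                {c: getattr(r, c) for c in ("patient_id", "group_label", *parameters)}
                for r in results
            ]
        )
    labels = results["group_label"].astype(int)
    if set(labels.unique()) != {0, 1}:
        raise ValueError(
            f"need patients in both groups; labels present: {sorted(labels.unique())}"
        )
    if (labels == 0).sum() < 2 or (labels == 1).sum() < 2:
        raise ValueError("need at least 2 patients per group")

    out: dict[str, CohortComparison] = {}
    for param in parameters:
        v0 = results.loc[labels == 0, param].to_numpy(dtype=float)
        v1 = results.loc[labels == 1, param].to_numpy(dtype=float)
        test = mann_whitney(v0, v1, mode=mode, seed=seed)
        auc, direction = roc_auc(
            results[param].to_numpy(dtype=float), labels.to_numpy()
        )
        out[param] = CohortComparison(
            parameter=param,
            summary_g0=summarize(v0),
            summary_g1=summarize(v1),
            u_statistic=test.u_statistic,
            p_value=test.p_value,
            auc=auc,
            auc_direction=direction,
        )
    return out


def comparison_table(comparisons: dict[str, CohortComparison]) -> pd.DataFrame:
    """Flatten comparisons into the report table written by the CLI."""
    rows = []
    for c in comparisons.values():
        rows.append(
            {
                "parameter": c.parameter,
                "n_g0": c.summary_g0.n,
                "median_g0": c.summary_g0.median,
                "q1_g0": c.summary_g0.q1,
                "q3_g0": c.summary_g0.q3,
                "n_g1": c.summary_g1.n,
                "median_g1": c.summary_g1.median,
                "q1_g1": c.summary_g1.q1,
                "q3_g1": c.summary_g1.q3,
                "u_statistic": c.u_statistic,
                "p_value": c.p_value,
                "auc": c.auc,
                "auc_direction": c.auc_direction,
            }
        )
    return pd.DataFrame(rows)
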