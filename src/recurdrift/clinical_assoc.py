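"""Clinical association statistics and the Ki-67/leukocyte histo-score.

Cohort-description contingency tables (receptor status, grade, age between
primary and recurrent tumors) use two-sided Fisher exact tests for 2x2
tables and Pearson chi-square (no continuity correction) for larger ones.
Group comparisons of continuous quantities (signature deltas, copy-number
gain counts, dissimilarities) use the Wilcoxon-Mann-Whitney rank-sum test
with Benjamini-Hochberg adjustment within an explicitly declared family.
Ranked monotone associations use Spearman correlation.

The histo-score summarizes routine pathology as the sum of the cohort
z-scores of the Ki-67-positive cell percentage and the infiltrating-
leukocyte percentage; patients are split at the median score and compared
by a two-group log-rank test on recurrence-free survival.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests


class ClinicalInputError(ValueError):
    pass


ER_PGR_LEVELS = {"positive", "negative"}
KI67_LEVELS = {"low", "high"}
ERBB2_LEVELS = {"normal", "amplified"}
GRADE_LEVELS = {"low", "intermediate", "high"}
AGE_LEVELS = {">55", "<=55"}


@dataclass(frozen=True)
class ClinicalRecord:
    """One sample's clinical annotation; None encodes a missing category."""

    patient_id: str
    role: str  # PT | IBTR
    er: Optional[str] = None
    pgr: Optional[str] = None
    ki67: Optional[str] = None
    erbb2: Optional[str] = None
    grade: Optional[str] = None
    age_group: Optional[str] = None
    ibtrfs_time: Optional[float] = None  # months
    event: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.role not in ("PT", "IBTR"):
            raise ClinicalInputError(f"role must be PT or IBTR, got {self.role!r}")
        for value, levels, name in (
            (self.er, ER_PGR_LEVELS, "ER"),
            (self.pgr, ER_PGR_LEVELS, "PgR"),
            (self.ki67, KI67_LEVELS, "Ki67"),
            (self.erbb2, ERBB2_LEVELS, "ERBB2"),
            (self.grade, GRADE_LEVELS, "grade"),
            (self.age_group, AGE_LEVELS, "age_group"),
        ):
            if value is not None and value not in levels:
                raise ClinicalInputError(f"{name} level {value!r} not in {sorted(levels)}")


@dataclass(frozen=True)
class HistologyRecord:
    patient_id: str
    ki67_pct: float
    leukocyte_pct: float

    def __post_init__(self) -> None:
        for p in (self.ki67_pct, self.leukocyte_pct):
            if not 0.0 <= p <= 100.0:
                raise ClinicalInputError(f"percentage {p} outside [0, 100]")


@dataclass
class AssociationResult:
    variable: str
    statistic: float
    raw_p: float
    test: str
    n: int
    adjusted_p: Optional[float] = None


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Two-sided by summation of all tables with the observed margins whose
    hypergeometric probability is <= that of the observed table.  A zero
    margin makes every table equally (un)informative; p = 1 by convention.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ClinicalInputError("fisher_exact_2x2 needs a nonnegative 2x2 table")
    if arr.sum() == 0:
        raise ClinicalInputError("empty table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p = 1 by convention", stacklevel=2)
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def chi_square_rxc(table: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) for an R x C table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ClinicalInputError("chi-square needs an R x C table with R, C >= 2")
    if arr.sum() == 0:
        raise ClinicalInputError("empty table")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def wilcoxon_rank_sum(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney rank-sum p-value.

    Exact null distribution when the combined sample is small (n <= 20)
    and tie-free; otherwise the normal approximation with tie correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ClinicalInputError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied across groups; p = 1", stacklevel=2)
        return 1.0
    ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ClinicalInputError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ClinicalInputError("spearman needs equal-length vectors of length >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ClinicalInputError("spearman undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def histoscore(record: HistologyRecord, cohort: Sequence[HistologyRecord]) -> float:
    """Sum of cohort z-scores of Ki-67 percentage and leukocyte percentage."""
    if len(cohort) < 2:
        raise ClinicalInputError("histo-score needs a cohort of >= 2 records")
    ki = np.array([r.ki67_pct for r in cohort], dtype=float)
    leu = np.array([r.leukocyte_pct for r in cohort], dtype=float)
    sd_ki = float(np.std(ki, ddof=1))
    sd_leu = float(np.std(leu, ddof=1))
    if sd_ki == 0:
        raise ClinicalInputError("degenerate marker: Ki-67 has zero cohort sd")
    if sd_leu == 0:
        raise ClinicalInputError("degenerate marker: leukocytes have zero cohort sd")
    return (record.ki67_pct - float(np.mean(ki))) / sd_ki + (
        record.leukocyte_pct - float(np.mean(leu))
    ) / sd_leu


def median_split(scores: Mapping[str, float]) -> dict[str, str]:
    """Split patients at the median score: <= median -> "low", above -> "high"."""
    if len(scores) < 2:
        raise ClinicalInputError("median split needs >= 2 patients")
    values = np.array(list(scores.values()), dtype=float)
    med = float(np.median(values))
    groups = {k: ("low" if v <= med else "high") for k, v in scores.items()}
    if len(set(groups.values())) == 1:
        warnings.warn("degenerate median split: all scores in one group", stacklevel=2)
    return groups


def logrank(
    groups: Sequence[str], times: Sequence[float], events: Sequence[bool]
) -> tuple[float, float]:
    """Two-group log-rank test (1 df chi-square), two-sided p."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ClinicalInputError(f"log-rank needs exactly 2 groups, got {labels.size}")
    if not events.any():
        warnings.warn("no events in either group; p = 1", stacklevel=2)
        return 0.0, 1.0
    mask = groups == labels[0]
    res = logrank_test(times[mask], times[~mask], events[mask], events[~mask])
    return float(res.test_statistic), float(res.p_value)


def table1_tests(clinical: Sequence[ClinicalRecord]) -> list[AssociationResult]:
    """Primary-vs-recurrence contingency tests over the standard biomarkers.

    ER/PgR/Ki-67/ERBB2/age use Fisher exact on 2x2 counts; grade uses
    chi-square on the 2x3 table.  Records with a missing category are
    dropped per variable; each result records the n actually used.
    """
    df = pd.DataFrame(
        {
            "role": [r.role for r in clinical],
            "ER": [r.er for r in clinical],
            "PgR": [r.pgr for r in clinical],
            "Ki67": [r.ki67 for r in clinical],
            "ERBB2": [r.erbb2 for r in clinical],
            "grade": [r.grade for r in clinical],
            "age": [r.age_group for r in clinical],
        }
    )
    results: list[AssociationResult] = []
    fisher_vars = {
        "ER": ["positive", "negative"],
        "PgR": ["positive", "negative"],
        "Ki67": ["low", "high"],
        "ERBB2": ["normal", "amplified"],
        "age": [">55", "<=55"],
    }
    for var, levels in fisher_vars.items():
        sub = df.dropna(subset=[var])
        table = [
            [int(((sub["role"] == role) & (sub[var] == lev)).sum()) for role in ("PT", "IBTR")]
            for lev in levels
        ]
        p = fisher_exact_2x2(table)
        results.append(AssociationResult(var, math.nan, p, "fisher_exact", len(sub)))
    sub = df.dropna(subset=["grade"])
    table = np.array(
        [
            [int(((sub["role"] == role) & (sub["grade"] == lev)).sum()) for lev in ("low", "intermediate", "high")]
            for role in ("PT", "IBTR")
        ]
    )
    table = table[:, table.sum(axis=0) > 0]  # levels absent from the cohort carry no information
    table = table[table.sum(axis=1) > 0, :]
    if min(table.shape) < 2:
        warnings.warn("degenerate grade table; chi-square not evaluable", stacklevel=2)
        results.append(AssociationResult("grade", math.nan, math.nan, "chi_square", len(sub)))
    else:
        statistic, _, p = chi_square_rxc(table)
        results.append(AssociationResult("grade", statistic, p, "chi_square", len(sub)))
    return results


def group_association_family(
    values: pd.DataFrame, groups: Mapping[str, str], family: str = ""
) -> list[AssociationResult]:
    """Wilcoxon rank-sum per column between two clinical groups, BH-adjusted.

    ``values`` is patients x variables; ``groups`` maps patient -> one of
    two labels.  The whole call is one multiple-testing family.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ClinicalInputError("group association needs exactly two group labels")
    results: list[AssociationResult] = []
    for col in values.columns:
        series = values[col].dropna()
        a = [series[p] for p in series.index if groups.get(p) == labels[0]]
        b = [series[p] for p in series.index if groups.get(p) == labels[1]]
        if not a or not b:
            continue
        p = wilcoxon_rank_sum(a, b)
        results.append(
            AssociationResult(f"{family}:{col}" if family else str(col), math.nan, p, "wilcoxon", len(a) + len(b))
        )
    adjusted = bh_adjust([r.raw_p for r in results])
    for r, ap in zip(results, adjusted):
        r.adjusted_p = float(ap)
    return results
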