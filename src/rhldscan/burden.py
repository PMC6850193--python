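"""Per-gene case-control burden testing and multiple-testing calibration.

Each gene is tested with a one-tailed Fisher exact test on the 2x2 table of
mutated / not-mutated counts in cases and controls, alternative = enrichment
in cases.  Because the number of genes that *could* reach significance
depends on how many subjects carry mutations, the Bonferroni correction is
calibrated adaptively: for each candidate case-carrier count x we count the
genes y(x) mutated in at least x subjects and ask whether a gene mutated in
x cases and no controls would pass alpha / y(x).

The Fisher tail is computed in exact rational arithmetic (the conditional
hypergeometric upper tail including the observed table), so P values are
exact to double precision at cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb
from typing import Iterable

import numpy as np
from scipy import stats

from .cohort import (
    GeneBurdenResult,
    GeneMutationMatrix,
    Subject,
    ValidationError,
    split_groups,
)


@lru_cache(maxsize=100_000)
def _fisher_tail_cached(a: int, b: int, c: int, d: int) -> float:
    n_case = a + b
    n_mut = a + c
    total = a + b + c + d
    hi = min(n_case, n_mut)
    tail = Fraction(0)
    denom = comb(total, n_mut)
    for x in range(a, hi + 1):
        tail += Fraction(comb(n_case, x) * comb(total - n_case, n_mut - x), denom)
    return float(tail)


def fisher_one_tailed(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail Fisher exact P for the 2x2 table [[a, b], [c, d]].

    Rows are case/control, columns mutated/not-mutated.  Conditioning on
    both margins, returns P(X >= a) for the hypergeometric count of mutated
    cases, including the observed table (the standard "greater"
    alternative).  Computed with exact integer arithmetic.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("2x2 counts must be non-negative")
    return _fisher_tail_cached(a, b, c, d)


def burden_scan(
    matrix: GeneMutationMatrix, cohort: Iterable[Subject]
) -> list[GeneBurdenResult]:
    """Fisher-test every gene with at least one mutated subject.

    Results are sorted by ascending P (ties by gene symbol).  The
    ``any_control_carrier`` flag marks genes mutated in at least one
    control; it is informational only and applied after testing, so it does
    not perturb the multiple-testing landscape.
    """
    cases, controls = split_groups(cohort)
    if not cases or not controls:
        raise ValidationError("burden scan needs both cases and controls")
    case_ids = {s.subject_id for s in cases}
    control_ids = {s.subject_id for s in controls}

    case_counts: dict[str, int] = {}
    control_counts: dict[str, int] = {}
    for sid, genes in matrix.entries.items():
        if sid in case_ids:
            for g in genes:
                case_counts[g] = case_counts.get(g, 0) + 1
        elif sid in control_ids:
            for g in genes:
                control_counts[g] = control_counts.get(g, 0) + 1

    results = []
    for gene in set(case_counts) | set(control_counts):
        a = case_counts.get(gene, 0)
        c = control_counts.get(gene, 0)
        b = len(case_ids) - a
        d = len(control_ids) - c
        results.append(
            GeneBurdenResult(
                gene=gene,
                a=a,
                b=b,
                c=c,
                d=d,
                p_one_tailed=fisher_one_tailed(a, b, c, d),
                any_control_carrier=c > 0,
            )
        )
    results.sort(key=lambda r: (r.p_one_tailed, r.gene))
    return results


@dataclass(frozen=True)
class QCCountResult:
    """Welch t comparison of per-subject mutated-gene totals, cases vs controls."""

    t: float
    p: float
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    degenerate: bool = False


def qc_count_comparison(
    matrix: GeneMutationMatrix, cohort: Iterable[Subject]
) -> QCCountResult:
    """Check that mutated-gene totals per subject do not separate the groups.

    A systematic difference would indicate batch or platform artifacts
    rather than trait biology, so the burden scan is only interpretable
    when this test is non-significant.  Uses the unequal-variance (Welch)
    two-sample t test.
    """
    cases, controls = split_groups(cohort)
    if len(cases) < 2 or len(controls) < 2:
        raise ValidationError("QC comparison needs >= 2 subjects per group")
    totals = matrix.genes_per_subject()
    x = np.array([totals[s.subject_id] for s in cases], dtype=float)
    y = np.array([totals[s.subject_id] for s in controls], dtype=float)
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        equal = x.mean() == y.mean()
        return QCCountResult(
            t=0.0 if equal else float("inf"),
            p=1.0 if equal else 0.0,
            n_case=len(x),
            n_control=len(y),
            mean_case=float(x.mean()),
            mean_control=float(y.mean()),
            degenerate=True,
        )
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return QCCountResult(
        t=float(t),
        p=float(p),
        n_case=len(x),
        n_control=len(y),
        mean_case=float(x.mean()),
        mean_control=float(y.mean()),
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Adaptive Bonferroni calibration of the burden scan.

    ``y_of_x`` maps x to the number of genes mutated in at least x subjects
    (cases and controls combined); ``min_x_nominal`` is the smallest
    case-carrier count (zero control carriers) reaching P < alpha, and
    ``min_x_bonferroni`` the smallest reaching P < alpha / y(x).  Either is
    None when no count up to the number of cases suffices.
    """

    model: str
    y_of_x: dict[int, int]
    min_x_nominal: int | None
    min_x_bonferroni: int | None
    alpha: float
    n_case: int
    n_control: int


def minimum_significant_carriers(
    n_case: int, n_control: int, alpha: float = 0.05
) -> int | None:
    """Smallest x with fisher_one_tailed(x, n_case-x, 0, n_control) < alpha."""
    for x in range(1, n_case + 1):
        if fisher_one_tailed(x, n_case - x, 0, n_control) < alpha:
            return x
    return None


def bonferroni_significant(
    results: Iterable[GeneBurdenResult], calib: "CalibrationResult"
) -> list[GeneBurdenResult]:
    """Genes passing the adaptive Bonferroni bound alpha / y(x).

    Each gene is judged at its own total carrier count x = a + c, against
    the number of genes y(x) mutated in at least that many subjects.
    """
    out = []
    for r in results:
        x = r.a + r.c
        y = max(calib.y_of_x.get(x, 0), 1)
        if r.p_one_tailed < calib.alpha / y:
            out.append(r)
    return out


def calibrate(
    matrix: GeneMutationMatrix,
    cohort: Iterable[Subject],
    alpha: float = 0.05,
) -> CalibrationResult:
    """Compute y(x) from the matrix and the two minimum-carrier thresholds.

    For the Bonferroni threshold the correction denominator at candidate
    count x is y(x), the number of genes mutated in >= x subjects; when no
    gene reaches x subjects y(x) is taken as 1 (a single hypothetical test
    needs no correction).
    """
    cohort = list(cohort)
    cases, controls = split_groups(cohort)
    if not cases or not controls:
        raise ValidationError("calibration needs both cases and controls")
    n_case, n_control = len(cases), len(controls)

    per_gene = matrix.subjects_per_gene()
    n_subjects = len(matrix.entries)
    y_of_x = {}
    for x in range(1, n_subjects + 1):
        y = sum(1 for n in per_gene.values() if n >= x)
        if y == 0:
            break
        y_of_x[x] = y

    min_x_nominal = minimum_significant_carriers(n_case, n_control, alpha)
    min_x_bonferroni = None
    for x in range(1, n_case + 1):
        y = max(y_of_x.get(x, 0), 1)
        if fisher_one_tailed(x, n_case - x, 0, n_control) < alpha / y:
            min_x_bonferroni = x
            break
    return CalibrationResult(
        model=matrix.model,
        y_of_x=y_of_x,
        min_x_nominal=min_x_nominal,
        min_x_bonferroni=min_x_bonferroni,
        alpha=alpha,
        n_case=n_case,
        n_control=n_control,
    )
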