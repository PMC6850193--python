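"""Mutational-load testing of candidate gene sets by exact binomial test.

Each (subject, gene) pair with the gene mutated for that subject and
belonging to the set counts as one mutated-gene instance.  Under the null
hypothesis that mutations fall on subjects irrespective of group, each
instance lands on a test-group subject with probability p0 = (#test
subjects) / (#subjects in the contrast); enrichment is assessed by the
upper tail of Binomial(n_total, p0) at the observed test-group count.
Subgroup contrasts (e.g. cases versus right-handed controls only, or a
single recruitment batch) restrict the subject universe and recompute p0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import stats

from .cohort import (
    GeneMutationMatrix,
    GeneSet,
    GeneSetLoadResult,
    Subject,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contrast:
    """Selects the test and comparison subject subsets for a load test.

    ``batch`` restricts both sides to one recruitment batch.  Handedness
    filters allow the post-hoc contrasts (e.g. cases versus right-handed
    controls, or right- versus left-handed controls).
    """

    test_group: str = "case"
    comparison_group: str = "control"
    test_handedness: str | None = None
    comparison_handedness: str | None = None
    batch: str | None = None

    def resolve(
        self, cohort: Iterable[Subject]
    ) -> tuple[list[str], list[str]]:
        cohort = list(cohort)
        if self.batch is not None:
            cohort = [s for s in cohort if s.batch == self.batch]

        def pick(group: str, handedness: str | None) -> list[str]:
            return [
                s.subject_id
                for s in cohort
                if s.group == group
                and (handedness is None or s.handedness == handedness)
            ]

        test = pick(self.test_group, self.test_handedness)
        comparison = pick(self.comparison_group, self.comparison_handedness)
        if not test or not comparison:
            raise ValidationError("contrast selects an empty subject subset")
        if set(test) & set(comparison):
            raise ValidationError("test and comparison subsets overlap")
        return test, comparison


def set_instance_counts(
    matrix: GeneMutationMatrix,
    gene_set: GeneSet,
    test_subjects: Sequence[str],
    comparison_subjects: Sequence[str],
) -> tuple[int, int]:
    """Count mutated-gene instances in the test group and the whole contrast.

    k_test sums |mutated genes ∩ set| over test subjects; n_total sums over
    test plus comparison subjects.  Genes absent from the matrix contribute
    nothing.  Ineligible sets (< 10 genes) are refused.
    """
    if not gene_set.eligible:
        raise ValidationError(
            f"gene set {gene_set.name!r} has {gene_set.size} genes; "
            "load testing requires at least 10"
        )
    genes = gene_set.genes

    def total(ids: Sequence[str]) -> int:
        return sum(len(matrix.entries.get(sid, set()) & genes) for sid in ids)

    k_test = total(test_subjects)
    n_total = k_test + total(comparison_subjects)
    return k_test, n_total


def binomial_load_test(k_test: int, n_total: int, p0: float) -> float:
    """Upper-tail exact binomial P(X >= k_test), X ~ Binomial(n_total, p0).

    Returns 1.0 for the empty contrast (n_total = 0): no instances carry no
    evidence of enrichment.
    """
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"null proportion {p0} outside (0, 1)")
    if not 0 <= k_test <= n_total:
        raise ValidationError("need 0 <= k_test <= n_total")
    if n_total == 0:
        return 1.0
    return float(
        stats.binomtest(k_test, n_total, p0, alternative="greater").pvalue
    )


def load_scan(
    matrix: GeneMutationMatrix,
    set_collection: Iterable[GeneSet],
    cohort: Iterable[Subject],
    contrast: Contrast = Contrast(),
) -> list[GeneSetLoadResult]:
    """Run the load test for every eligible set under one contrast.

    Ineligible sets are skipped with a warning.  Results keep the input
    set order; no correction across sets is applied (raw P values are
    reported alongside the number of sets tested).
    """
    test_ids, comparison_ids = contrast.resolve(cohort)
    p0 = len(test_ids) / (len(test_ids) + len(comparison_ids))
    results = []
    for gene_set in set_collection:
        if not gene_set.eligible:
            logger.warning(
                "skipping gene set %r (%d genes < 10)",
                gene_set.name, gene_set.size,
            )
            continue
        k, n = set_instance_counts(matrix, gene_set, test_ids, comparison_ids)
        results.append(
            GeneSetLoadResult(
                name=gene_set.name,
                set_size=gene_set.size,
                k_test=k,
                n_total=n,
                p0=p0,
                p_binomial=binomial_load_test(k, n, p0),
            )
        )
    return results
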