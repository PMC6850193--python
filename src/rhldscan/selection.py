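"""Classify subjects as rightward-language-dominant from laterality indices.

The two-step rule: a subject is rightward-dominant if the language-production
laterality index falls below a stringent cutoff (step 1, default -50), or
failing that if all three task indices (production, reading, listening) fall
below a milder cutoff (step 2, default -15).  The step-2 cutoff stands in for
the boundary that a Gaussian-mixture consensus clustering of the joint
three-task distribution produced in the original screening; a user-supplied
classifier hook is accepted for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Callable, Iterable

from .cohort import Subject, ValidationError

RHLD_STEP1 = "rhld_step1"
RHLD_STEP2 = "rhld_step2"
NOT_RHLD = "not_rhld"


@dataclass(frozen=True)
class SelectionRule:
    """Thresholds of the two-step rightward-dominance rule.

    All comparisons are strict (``<`` / ``>``).  ``control_cutoff`` marks
    strongly leftward-lateralized controls (production index > +50).
    """

    production_cutoff: float = -50.0
    all_task_cutoff: float = -15.0
    control_cutoff: float = 50.0

    def __post_init__(self) -> None:
        if not (
            self.production_cutoff <= self.all_task_cutoff < 0 < self.control_cutoff
        ):
            raise ValidationError(
                "selection rule requires production_cutoff <= all_task_cutoff "
                "< 0 < control_cutoff"
            )


class ClassificationError(ValueError):
    """A subject cannot be classified (required laterality index missing)."""


def classify_rhld(
    subject: Subject,
    rule: SelectionRule = SelectionRule(),
    second_step: Callable[[Subject], bool] | None = None,
) -> str:
    """Label one subject as rhld_step1, rhld_step2 or not_rhld.

    Step 1 tests production alone against the stringent cutoff; subjects
    passing step 1 are labelled rhld_step1 even if they would also pass
    step 2.  Step 2 requires all three task indices present and below the
    milder cutoff; ``second_step`` replaces that built-in rule when given.
    """
    if subject.hfli_production is None:
        raise ClassificationError(
            f"subject {subject.subject_id} has no production laterality index"
        )
    if subject.hfli_production < rule.production_cutoff:
        return RHLD_STEP1
    if second_step is not None:
        return RHLD_STEP2 if second_step(subject) else NOT_RHLD
    tasks = (subject.hfli_production, subject.hfli_reading, subject.hfli_listening)
    if all(t is not None and t < rule.all_task_cutoff for t in tasks):
        return RHLD_STEP2
    return NOT_RHLD


def summarize_laterality(subjects: Iterable[Subject]) -> dict:
    """Per-group median and [min; max] of EHI and each laterality index.

    Missing values are dropped per statistic; a measure with no observed
    values in a group is reported as None.  Mirrors the median [min-max]
    presentation of cohort summary tables.
    """
    groups: dict[str, list[Subject]] = {}
    for s in subjects:
        groups.setdefault(s.group, []).append(s)

    def stat(values: list[float | None]) -> dict | None:
        present = [v for v in values if v is not None]
        if not present:
            return None
        return {
            "n": len(present),
            "median": median(present),
            "min": min(present),
            "max": max(present),
        }

    summary = {}
    for group, members in groups.items():
        summary[group] = {
            "n": len(members),
            "ehi": stat([s.ehi for s in members]),
            "hfli_production": stat([s.hfli_production for s in members]),
            "hfli_reading": stat([s.hfli_reading for s in members]),
            "hfli_listening": stat([s.hfli_listening for s in members]),
        }
    return summary
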