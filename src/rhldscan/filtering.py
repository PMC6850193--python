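"""Annotation-driven variant filters and the two monogenic mutation models.

The filters narrow a whole-genome call set to rare, putatively
protein-disrupting variants: an impact-severity filter (coding MEDIUM/HIGH
or noncoding HIGH, dropping MEDIUM missense calls that PolyPhen labels
benign), a within-batch cohort-presence filter removing likely platform
artifacts, and per-model minor-allele-frequency bounds.  The dominant model
calls a gene mutated for a subject on any single qualifying alternate
allele; the recessive model requires a homozygous qualifying variant or
putative compound heterozygosity (two or more distinct heterozygous
variants in the gene, discarded only when read-level phase proves every
pairing to lie on the same allele).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .cohort import (
    AnnotatedVariant,
    GeneMutationMatrix,
    Subject,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the variant-level filters.

    ``cohort_presence_max`` is an exclusive upper bound on alternate-allele
    carriers per batch (variants carried by at least this many subjects in a
    batch are removed as likely platform artifacts).  The MAF bounds are the
    Hardy-Weinberg/penetrance-motivated cutoffs: recessive 10%, dominant 1%.
    Variants absent from every population database are kept when
    ``keep_missing_maf`` (novel variants cannot be excluded on frequency).
    """

    cohort_presence_max: int = 19
    recessive_maf_max: float = 0.10
    dominant_maf_max: float = 0.01
    keep_missing_maf: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.dominant_maf_max <= self.recessive_maf_max < 1.0:
            raise ValidationError(
                "need 0 < dominant_maf_max <= recessive_maf_max < 1"
            )
        if self.cohort_presence_max < 2:
            raise ValidationError("cohort_presence_max must be >= 2")


def max_maf(variant: AnnotatedVariant) -> float | None:
    """Maximum allele frequency across the available population databases.

    Returns None when the variant carries no frequency annotation at all.
    """
    if not variant.maf_by_source:
        return None
    freqs = variant.maf_by_source.values()
    for f in freqs:
        if not 0.0 <= f <= 1.0:
            raise ValidationError(
                f"frequency {f} outside [0, 1] at {variant.chrom}:{variant.pos}"
            )
    return max(freqs)


def severity_filter(
    variants: Iterable[AnnotatedVariant],
) -> list[AnnotatedVariant]:
    """Keep protein-coding MEDIUM/HIGH and noncoding HIGH impact variants.

    Coding MEDIUM variants explicitly predicted benign by PolyPhen are
    dropped; MEDIUM variants with no PolyPhen call are retained.  Unknown
    severity labels are dropped with a warning.
    """
    kept = []
    for v in variants:
        if v.severity not in ("HIGH", "MEDIUM", "LOW", "MODIFIER"):
            logger.warning(
                "dropping variant %s:%s with unknown severity %r",
                v.chrom, v.pos, v.severity,
            )
            continue
        if v.region_class == "coding":
            if v.severity == "HIGH":
                kept.append(v)
            elif v.severity == "MEDIUM" and v.polyphen != "benign":
                kept.append(v)
        else:  # noncoding: only splice-level HIGH impact
            if v.severity == "HIGH":
                kept.append(v)
    return kept


def cohort_presence_filter(
    variants: Iterable[AnnotatedVariant],
    batch_map: Mapping[str, str],
    config: FilterConfig = FilterConfig(),
) -> list[AnnotatedVariant]:
    """Drop variants carried by >= cohort_presence_max subjects in any batch.

    Carrier = het or hom_alt.  The bound is applied within each batch
    separately (the batches were sequenced on different platforms/protocols,
    and recurrent within-batch calls are likely platform-specific errors or
    undercatalogued common variants).
    """
    kept = []
    for v in variants:
        per_batch: dict[str, int] = {}
        for sid in v.carriers():
            batch = batch_map.get(sid)
            if batch is None:
                continue
            per_batch[batch] = per_batch.get(batch, 0) + 1
        if all(n < config.cohort_presence_max for n in per_batch.values()):
            kept.append(v)
    return kept


def _qualifies(
    variant: AnnotatedVariant, maf_bound: float, config: FilterConfig
) -> bool:
    m = max_maf(variant)
    if m is None:
        return config.keep_missing_maf
    return m < maf_bound


def dominant_mutated_genes(
    subject_id: str,
    variants: Iterable[AnnotatedVariant],
    config: FilterConfig = FilterConfig(),
) -> set[str]:
    """Genes with >= 1 qualifying het or hom_alt variant in this subject.

    Qualifying = maximum database MAF below the dominant bound, or no MAF
    annotation.  Variants are assumed already severity- and
    cohort-presence-filtered.
    """
    genes = set()
    for v in variants:
        if v.genotypes.get(subject_id) in ("het", "hom_alt") and _qualifies(
            v, config.dominant_maf_max, config
        ):
            genes.add(v.gene)
    return genes


def recessive_mutated_genes(
    subject_id: str,
    variants: Iterable[AnnotatedVariant],
    config: FilterConfig = FilterConfig(),
) -> set[str]:
    """Genes mutated under the recessive model for this subject.

    A gene qualifies through a homozygous qualifying variant, or through
    putative compound heterozygosity: at least two distinct qualifying
    heterozygous variants of which at least one pairing is not proven to
    lie on the same allele.  Phase proof requires both variants to carry
    the same read-phase label for this subject; a gene whose heterozygous
    variants are all proven mutually in cis is excluded, but one unphased
    variant alongside a phased pair suffices to retain the gene (it may
    pair in trans with either).
    """
    hom_genes: set[str] = set()
    hets: dict[str, list[AnnotatedVariant]] = {}
    for v in variants:
        gt = v.genotypes.get(subject_id)
        if gt not in ("het", "hom_alt"):
            continue
        if not _qualifies(v, config.recessive_maf_max, config):
            continue
        if gt == "hom_alt":
            hom_genes.add(v.gene)
        else:
            hets.setdefault(v.gene, []).append(v)

    genes = set(hom_genes)
    for gene, vs in hets.items():
        if gene in genes or len(vs) < 2:
            continue
        # distinct variant sites only: the same site listed twice is one mutation
        distinct = {v.key: v for v in vs}.values()
        if len(distinct) < 2:
            continue
        labels = [v.phase_groups.get(subject_id) for v in distinct]
        proven_cis_all = all(lab is not None for lab in labels) and len(
            set(labels)
        ) == 1
        if not proven_cis_all:
            genes.add(gene)
    return genes


def build_matrix(
    cohort: Iterable[Subject],
    variants: Iterable[AnnotatedVariant],
    model: str,
    config: FilterConfig = FilterConfig(),
) -> GeneMutationMatrix:
    """Assemble the subjects x genes boolean matrix under one model.

    ``variants`` must already be severity- and cohort-presence-filtered
    (see :func:`prepare_variants`).  Subjects with no variant data get an
    all-false row with a warning.
    """
    cohort = list(cohort)
    variants = list(variants)
    with_data = {sid for v in variants for sid, gt in v.genotypes.items()
                 if gt != "missing"}
    entries: dict[str, set[str]] = {}
    for s in cohort:
        if variants and s.subject_id not in with_data:
            logger.warning(
                "subject %s has no observed genotypes; all-false row",
                s.subject_id,
            )
        if model == "dominant":
            entries[s.subject_id] = dominant_mutated_genes(
                s.subject_id, variants, config
            )
        elif model == "recessive":
            entries[s.subject_id] = recessive_mutated_genes(
                s.subject_id, variants, config
            )
        else:
            raise ValidationError(f"unknown model {model!r}")
    return GeneMutationMatrix(model=model, entries=entries)


def prepare_variants(
    variants: Iterable[AnnotatedVariant],
    cohort: Iterable[Subject],
    config: FilterConfig = FilterConfig(),
) -> list[AnnotatedVariant]:
    """Severity filter followed by the per-batch cohort-presence filter."""
    batch_map = {s.subject_id: s.batch for s in cohort}
    return cohort_presence_filter(
        severity_filter(variants), batch_map, config
    )
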