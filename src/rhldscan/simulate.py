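"""Seeded generator of synthetic case-control cohorts.

The generator emulates the statistical structure the screening pipeline
assumes: 67 subjects (33 rightward-language-dominant cases, 34 controls of
mixed handedness) recruited in two batches with different task coverage and
read lengths; per-subject counts of dominant- and recessive-model mutated
genes near the observed study rates (hundreds and tens of genes per subject
respectively); rare-skewed database allele frequencies including
database-absent variants; a configurable fraction of recessive events
realized as compound heterozygotes, with a small proven-in-cis fraction to
exercise the phase-discard rule; and laterality indices drawn from a
two-component mixture (leftward mode near +60, rightward near -60).

Optional implants create ground truth for power studies: a penetrant causal
gene carried by a chosen number of cases, or a rate-ratio enrichment of
mutations within one named gene set.

Everything is deterministic under the configured seed.  Two entry points
trade realism for speed: :func:`generate` materializes full annotated
variant tables that round-trip through the filters, while
:func:`sample_matrix` draws gene-mutation matrices directly for replicate-
heavy simulation studies (null calibration, power curves).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

from .cohort import (
    AnnotatedVariant,
    GeneMutationMatrix,
    GeneSet,
    Subject,
    ValidationError,
    write_cohort,
    write_gene_sets_gmt,
    write_variants_flat,
)


@dataclass(frozen=True)
class BatchSpec:
    """One recruitment batch: subject counts and which tasks were measured."""

    label: str
    n_case: int
    n_control_lh: int
    n_control_rh: int
    tasks: tuple[str, ...] = ("production", "reading", "listening")
    read_length: str = "150bp"


@dataclass(frozen=True)
class CausalGeneSpec:
    """A penetrant implanted gene: carriers land in cases w.p. ``penetrance``."""

    gene: str
    model: str = "dominant"
    penetrance: float = 1.0
    n_carriers: int = 12


@dataclass(frozen=True)
class SetEffectSpec:
    """Multiply the per-gene mutation probability within one set, in cases."""

    set_name: str
    rate_ratio: float = 2.0
    model: str = "dominant"

    def __post_init__(self) -> None:
        if self.rate_ratio < 1.0:
            raise ValidationError("set-effect rate ratio must be >= 1")


@dataclass(frozen=True)
class HfliComponent:
    mean: float
    sd: float


# Batch composition mirrors the study design: one three-task batch with
# handedness-balanced controls, one production-only batch with right-handed
# controls (33 cases, 34 controls, 14 LH / 20 RH controls overall).
DEFAULT_BATCHES = (
    BatchSpec("BILGIN", n_case=17, n_control_lh=14, n_control_rh=8,
              tasks=("production", "reading", "listening"), read_length="90bp"),
    BatchSpec("GOAL", n_case=16, n_control_lh=0, n_control_rh=12,
              tasks=("production",), read_length="150bp"),
)

DEFAULT_SET_SIZES = {
    "actin_like": ("GO:SYN0001", 205),
    "cilium_like": ("GO:SYN0002", 173),
    "lr_axis_like": ("GO:SYN0003", 13),
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; the seed fully determines the output."""

    batches: tuple[BatchSpec, ...] = DEFAULT_BATCHES
    gene_universe: int = 20_000
    set_definitions: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_SET_SIZES)
    )
    # target mean mutated genes per subject, per model
    dominant_rate: float = 240.0
    recessive_rate: float = 50.0
    causal_gene: CausalGeneSpec | None = None
    set_effect: SetEffectSpec | None = None
    hfli_case: HfliComponent = HfliComponent(-60.0, 15.0)
    hfli_control: HfliComponent = HfliComponent(60.0, 15.0)
    # recessive event composition
    hom_fraction: float = 0.5          # homozygous vs compound-het events
    in_phase_fraction: float = 0.05    # extra compound hets proven in cis
    maf_missing_fraction: float = 0.3  # database-absent variants
    n_chaff: int = 300                 # non-qualifying variants for the filters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_universe < 1:
            raise ValidationError("gene universe must be positive")
        for name, (_, size) in self.set_definitions.items():
            if size > self.gene_universe:
                raise ValidationError(
                    f"set {name!r} size {size} exceeds gene universe"
                )
        for rate in (self.dominant_rate, self.recessive_rate):
            if not 0 <= rate <= self.gene_universe:
                raise ValidationError("background rate outside [0, universe]")

    @property
    def n_case(self) -> int:
        return sum(b.n_case for b in self.batches)

    @property
    def n_control(self) -> int:
        return sum(b.n_control_lh + b.n_control_rh for b in self.batches)


def gene_names(universe: int) -> list[str]:
    return [f"G{i:05d}" for i in range(universe)]


def generate_cohort(config: SimConfig, rng: np.random.Generator) -> list[Subject]:
    """Draw the phenotype table: batches, groups, handedness, EHI, HFLIs."""
    subjects: list[Subject] = []
    first_case = True
    for batch in config.batches:
        roster = (
            [("case", "LH")] * batch.n_case
            + [("control", "LH")] * batch.n_control_lh
            + [("control", "RH")] * batch.n_control_rh
        )
        for i, (group, hand) in enumerate(roster):
            sid = f"{batch.label}_S{i + 1:02d}"
            if group == "case":
                comp = config.hfli_case
                # one atypical right-handed case, as in mixed-handedness cohorts
                if first_case:
                    hand, first_case = "RH", False
                ehi = float(np.clip(rng.normal(-60.0, 40.0), -100, 100))
                if hand == "RH":
                    ehi = abs(ehi)
            else:
                comp = config.hfli_control
                loc = -80.0 if hand == "LH" else 80.0
                ehi = float(np.clip(rng.normal(loc, 20.0), -100, 100))
            hfli = {
                task: float(rng.normal(comp.mean, comp.sd))
                for task in ("production", "reading", "listening")
            }
            subjects.append(
                Subject(
                    subject_id=sid,
                    batch=batch.label,
                    group=group,
                    handedness=hand,
                    ehi=round(ehi, 2),
                    hfli_production=round(hfli["production"], 2)
                    if "production" in batch.tasks else None,
                    hfli_reading=round(hfli["reading"], 2)
                    if "reading" in batch.tasks else None,
                    hfli_listening=round(hfli["listening"], 2)
                    if "listening" in batch.tasks else None,
                )
            )
    return subjects


def build_gene_sets(config: SimConfig, rng: np.random.Generator) -> list[GeneSet]:
    names = gene_names(config.gene_universe)
    sets = []
    for set_name in sorted(config.set_definitions):
        source_id, size = config.set_definitions[set_name]
        idx = rng.choice(config.gene_universe, size=size, replace=False)
        sets.append(
            GeneSet(
                name=set_name,
                source_id=source_id,
                genes=frozenset(names[i] for i in idx),
            )
        )
    return sets


def _subject_gene_indices(
    rng: np.random.Generator,
    universe: int,
    rate: float,
    boost_indices: np.ndarray | None,
    rate_ratio: float,
) -> np.ndarray:
    """Draw per-gene Bernoulli mutations with an optional boosted subset."""
    p = rate / universe
    if boost_indices is None or rate_ratio == 1.0:
        k = rng.binomial(universe, p)
        return rng.choice(universe, size=k, replace=False)
    boosted = np.asarray(boost_indices)
    rest = np.setdiff1d(np.arange(universe), boosted, assume_unique=False)
    k_set = rng.binomial(len(boosted), min(1.0, p * rate_ratio))
    k_rest = rng.binomial(len(rest), p)
    chosen_set = rng.choice(boosted, size=k_set, replace=False)
    chosen_rest = rng.choice(rest, size=k_rest, replace=False)
    return np.concatenate([chosen_set, chosen_rest])


def sample_matrix(
    config: SimConfig,
    model: str,
    subjects: Iterable[Subject],
    rng: np.random.Generator,
    gene_sets: Iterable[GeneSet] | None = None,
) -> GeneMutationMatrix:
    """Draw a gene-mutation matrix directly (no variant records).

    This is the fast path for replicate-heavy studies; it produces the same
    marginal structure the full generator realizes through variants:
    independent per-gene mutation indicators at the model's background
    rate, an optional set-level rate-ratio in cases, and an optional
    penetrant causal gene.
    """
    names = gene_names(config.gene_universe)
    rate = config.dominant_rate if model == "dominant" else config.recessive_rate

    boost_idx = None
    rate_ratio = 1.0
    if (
        config.set_effect is not None
        and config.set_effect.model == model
        and gene_sets is not None
    ):
        target = {s.name: s for s in gene_sets}.get(config.set_effect.set_name)
        if target is None:
            raise ValidationError(
                f"set effect names unknown set {config.set_effect.set_name!r}"
            )
        name_to_idx = {g: i for i, g in enumerate(names)}
        boost_idx = np.array(sorted(name_to_idx[g] for g in target.genes))
        rate_ratio = config.set_effect.rate_ratio

    subjects = list(subjects)
    entries: dict[str, set[str]] = {}
    for s in subjects:
        boost = boost_idx if s.group == "case" else None
        idx = _subject_gene_indices(
            rng, config.gene_universe, rate, boost, rate_ratio
        )
        entries[s.subject_id] = {names[i] for i in idx}

    if config.causal_gene is not None and config.causal_gene.model == model:
        for sid in _causal_carriers(config, subjects, rng):
            entries[sid].add(config.causal_gene.gene)
    return GeneMutationMatrix(model=model, entries=entries)


def _causal_carriers(
    config: SimConfig, subjects: list[Subject], rng: np.random.Generator
) -> list[str]:
    spec = config.causal_gene
    assert spec is not None
    cases = [s.subject_id for s in subjects if s.group == "case"]
    controls = [s.subject_id for s in subjects if s.group == "control"]
    in_case = rng.random(spec.n_carriers) < spec.penetrance
    n_case_carriers = min(int(in_case.sum()), len(cases))
    n_control_carriers = min(spec.n_carriers - n_case_carriers, len(controls))
    carriers = list(rng.choice(cases, size=n_case_carriers, replace=False))
    if n_control_carriers:
        carriers += list(
            rng.choice(controls, size=n_control_carriers, replace=False)
        )
    return carriers


# ---------------------------------------------------------------------------
# full variant-level generation

_MAF_SOURCES = ("gnomAD", "ExAC", "KG1", "ESP")


def _draw_maf(
    rng: np.random.Generator,
    config: SimConfig,
    low: float,
    high: float,
    allow_missing: bool = True,
) -> dict[str, float]:
    """Rare-skewed frequencies: point mass at database-absent, else
    log-uniform over [low, high) in 1-2 random databases."""
    if allow_missing and rng.random() < config.maf_missing_fraction:
        return {}
    freq = float(np.exp(rng.uniform(np.log(low), np.log(high))))
    n_sources = int(rng.integers(1, 3))
    sources = rng.choice(len(_MAF_SOURCES), size=n_sources, replace=False)
    # secondary databases report slightly lower frequencies
    return {
        _MAF_SOURCES[s]: round(freq * (1.0 if j == 0 else 0.6), 8)
        for j, s in enumerate(sorted(sources))
    }


@dataclass
class SimOutput:
    subjects: list[Subject]
    variants: list[AnnotatedVariant]
    gene_sets: list[GeneSet]
    dominant_events: dict[str, set[str]]
    recessive_events: dict[str, set[str]]


def generate(config: SimConfig, out_dir: str | Path | None = None) -> SimOutput:
    """Materialize a full synthetic cohort: phenotypes, variants, gene sets.

    Dominant-model events become single heterozygous variants private to
    one subject with max MAF below 1% (or database-absent); recessive
    events become either a homozygous variant or a compound-heterozygous
    pair, with MAFs in [1%, 10%) so the two models stay independently
    controlled.  Extra proven-in-cis het pairs and assorted non-qualifying
    variants (benign missense, low-impact, common, and batch-recurrent
    calls) are added to exercise every filter.  When ``out_dir`` is given,
    writes ``cohort.tsv``, ``variants.tsv`` and ``sets.gmt``.
    """
    rng = np.random.default_rng(config.seed)
    subjects = generate_cohort(config, rng)
    gene_sets = build_gene_sets(config, rng)
    names = gene_names(config.gene_universe)
    all_ids = [s.subject_id for s in subjects]

    dom_matrix = sample_matrix(config, "dominant", subjects, rng, gene_sets)
    rec_matrix = sample_matrix(config, "recessive", subjects, rng, gene_sets)

    variants: list[AnnotatedVariant] = []
    pos_counter = [1000]

    def next_pos() -> int:
        pos_counter[0] += int(rng.integers(10, 5000))
        return pos_counter[0]

    def hom_ref_map() -> dict[str, str]:
        return {sid: "hom_ref" for sid in all_ids}

    def add_variant(gene: str, gt_map: dict[str, str], maf: dict[str, float],
                    severity: str = "MEDIUM", polyphen: str | None = None,
                    region: str = "coding",
                    phase: dict[str, str] | None = None) -> None:
        if polyphen is None:
            polyphen = "missing" if severity != "MEDIUM" else str(
                rng.choice(["possibly_damaging", "probably_damaging", "missing"])
            )
        chrom = f"chr{1 + sum(gene.encode()) % 22}"  # stable across runs
        variants.append(
            AnnotatedVariant(
                chrom=chrom, pos=next_pos(), ref="A", alt="T", gene=gene,
                region_class=region, severity=severity, polyphen=polyphen,
                maf_by_source=maf, genotypes=gt_map,
                phase_groups=phase or {},
            )
        )

    # the causal gene (already implanted by sample_matrix) is materialized
    # below as one shared variant, not as private background events
    causal = config.causal_gene

    def background_genes(matrix: GeneMutationMatrix, model: str, sid: str):
        genes = sorted(matrix.entries[sid])
        if causal is not None and causal.model == model:
            genes = [g for g in genes if g != causal.gene]
        return genes

    # dominant events: one private qualifying het per (subject, gene)
    for sid in all_ids:
        for gene in background_genes(dom_matrix, "dominant", sid):
            gt = hom_ref_map()
            gt[sid] = "het"
            severity = "HIGH" if rng.random() < 0.1 else "MEDIUM"
            add_variant(gene, gt, _draw_maf(rng, config, 1e-5, 0.009),
                        severity=severity)

    # recessive events: homozygous or compound het, MAF in [1%, 10%)
    for sid in all_ids:
        for gene in background_genes(rec_matrix, "recessive", sid):
            if rng.random() < config.hom_fraction:
                gt = hom_ref_map()
                gt[sid] = "hom_alt"
                add_variant(gene, gt,
                            _draw_maf(rng, config, 0.011, 0.099,
                                      allow_missing=False))
            else:
                for _ in range(2):
                    gt = hom_ref_map()
                    gt[sid] = "het"
                    add_variant(gene, gt,
                                _draw_maf(rng, config, 0.011, 0.099,
                                          allow_missing=False))

    # proven-in-cis compound hets: same phase label, so they must NOT count
    n_cis = rng.poisson(config.recessive_rate * config.in_phase_fraction
                        * len(all_ids))
    for _ in range(n_cis):
        sid = all_ids[int(rng.integers(len(all_ids)))]
        gene = names[int(rng.integers(config.gene_universe))]
        if gene in rec_matrix.entries[sid] or gene in dom_matrix.entries[sid]:
            continue
        label = f"ps{pos_counter[0]}"
        for _ in range(2):
            gt = hom_ref_map()
            gt[sid] = "het"
            add_variant(gene, gt,
                        _draw_maf(rng, config, 0.011, 0.099,
                                  allow_missing=False),
                        phase={sid: label})

    # causal implant, dominant: a shared penetrant missense; recessive: hom.
    # Carriers come from the implanted matrix, keeping both paths consistent.
    if causal is not None:
        matrix = dom_matrix if causal.model == "dominant" else rec_matrix
        carriers = sorted(
            sid for sid, genes in matrix.entries.items()
            if causal.gene in genes
        )
        gt = hom_ref_map()
        for sid in carriers:
            gt[sid] = "het" if causal.model == "dominant" else "hom_alt"
        add_variant(causal.gene, gt, {}, severity="HIGH")

    # chaff: variants every filter should remove
    for _ in range(config.n_chaff):
        gene = names[int(rng.integers(config.gene_universe))]
        carrier = all_ids[int(rng.integers(len(all_ids)))]
        # avoid pairing a chaff het with the carrier's real events, which
        # would create an unplanned compound heterozygote
        if (gene in dom_matrix.entries[carrier]
                or gene in rec_matrix.entries[carrier]):
            continue
        gt = hom_ref_map()
        gt[carrier] = "het"
        kind = rng.random()
        if kind < 0.3:
            add_variant(gene, gt, _draw_maf(rng, config, 1e-4, 0.05),
                        severity="MEDIUM", polyphen="benign")
        elif kind < 0.6:
            add_variant(gene, gt, _draw_maf(rng, config, 1e-4, 0.05),
                        severity="LOW")
        elif kind < 0.8:
            add_variant(gene, gt,
                        _draw_maf(rng, config, 0.10, 0.5, allow_missing=False))
        else:
            # noncoding HIGH passes the severity filter but fails both MAF
            # bounds, exercising the splice-variant path without perturbing
            # the configured matrix rates
            add_variant(gene, gt,
                        _draw_maf(rng, config, 0.011, 0.099,
                                  allow_missing=False),
                        severity="HIGH", region="noncoding")

    # batch-recurrent artifacts: carried by >= 19 subjects of one batch
    for batch in config.batches:
        batch_ids = [s.subject_id for s in subjects if s.batch == batch.label]
        n_rec = min(len(batch_ids), 19)
        gene = names[int(rng.integers(config.gene_universe))]
        gt = hom_ref_map()
        for sid in rng.choice(batch_ids, size=n_rec, replace=False):
            gt[sid] = "het"
        add_variant(gene, gt, {}, severity="HIGH")

    variants.sort(key=lambda v: (v.chrom, v.pos, v.gene))

    out = SimOutput(
        subjects=subjects,
        variants=variants,
        gene_sets=gene_sets,
        dominant_events={s: set(g) for s, g in dom_matrix.entries.items()},
        recessive_events={s: set(g) for s, g in rec_matrix.entries.items()},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(subjects, out_dir / "cohort.tsv")
        write_variants_flat(variants, out_dir / "variants.tsv")
        write_gene_sets_gmt(gene_sets, out_dir / "sets.gmt")
    return out


# ---------------------------------------------------------------------------
# the three-variant worked-example fixture (synthetic reconstruction of the
# published candidate-gene carrier pattern)

WORKED_EXAMPLE_GENE = "TCTN1"


def default_example_cohort() -> list[Subject]:
    """A minimal 33-case / 34-control cohort for the worked example."""
    subjects = []
    for i in range(33):
        subjects.append(
            Subject(f"CASE_{i + 1:02d}", "BILGIN" if i < 17 else "GOAL",
                    "case", "LH", ehi=-80.0, hfli_production=-60.0)
        )
    for i in range(34):
        subjects.append(
            Subject(f"CTRL_{i + 1:02d}", "BILGIN" if i < 22 else "GOAL",
                    "control", "LH" if i < 14 else "RH",
                    ehi=-70.0 if i < 14 else 80.0, hfli_production=60.0)
        )
    return subjects


def implant_worked_example(
    cohort: list[Subject] | None = None,
) -> tuple[list[Subject], list[AnnotatedVariant]]:
    """Synthetic fixture reproducing the published candidate-gene pattern:
    three rare heterozygous TCTN1 variants carried by five distinct cases
    (1, 1 and 3 carriers) and no controls.

    Returns (cohort, variants); a default 33/34 cohort is built when none
    is supplied.
    """
    if cohort is None:
        cohort = default_example_cohort()
    cases = [s.subject_id for s in cohort if s.group == "case"]
    if len(cases) < 5:
        raise ValidationError("worked example needs at least 5 cases")
    all_ids = [s.subject_id for s in cohort]

    def genotypes(carriers: list[str]) -> dict[str, str]:
        gt = {sid: "hom_ref" for sid in all_ids}
        for sid in carriers:
            gt[sid] = "het"
        return gt

    specs = [
        # (pos, ref, alt, maf sources, polyphen, carriers)
        (111_070_349, "GATA", "G", {"KG1": 3.3e-3}, "missing", cases[0:1]),
        (111_078_865, "G", "C", {"ExAC": 8.0e-4}, "possibly_damaging",
         cases[1:2]),
        (111_080_154, "G", "C", {"ExAC": 0.0014, "gnomAD": 0.001199},
         "possibly_damaging", cases[2:5]),
    ]
    variants = [
        AnnotatedVariant(
            chrom="chr12", pos=pos, ref=ref, alt=alt,
            gene=WORKED_EXAMPLE_GENE, region_class="coding",
            severity="MEDIUM", polyphen=pph,
            maf_by_source=maf, genotypes=genotypes(carriers),
        )
        for pos, ref, alt, maf, pph, carriers in specs
    ]
    return cohort, variants


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A scaled-down configuration for replicate-heavy null simulations."""
    cfg = SimConfig(
        gene_universe=2_000,
        dominant_rate=40.0,
        recessive_rate=10.0,
        set_definitions={"probe_set": ("SYN:NULL", 50)},
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg
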