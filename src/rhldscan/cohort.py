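"""Domain types and tabular I/O shared by every analysis stage.

The cohort couples two kinds of records: per-subject phenotypes (group,
handedness, Edinburgh Handedness Inventory score, and hemispheric functional
laterality indices from up to three language-task fMRI contrasts), and
annotated variants carrying a gene symbol, impact severity, PolyPhen class,
per-database minor allele frequencies and per-subject genotypes.

Coordinates are 1-based fully-closed (VCF convention) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")
HANDEDNESS = ("LH", "RH")
SEVERITIES = ("HIGH", "MEDIUM", "LOW", "MODIFIER")
REGION_CLASSES = ("coding", "noncoding")
POLYPHEN_CLASSES = ("benign", "possibly_damaging", "probably_damaging", "missing")
GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")

PHENO_COLUMNS = [
    "subject_id",
    "batch",
    "group",
    "handedness",
    "ehi",
    "hfli_production",
    "hfli_reading",
    "hfli_listening",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class Subject:
    """One study participant.

    ``ehi`` is the Edinburgh Handedness Inventory score in [-100, 100]
    (negative = left-handed).  The three ``hfli_*`` fields are hemispheric
    functional laterality indices (negative = rightward dominance); any may
    be missing (``None``) — one recruitment batch measured production only.
    """

    subject_id: str
    batch: str
    group: str
    handedness: str
    ehi: float | None = None
    hfli_production: float | None = None
    hfli_reading: float | None = None
    hfli_listening: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r} for {self.subject_id}")
        if self.handedness not in HANDEDNESS:
            raise ValidationError(
                f"unknown handedness {self.handedness!r} for {self.subject_id}"
            )
        if not self.batch:
            raise ValidationError(f"subject {self.subject_id} lacks a batch label")


@dataclass
class AnnotatedVariant:
    """One biallelic, gene-assigned variant with its annotations.

    ``maf_by_source`` maps population-database labels (gnomAD, ExAC, 1KG,
    ESP, ...) to allele frequencies; an empty map means the variant was
    absent from every database.  ``genotypes`` maps subject id to one of
    ``GENOTYPES``.  ``phase_groups`` optionally maps subject id to an opaque
    phase label: two heterozygous variants of one subject sharing a label
    were observed on the same sequence read, i.e. proven in cis.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    region_class: str = "coding"
    severity: str = "MEDIUM"
    polyphen: str = "missing"
    maf_by_source: dict[str, float] = field(default_factory=dict)
    genotypes: dict[str, str] = field(default_factory=dict)
    phase_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"position must be >= 1, got {self.pos}")
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(f"unknown region class {self.region_class!r}")
        if self.polyphen not in POLYPHEN_CLASSES:
            raise ValidationError(f"unknown PolyPhen class {self.polyphen!r}")
        for source, freq in self.maf_by_source.items():
            if not 0.0 <= freq <= 1.0:
                raise ValidationError(
                    f"MAF {freq} from {source} outside [0, 1] at "
                    f"{self.chrom}:{self.pos}"
                )

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt, self.gene)

    def carriers(self) -> list[str]:
        """Subjects with at least one observed alternate allele."""
        return [s for s, g in self.genotypes.items() if g in ("het", "hom_alt")]


@dataclass
class GeneMutationMatrix:
    """Boolean subjects x genes matrix: "mutated under model" indicators.

    ``entries`` maps subject id to the set of genes mutated for that subject
    under the named monogenic model (dominant or recessive).  Every cohort
    subject has a row, possibly empty.
    """

    model: str
    entries: dict[str, set[str]]

    def __post_init__(self) -> None:
        if self.model not in ("dominant", "recessive"):
            raise ValidationError(f"unknown model {self.model!r}")

    @property
    def subjects(self) -> list[str]:
        return list(self.entries)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.entries.values():
            out |= gs
        return out

    def genes_per_subject(self) -> dict[str, int]:
        return {s: len(gs) for s, gs in self.entries.items()}

    def subjects_per_gene(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for gs in self.entries.values():
            for g in gs:
                counts[g] = counts.get(g, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.genes)
        data = {
            s: [1 if g in gs else 0 for g in genes]
            for s, gs in self.entries.items()
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=genes)


@dataclass(frozen=True)
class GeneBurdenResult:
    """Per-gene 2x2 case-control burden table and its one-tailed Fisher P.

    a/b = mutated/unmutated cases, c/d = mutated/unmutated controls.
    ``any_control_carrier`` is the post-hoc flag marking genes mutated in at
    least one control (applied after testing so the multiple-testing count
    is unaffected).
    """

    gene: str
    a: int
    b: int
    c: int
    d: int
    p_one_tailed: float
    any_control_carrier: bool

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError(f"negative count in 2x2 table for {self.gene}")
        if not 0.0 < self.p_one_tailed <= 1.0:
            raise ValidationError(f"P outside (0, 1] for {self.gene}")


MIN_SET_SIZE = 10


@dataclass
class GeneSet:
    """A named candidate gene set (e.g. a Gene Ontology term)."""

    name: str
    source_id: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("gene set with empty name")
        self.genes = frozenset(self.genes)

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def eligible(self) -> bool:
        """Sets below 10 genes are excluded from load testing."""
        return self.size >= MIN_SET_SIZE


@dataclass(frozen=True)
class GeneSetLoadResult:
    """Result of an exact-binomial mutational-load test for one gene set.

    ``k_test`` counts mutated-gene instances in the test group, ``n_total``
    over all subjects in the contrast; ``p0`` is the null proportion
    (#test subjects / #subjects in the contrast).
    """

    name: str
    set_size: int
    k_test: int
    n_total: int
    p0: float
    p_binomial: float

    def __post_init__(self) -> None:
        if not 0 <= self.k_test <= self.n_total:
            raise ValidationError(f"k_test outside [0, n_total] for {self.name}")
        if not 0.0 < self.p0 < 1.0:
            raise ValidationError(f"p0 outside (0, 1) for {self.name}")


# ---------------------------------------------------------------------------
# phenotype table


def read_cohort(path: str | Path) -> list[Subject]:
    """Read the tab-separated phenotype table into Subject records.

    Empty cells are missing values; unparseable numeric cells become missing
    with a logged warning.  Duplicate subject ids raise ValidationError.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing_cols = [c for c in PHENO_COLUMNS[:4] if c not in df.columns]
    if missing_cols:
        raise FormatError(f"phenotype table lacks required columns {missing_cols}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject ids {dups}")

    def to_float(cell: object, subject: str, column: str) -> float | None:
        if cell is None or (isinstance(cell, float) and pd.isna(cell)):
            return None
        text = str(cell).strip().replace("−", "-")  # tolerate unicode minus
        if not text:
            return None
        try:
            return float(text)
        except ValueError:
            logger.warning(
                "unparseable %s value %r for subject %s treated as missing",
                column, cell, subject,
            )
            return None

    subjects = []
    for row in df.itertuples(index=False):
        sid = str(row.subject_id).strip()
        subjects.append(
            Subject(
                subject_id=sid,
                batch=str(row.batch).strip(),
                group=str(row.group).strip(),
                handedness=str(row.handedness).strip(),
                ehi=to_float(getattr(row, "ehi", None), sid, "ehi"),
                hfli_production=to_float(
                    getattr(row, "hfli_production", None), sid, "hfli_production"
                ),
                hfli_reading=to_float(
                    getattr(row, "hfli_reading", None), sid, "hfli_reading"
                ),
                hfli_listening=to_float(
                    getattr(row, "hfli_listening", None), sid, "hfli_listening"
                ),
            )
        )
    return subjects


def write_cohort(subjects: Iterable[Subject], path: str | Path) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "batch": s.batch,
                "group": s.group,
                "handedness": s.handedness,
                "ehi": s.ehi,
                "hfli_production": s.hfli_production,
                "hfli_reading": s.hfli_reading,
                "hfli_listening": s.hfli_listening,
            }
        )
    pd.DataFrame(rows, columns=PHENO_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep=""
    )


# ---------------------------------------------------------------------------
# variant tables

_GT_FROM_TEXT = {
    "0/0": "hom_ref", "0|0": "hom_ref",
    "0/1": "het", "1/0": "het", "0|1": "het", "1|0": "het",
    "1/1": "hom_alt", "1|1": "hom_alt",
    "./.": "missing", ".|.": "missing", ".": "missing",
}
_GT_TO_TEXT = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}

FLAT_HEADER_COMMENT = (
    "# variant flat dialect: 1-based fully-closed coordinates (VCF convention); "
    "GT_<subject> in {0/0, 0/1, 1/1, ./.}; PH_<subject> optional phase label"
)


def read_variants(
    path: str | Path,
    dialect: str = "flat_tsv",
    cohort: Iterable[Subject] | None = None,
) -> list[AnnotatedVariant]:
    """Read annotated variants in either the flat TSV dialect or VCF.

    When ``cohort`` is given, every variant's genotype map is completed with
    ``missing`` entries for subjects absent from the file.
    """
    if dialect == "flat_tsv":
        variants = _read_variants_flat(path)
    elif dialect == "vcf":
        variants = _read_variants_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if cohort is not None:
        ids = [s.subject_id for s in cohort]
        for v in variants:
            for sid in ids:
                v.genotypes.setdefault(sid, "missing")
    return variants


def _read_variants_flat(path: str | Path) -> list[AnnotatedVariant]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    fixed = ["chrom", "pos", "ref", "alt", "gene", "region_class", "severity", "polyphen"]
    missing_cols = [c for c in fixed if c not in df.columns]
    if missing_cols:
        raise FormatError(f"variant table lacks columns {missing_cols}")
    maf_cols = [c for c in df.columns if c.startswith("maf_")]
    gt_cols = [c for c in df.columns if c.startswith("GT_")]
    ph_cols = [c for c in df.columns if c.startswith("PH_")]

    variants = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        maf = {}
        for c in maf_cols:
            cell = d[c]
            if cell is not None and not pd.isna(cell) and str(cell).strip():
                maf[c[len("maf_"):]] = float(cell)
        genotypes = {}
        for c in gt_cols:
            cell = d[c]
            text = "./." if cell is None or pd.isna(cell) else str(cell).strip()
            if text not in _GT_FROM_TEXT:
                raise FormatError(f"unrecognized genotype {text!r} in column {c}")
            genotypes[c[len("GT_"):]] = _GT_FROM_TEXT[text]
        phase = {}
        for c in ph_cols:
            cell = d[c]
            if cell is not None and not pd.isna(cell) and str(cell).strip():
                phase[c[len("PH_"):]] = str(cell).strip()
        pph = d["polyphen"]
        variants.append(
            AnnotatedVariant(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                ref=str(d["ref"]),
                alt=str(d["alt"]),
                gene=str(d["gene"]),
                region_class=str(d["region_class"]),
                severity=str(d["severity"]),
                polyphen="missing" if pph is None or pd.isna(pph) else str(pph),
                maf_by_source=maf,
                genotypes=genotypes,
                phase_groups=phase,
            )
        )
    return variants


def write_variants_flat(
    variants: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    variants = list(variants)
    maf_sources = sorted({s for v in variants for s in v.maf_by_source})
    subject_ids = sorted({s for v in variants for s in v.genotypes})
    header = (
        ["chrom", "pos", "ref", "alt", "gene", "region_class", "severity", "polyphen"]
        + [f"maf_{s}" for s in maf_sources]
        + [f"GT_{s}" for s in subject_ids]
        + [f"PH_{s}" for s in subject_ids]
    )
    with open(path, "w") as fh:
        fh.write(FLAT_HEADER_COMMENT + "\n")
        fh.write("\t".join(header) + "\n")
        for v in variants:
            row = [
                v.chrom, str(v.pos), v.ref, v.alt, v.gene,
                v.region_class, v.severity, v.polyphen,
            ]
            row += [
                repr(v.maf_by_source[s]) if s in v.maf_by_source else ""
                for s in maf_sources
            ]
            row += [_GT_TO_TEXT[v.genotypes.get(s, "missing")] for s in subject_ids]
            row += [v.phase_groups.get(s, "") for s in subject_ids]
            fh.write("\t".join(row) + "\n")


def _read_variants_vcf(path: str | Path) -> list[AnnotatedVariant]:
    import pysam

    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"multi-allelic record at {rec.chrom}:{rec.pos}; split and "
                    "normalize upstream (e.g. `bcftools norm -m-`)"
                )
            info = dict(rec.info)
            maf = {
                k[len("MAF_"):]: float(v)
                for k, v in info.items()
                if k.startswith("MAF_")
            }
            genotypes: dict[str, str] = {}
            phase: dict[str, str] = {}
            for sid in samples:
                call = rec.samples[sid]
                alleles = call["GT"]
                if alleles is None or any(a is None for a in alleles):
                    genotypes[sid] = "missing"
                    continue
                n_alt = sum(1 for a in alleles if a == 1)
                genotypes[sid] = ("hom_ref", "het", "hom_alt")[n_alt]
                if call.phased and "PS" in call and call["PS"] is not None:
                    phase[sid] = str(call["PS"])
            variants.append(
                AnnotatedVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    gene=str(info.get("GENE", "")),
                    region_class=str(info.get("REGION", "coding")),
                    severity=str(info.get("SEV", "MODIFIER")),
                    polyphen=str(info.get("PPH", "missing")),
                    maf_by_source=maf,
                    genotypes=genotypes,
                    phase_groups=phase,
                )
            )
    return variants


def write_variants_vcf(
    variants: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    """Write variants as an uncompressed VCF 4.2 text file."""
    variants = list(variants)
    maf_sources = sorted({s for v in variants for s in v.maf_by_source})
    subject_ids = sorted({s for v in variants for s in v.genotypes})
    gt_text = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="coding or noncoding">\n')
        fh.write('##INFO=<ID=SEV,Number=1,Type=String,Description="Impact severity">\n')
        fh.write('##INFO=<ID=PPH,Number=1,Type=String,Description="PolyPhen class">\n')
        for s in maf_sources:
            fh.write(
                f'##INFO=<ID=MAF_{s},Number=1,Type=Float,'
                f'Description="Allele frequency in {s}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        chroms = []
        for v in variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(subject_ids) + "\n"
        )
        phase_ids: dict[str, int] = {}
        for v in variants:
            info = [f"GENE={v.gene}", f"REGION={v.region_class}", f"SEV={v.severity}"]
            if v.polyphen != "missing":
                info.append(f"PPH={v.polyphen}")
            for s, f in sorted(v.maf_by_source.items()):
                info.append(f"MAF_{s}={f:g}")
            cells = []
            for sid in subject_ids:
                gt = gt_text[v.genotypes.get(sid, "missing")]
                if sid in v.phase_groups:
                    label = f"{sid}:{v.phase_groups[sid]}"
                    ps = phase_ids.setdefault(label, len(phase_ids) + 1)
                    cells.append(f"{gt.replace('/', '|')}:{ps}")
                else:
                    cells.append(f"{gt}:.")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                + ";".join(info) + "\tGT:PS\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(path: str | Path, format: str = "gmt") -> list[GeneSet]:
    """Read gene sets from GMT or two-column ``set_name<TAB>gene`` files.

    Duplicate genes within a set are collapsed; duplicate set names raise.
    """
    sets: list[GeneSet] = []
    if format == "gmt":
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"malformed GMT line: {line[:60]!r}")
                name, source_id, *genes = parts
                if not name.strip():
                    raise FormatError("GMT line with empty set name")
                sets.append(
                    GeneSet(
                        name=name.strip(),
                        source_id=source_id.strip(),
                        genes=frozenset(g.strip() for g in genes if g.strip()),
                    )
                )
    elif format == "two_column":
        grouped: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(f"expected two columns, got {line[:60]!r}")
                name, gene = (p.strip() for p in parts)
                if not name:
                    raise FormatError("row with empty set name")
                grouped.setdefault(name, set()).add(gene)
        sets = [
            GeneSet(name=n, source_id="", genes=frozenset(g))
            for n, g in grouped.items()
        ]
    else:
        raise ValueError(f"unknown gene-set format {format!r}")

    names = [s.name for s in sets]
    if len(names) != len(set(names)):
        raise ValidationError("duplicate gene-set names in collection")
    return sets


def write_gene_sets_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.source_id] + sorted(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# mutation matrices


def write_matrix(matrix: GeneMutationMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = f"subject_id:{matrix.model}"
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> GeneMutationMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    index_name = df.index.name or ""
    if ":" not in index_name:
        raise FormatError("matrix file lacks the subject_id:<model> index header")
    model = index_name.split(":", 1)[1]
    entries = {
        str(sid): {g for g in df.columns if df.at[sid, g] == 1} for sid in df.index
    }
    return GeneMutationMatrix(model=model, entries=entries)


def split_groups(
    subjects: Iterable[Subject],
) -> tuple[list[Subject], list[Subject]]:
    """Return (cases, controls)."""
    subjects = list(subjects)
    return (
        [s for s in subjects if s.group == "case"],
        [s for s in subjects if s.group == "control"],
    )
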