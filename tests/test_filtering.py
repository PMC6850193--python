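"""Annotation filters, monogenic models, and the brute-force matrix oracle."""

import itertools

import numpy as np
import pytest

from rhldscan import filtering as flt
from rhldscan.cohort import AnnotatedVariant, Subject, ValidationError


def variant(gene="G1", pos=100, severity="MEDIUM", region="coding",
            polyphen="missing", maf=None, genotypes=None, phase=None):
    return AnnotatedVariant(
        chrom="chr1", pos=pos, ref="A", alt="T", gene=gene,
        region_class=region, severity=severity, polyphen=polyphen,
        maf_by_source=maf or {}, genotypes=genotypes or {},
        phase_groups=phase or {},
    )


class TestMaxMaf:
    def test_maximum_across_sources(self):
        v = variant(maf={"gnomAD": 0.0008, "ExAC": 0.0014})
        assert flt.max_maf(v) == 0.0014

    def test_no_sources_is_missing(self):
        assert flt.max_maf(variant(maf={})) is None

    def test_single_source(self):
        assert flt.max_maf(variant(maf={"ESP": 0.2})) == 0.2


class TestSeverityFilter:
    CASES = [
        (dict(severity="MEDIUM", region="coding", polyphen="benign"), False),
        (dict(severity="MEDIUM", region="coding", polyphen="possibly_damaging"), True),
        (dict(severity="MEDIUM", region="coding", polyphen="missing"), True),
        (dict(severity="HIGH", region="coding", polyphen="benign"), True),
        (dict(severity="HIGH", region="noncoding"), True),   # splice-level
        (dict(severity="MEDIUM", region="noncoding"), False),
        (dict(severity="LOW", region="coding"), False),
        (dict(severity="MODIFIER", region="coding"), False),
    ]

    @pytest.mark.parametrize("kw, kept", CASES)
    def test_retention_rule(self, kw, kept):
        assert bool(flt.severity_filter([variant(**kw)])) is kept

    def test_idempotent(self):
        vs = [variant(**kw) for kw, _ in self.CASES]
        once = flt.severity_filter(vs)
        assert flt.severity_filter(once) == once


class TestCohortPresence:
    def _variant_with_carriers(self, ids):
        return variant(genotypes={s: "het" for s in ids})

    def test_nineteen_in_batch_removed_eighteen_kept(self):
        batch_map = {f"S{i}": "BILGIN" for i in range(39)}
        v19 = self._variant_with_carriers([f"S{i}" for i in range(19)])
        v18 = self._variant_with_carriers([f"S{i}" for i in range(18)])
        kept = flt.cohort_presence_filter([v19, v18], batch_map)
        assert kept == [v18]

    def test_applied_per_batch_not_pooled(self):
        """19 carriers split across batches (<=18 within each) survive."""
        batch_map = {f"A{i}": "BILGIN" for i in range(10)}
        batch_map.update({f"B{i}": "GOAL" for i in range(9)})
        v = self._variant_with_carriers(list(batch_map))
        assert flt.cohort_presence_filter([v], batch_map) == [v]

    def test_idempotent(self):
        batch_map = {f"S{i}": "X" for i in range(30)}
        vs = [
            self._variant_with_carriers([f"S{i}" for i in range(n)])
            for n in (5, 18, 19, 25)
        ]
        once = flt.cohort_presence_filter(vs, batch_map)
        assert flt.cohort_presence_filter(once, batch_map) == once


class TestDominantModel:
    def test_rare_het_counts(self):
        vs = [variant(gene="TCTN1", maf={"ExAC": 0.0014},
                      genotypes={"S1": "het"})]
        assert "TCTN1" in flt.dominant_mutated_genes("S1", vs)

    def test_common_variant_excluded(self):
        vs = [variant(maf={"ExAC": 0.02}, genotypes={"S1": "het"})]
        assert flt.dominant_mutated_genes("S1", vs) == set()

    def test_missing_maf_retained(self):
        vs = [variant(maf={}, genotypes={"S1": "het"})]
        assert flt.dominant_mutated_genes("S1", vs) == {"G1"}

    def test_homozygous_also_counts(self):
        vs = [variant(maf={"ExAC": 0.001}, genotypes={"S1": "hom_alt"})]
        assert flt.dominant_mutated_genes("S1", vs) == {"G1"}

    def test_missing_genotype_treated_as_reference(self):
        vs = [variant(maf={}, genotypes={"S1": "missing"})]
        assert flt.dominant_mutated_genes("S1", vs) == set()

    def test_raising_maf_bound_only_adds_genes(self):
        rng = np.random.default_rng(7)
        vs = [
            variant(gene=f"G{i}", pos=100 + i,
                    maf={"x": float(rng.uniform(0, 0.05))} if rng.random() > 0.3 else {},
                    genotypes={"S1": "het"})
            for i in range(40)
        ]
        bounds = [0.001, 0.005, 0.01, 0.02, 0.05]
        results = [
            flt.dominant_mutated_genes(
                "S1", vs, flt.FilterConfig(dominant_maf_max=b,
                                           recessive_maf_max=0.10))
            for b in bounds
        ]
        for smaller, larger in zip(results, results[1:]):
            assert smaller <= larger


class TestRecessiveModel:
    def test_homozygous_single_variant(self):
        vs = [variant(maf={"x": 0.05}, genotypes={"S1": "hom_alt"})]
        assert flt.recessive_mutated_genes("S1", vs) == {"G1"}

    def test_common_homozygote_excluded(self):
        vs = [variant(maf={"x": 0.10}, genotypes={"S1": "hom_alt"})]
        assert flt.recessive_mutated_genes("S1", vs) == set()

    def test_compound_het_phase_unknown(self):
        vs = [
            variant(pos=100, maf={"x": 0.05}, genotypes={"S1": "het"}),
            variant(pos=200, maf={}, genotypes={"S1": "het"}),
        ]
        assert flt.recessive_mutated_genes("S1", vs) == {"G1"}

    def test_single_het_insufficient(self):
        vs = [variant(maf={"x": 0.05}, genotypes={"S1": "het"})]
        assert flt.recessive_mutated_genes("S1", vs) == set()

    def test_proven_cis_pair_discarded(self):
        vs = [
            variant(pos=100, maf={"x": 0.05}, genotypes={"S1": "het"},
                    phase={"S1": "read7"}),
            variant(pos=200, maf={"x": 0.05}, genotypes={"S1": "het"},
                    phase={"S1": "read7"}),
        ]
        assert flt.recessive_mutated_genes("S1", vs) == set()

    def test_third_unphased_variant_rescues_gene(self):
        """Two proven-cis variants plus one unphased: a trans pair exists."""
        vs = [
            variant(pos=100, maf={"x": 0.05}, genotypes={"S1": "het"},
                    phase={"S1": "read7"}),
            variant(pos=200, maf={"x": 0.05}, genotypes={"S1": "het"},
                    phase={"S1": "read7"}),
            variant(pos=300, maf={"x": 0.05}, genotypes={"S1": "het"}),
        ]
        assert flt.recessive_mutated_genes("S1", vs) == {"G1"}

    def test_different_phase_groups_not_proven_cis(self):
        vs = [
            variant(pos=100, maf={"x": 0.05}, genotypes={"S1": "het"},
                    phase={"S1": "a"}),
            variant(pos=200, maf={"x": 0.05}, genotypes={"S1": "het"},
                    phase={"S1": "b"}),
        ]
        assert flt.recessive_mutated_genes("S1", vs) == {"G1"}


# ---------------------------------------------------------------------------
# brute-force oracle for the whole filter chain + matrix construction


def oracle_mutated(sid, gene, variants, model, cfg, batch_map):
    """Direct restatement of the rules for one (subject, gene) pair."""

    def severity_ok(v):
        if v.region_class == "coding":
            if v.severity == "HIGH":
                return True
            return v.severity == "MEDIUM" and v.polyphen != "benign"
        return v.severity == "HIGH"

    def presence_ok(v):
        for batch in set(batch_map.values()):
            n = sum(
                1 for s, g in v.genotypes.items()
                if batch_map.get(s) == batch and g in ("het", "hom_alt")
            )
            if n >= cfg.cohort_presence_max:
                return False
        return True

    def maf_ok(v, bound):
        if not v.maf_by_source:
            return cfg.keep_missing_maf
        return max(v.maf_by_source.values()) < bound

    usable = [
        v for v in variants
        if v.gene == gene and severity_ok(v) and presence_ok(v)
    ]
    if model == "dominant":
        return any(
            v.genotypes.get(sid) in ("het", "hom_alt")
            and maf_ok(v, cfg.dominant_maf_max)
            for v in usable
        )
    qual = [v for v in usable if maf_ok(v, cfg.recessive_maf_max)]
    if any(v.genotypes.get(sid) == "hom_alt" for v in qual):
        return True
    hets = {v.key: v for v in qual if v.genotypes.get(sid) == "het"}.values()
    for v1, v2 in itertools.combinations(hets, 2):
        p1, p2 = v1.phase_groups.get(sid), v2.phase_groups.get(sid)
        proven_cis = p1 is not None and p1 == p2
        if not proven_cis:
            return True
    return False


def random_instance(rng):
    n_subj = int(rng.integers(2, 6))
    subjects = [
        Subject(f"S{i}", rng.choice(["B1", "B2"]),
                str(rng.choice(["case", "control"])), "LH",
                hfli_production=-60.0)
        for i in range(n_subj)
    ]
    ids = [s.subject_id for s in subjects]
    variants = []
    for j in range(int(rng.integers(1, 11))):
        maf = {}
        if rng.random() > 0.3:
            maf = {"db": float(rng.choice([0.0005, 0.005, 0.05, 0.15]))}
        genotypes = {
            sid: str(rng.choice(
                ["hom_ref", "het", "hom_alt", "missing"],
                p=[0.35, 0.4, 0.15, 0.1]))
            for sid in ids
        }
        phase = {
            sid: str(rng.choice(["p1", "p2"]))
            for sid in ids
            if genotypes[sid] == "het" and rng.random() < 0.3
        }
        variants.append(variant(
            gene=f"G{int(rng.integers(1, 4))}", pos=100 + j,
            severity=str(rng.choice(["HIGH", "MEDIUM", "LOW"])),
            region=str(rng.choice(["coding", "noncoding"], p=[0.8, 0.2])),
            polyphen=str(rng.choice(["benign", "possibly_damaging", "missing"])),
            maf=maf, genotypes=genotypes, phase=phase,
        ))
    return subjects, variants


@pytest.mark.parametrize("model", ["dominant", "recessive"])
def test_matrix_matches_brute_force_on_small_instances(model):
    """Filter chain + matrix equals direct rule enumeration, 60 random cases."""
    rng = np.random.default_rng(2024)
    cfg = flt.FilterConfig(cohort_presence_max=3)
    for _ in range(60):
        subjects, variants = random_instance(rng)
        batch_map = {s.subject_id: s.batch for s in subjects}
        prepared = flt.prepare_variants(variants, subjects, cfg)
        matrix = flt.build_matrix(subjects, prepared, model, cfg)
        genes = {v.gene for v in variants}
        for s in subjects:
            for g in genes:
                expected = oracle_mutated(
                    s.subject_id, g, variants, model, cfg, batch_map)
                assert (g in matrix.entries[s.subject_id]) == expected, (
                    f"{model} mismatch for {s.subject_id}/{g}")


def test_matrix_covers_every_subject_and_warns_on_no_data(caplog):
    subjects = [
        Subject("S1", "B", "case", "LH", hfli_production=-60.0),
        Subject("S2", "B", "control", "RH", hfli_production=60.0),
    ]
    vs = [variant(maf={}, genotypes={"S1": "het", "S2": "missing"})]
    with caplog.at_level("WARNING"):
        m = flt.build_matrix(subjects, vs, "dominant")
    assert m.entries == {"S1": {"G1"}, "S2": set()}
    assert "S2" in caplog.text


def test_empty_variant_list_gives_all_false_matrix():
    subjects = [Subject("S1", "B", "case", "LH")]
    m = flt.build_matrix(subjects, [], "recessive")
    assert m.entries == {"S1": set()}


def test_filter_config_invariants():
    with pytest.raises(ValidationError):
        flt.FilterConfig(dominant_maf_max=0.2, recessive_maf_max=0.1)
    with pytest.raises(ValidationError):
        flt.FilterConfig(cohort_presence_max=1)
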