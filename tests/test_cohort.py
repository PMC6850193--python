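"""I/O round trips and validation for the shared domain types."""

import pytest

from rhldscan import cohort as cm


def make_subject(i, group="case", **kw):
    defaults = dict(
        subject_id=f"S{i}", batch="BILGIN", group=group, handedness="LH",
        ehi=-87.5, hfli_production=-58.0, hfli_reading=-61.0,
        hfli_listening=-59.0,
    )
    defaults.update(kw)
    return cm.Subject(**defaults)


class TestCohortTable:
    def test_round_trip_field_by_field(self, tmp_path):
        subjects = [
            make_subject(1),
            make_subject(2, group="control", handedness="RH", ehi=76.39,
                         hfli_production=61.0, hfli_reading=None,
                         hfli_listening=None),
            make_subject(3, batch="GOAL", ehi=None),
        ]
        path = tmp_path / "cohort.tsv"
        cm.write_cohort(subjects, path)
        assert cm.read_cohort(path) == subjects

    def test_full_row_parses(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            "subject_id\tbatch\tgroup\thandedness\tehi\thfli_production\t"
            "hfli_reading\thfli_listening\n"
            "S1\tBILGIN\tcase\tLH\t−87.5\t-58\t-61\t-59\n"
        )
        (s,) = cm.read_cohort(path)
        assert s.ehi == -87.5 and s.hfli_production == -58.0
        assert s.group == "case" and s.batch == "BILGIN"

    def test_empty_cells_become_missing(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            "subject_id\tbatch\tgroup\thandedness\tehi\thfli_production\t"
            "hfli_reading\thfli_listening\n"
            "S1\tGOAL\tcase\tLH\t-100\t-77\t\t\n"
        )
        (s,) = cm.read_cohort(path)
        assert s.hfli_reading is None and s.hfli_listening is None
        assert s.hfli_production == -77.0

    def test_unparseable_number_warns_and_is_missing(self, tmp_path, caplog):
        path = tmp_path / "c.tsv"
        path.write_text(
            "subject_id\tbatch\tgroup\thandedness\tehi\thfli_production\t"
            "hfli_reading\thfli_listening\n"
            "S1\tGOAL\tcase\tLH\tnot_a_number\t-77\t\t\n"
        )
        with caplog.at_level("WARNING"):
            (s,) = cm.read_cohort(path)
        assert s.ehi is None
        assert "unparseable" in caplog.text

    def test_duplicate_subject_id_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            "subject_id\tbatch\tgroup\thandedness\tehi\thfli_production\t"
            "hfli_reading\thfli_listening\n"
            "S1\tGOAL\tcase\tLH\t-100\t-77\t\t\n"
            "S1\tGOAL\tcase\tLH\t-90\t-60\t\t\n"
        )
        with pytest.raises(cm.ValidationError, match="duplicate"):
            cm.read_cohort(path)

    def test_missing_required_column_rejected(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("subject_id\tbatch\tgroup\nS1\tGOAL\tcase\n")
        with pytest.raises(cm.FormatError, match="handedness"):
            cm.read_cohort(path)


def make_variant(**kw):
    defaults = dict(
        chrom="chr12", pos=111_080_154, ref="G", alt="C", gene="TCTN1",
        region_class="coding", severity="MEDIUM", polyphen="possibly_damaging",
        maf_by_source={"ExAC": 0.0014, "gnomAD": 0.0008},
        genotypes={"S1": "het", "S2": "hom_ref"},
    )
    defaults.update(kw)
    return cm.AnnotatedVariant(**defaults)


class TestVariantTables:
    def test_flat_round_trip(self, tmp_path):
        variants = [
            make_variant(),
            make_variant(pos=500, gene="DNAH5", severity="HIGH",
                         polyphen="missing", maf_by_source={},
                         genotypes={"S1": "hom_alt", "S2": "missing"},
                         phase_groups={"S1": "ps1"}),
        ]
        path = tmp_path / "v.tsv"
        cm.write_variants_flat(variants, path)
        assert cm.read_variants(path, "flat_tsv") == variants

    def test_vcf_round_trip(self, tmp_path):
        variants = [
            make_variant(genotypes={"S1": "het", "S2": "hom_ref"}),
            make_variant(pos=500, gene="DNAH5", region_class="noncoding",
                         severity="HIGH", polyphen="missing",
                         maf_by_source={},
                         genotypes={"S1": "hom_alt", "S2": "het"},
                         phase_groups={"S2": "a"}),
        ]
        path = tmp_path / "v.vcf"
        cm.write_variants_vcf(variants, path)
        back = cm.read_variants(path, "vcf")
        for orig, rt in zip(variants, back):
            assert (rt.chrom, rt.pos, rt.ref, rt.alt) == (
                orig.chrom, orig.pos, orig.ref, orig.alt)
            assert rt.gene == orig.gene
            assert rt.severity == orig.severity
            assert rt.polyphen == orig.polyphen
            assert rt.region_class == orig.region_class
            assert rt.genotypes == orig.genotypes
            assert set(rt.phase_groups) == set(orig.phase_groups)
            for src, f in orig.maf_by_source.items():
                assert rt.maf_by_source[src] == pytest.approx(f)

    def test_multiallelic_vcf_rejected(self, tmp_path):
        path = tmp_path / "v.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=GENE,Number=1,Type=String,Description="g">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tT,G\t.\tPASS\tGENE=X\tGT\t0/1\n"
        )
        with pytest.raises(cm.FormatError, match="split"):
            cm.read_variants(path, "vcf")

    def test_position_below_one_rejected(self):
        with pytest.raises(cm.FormatError, match="position"):
            make_variant(pos=0)

    def test_maf_outside_unit_interval_rejected(self):
        with pytest.raises(cm.ValidationError):
            make_variant(maf_by_source={"ExAC": 1.5})

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "v.tsv"
        cm.write_variants_flat([], path)
        assert cm.read_variants(path, "flat_tsv") == []

    def test_genotype_map_completed_from_cohort(self, tmp_path):
        cohort = [make_subject(i) for i in (1, 2, 3)]
        path = tmp_path / "v.tsv"
        cm.write_variants_flat([make_variant()], path)
        (v,) = cm.read_variants(path, "flat_tsv", cohort=cohort)
        assert set(v.genotypes) == {"S1", "S2", "S3"}
        assert v.genotypes["S3"] == "missing"


class TestGeneSets:
    def test_gmt_parse_and_eligibility(self, tmp_path):
        genes = [f"GENE{i}" for i in range(205)]
        path = tmp_path / "sets.gmt"
        path.write_text(
            "actin_cytoskeleton\tGO:0015629\t" + "\t".join(genes) + "\n"
            "tiny\tGO:0000009\t" + "\t".join(genes[:9]) + "\n"
            "dupped\tGO:0000010\t" + "\t".join(genes[:10] + genes[:5]) + "\n"
        )
        sets = {s.name: s for s in cm.read_gene_sets(path, "gmt")}
        assert sets["actin_cytoskeleton"].size == 205
        assert sets["actin_cytoskeleton"].eligible
        assert sets["tiny"].size == 9 and not sets["tiny"].eligible
        # a gene listed twice counts once
        assert sets["dupped"].size == 10 and sets["dupped"].eligible

    def test_two_column_format(self, tmp_path):
        path = tmp_path / "sets.tsv"
        path.write_text("".join(f"mySet\tG{i}\n" for i in range(12)))
        (s,) = cm.read_gene_sets(path, "two_column")
        assert s.name == "mySet" and s.size == 12 and s.eligible

    def test_empty_set_name_rejected(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("\tGO:1\tA\tB\n")
        with pytest.raises(cm.FormatError, match="empty set name"):
            cm.read_gene_sets(path, "gmt")

    def test_gmt_round_trip(self, tmp_path):
        sets = [
            cm.GeneSet("alpha", "GO:1", frozenset({"A", "B", "C"})),
            cm.GeneSet("beta", "SRC:2", frozenset(f"G{i}" for i in range(11))),
        ]
        path = tmp_path / "sets.gmt"
        cm.write_gene_sets_gmt(sets, path)
        back = {s.name: s for s in cm.read_gene_sets(path, "gmt")}
        for s in sets:
            assert back[s.name].genes == s.genes
            assert back[s.name].source_id == s.source_id


class TestMatrix:
    def test_round_trip_and_derived_counts(self, tmp_path):
        m = cm.GeneMutationMatrix(
            model="dominant",
            entries={"S1": {"A", "B"}, "S2": {"B"}, "S3": set()},
        )
        path = tmp_path / "m.tsv"
        cm.write_matrix(m, path)
        back = cm.read_matrix(path)
        assert back.model == "dominant"
        assert back.entries == m.entries
        assert back.genes_per_subject() == {"S1": 2, "S2": 1, "S3": 0}
        assert back.subjects_per_gene() == {"A": 1, "B": 2}

    def test_burden_result_invariants(self):
        with pytest.raises(cm.ValidationError):
            cm.GeneBurdenResult("X", -1, 3, 0, 4, 0.5, False)
        with pytest.raises(cm.ValidationError):
            cm.GeneBurdenResult("X", 1, 3, 0, 4, 0.0, False)
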