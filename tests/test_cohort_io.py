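import numpy as np
import pytest

from acmgsf import cohort_io
from acmgsf.cohort_io import (
    DB_NAMES,
    GenotypeMatrix,
    PhenotypeRecord,
    SampleRecord,
    VariantRecord,
)
from acmgsf.errors import (
    AnnotationError,
    KinshipBoundsError,
    SampleMismatchError,
    UnsortedVCFError,
    VocabularyError,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
)


def _samples_tsv(tmp_path, ids=("A", "B", "C")):
    path = tmp_path / "samples.tsv"
    path.write_text(
        "sample_id\tsubpopulation\n" + "".join(f"{i}\tGAR\n" for i in ids)
    )
    return path


def test_gt_decoding_het_hom_missing(tmp_path):
    vcf = tmp_path / "c.vcf"
    vcf.write_text(VCF_HEADER + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\t./.\n")
    matrix, stubs, samples = cohort_io.read_cohort(vcf, _samples_tsv(tmp_path))
    assert [s.subpopulation for s in samples] == ["GAR"] * 3
    assert stubs[0].key == ("1", 99, "A", "G")  # 0-based internally
    assert list(matrix.dosages(stubs[0].key)) == [1, 2, -1]


def test_multiallelic_site_splits_into_one_record_per_alt(tmp_path):
    vcf = tmp_path / "c.vcf"
    vcf.write_text(VCF_HEADER + "1\t100\t.\tC\tA,G\t.\tPASS\t.\tGT\t1/2\t0/2\t0/0\n")
    matrix, stubs, _ = cohort_io.read_cohort(vcf, _samples_tsv(tmp_path))
    assert [(s.ref, s.alt) for s in stubs] == [("C", "A"), ("C", "G")]
    assert list(matrix.dosages(("1", 99, "C", "A"))) == [1, 0, 0]
    assert list(matrix.dosages(("1", 99, "C", "G"))) == [1, 1, 0]


def test_unsorted_vcf_rejected(tmp_path):
    vcf = tmp_path / "c.vcf"
    vcf.write_text(
        VCF_HEADER
        + "1\t200\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
    )
    with pytest.raises(UnsortedVCFError):
        cohort_io.read_cohort(vcf, _samples_tsv(tmp_path))


def test_sample_table_not_subset_of_vcf_rejected(tmp_path):
    vcf = tmp_path / "c.vcf"
    vcf.write_text(VCF_HEADER + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n")
    with pytest.raises(SampleMismatchError, match="ZZZ"):
        cohort_io.read_cohort(vcf, _samples_tsv(tmp_path, ids=("A", "ZZZ")))


def test_vcf_write_read_round_trip_preserves_dosages(tmp_path):
    rng = np.random.default_rng(42)
    samples = [f"P{i:02d}" for i in range(20)]
    variants = []
    used = set()
    for _ in range(50):
        pos = int(rng.integers(1, 10_000))
        while pos in used:
            pos += 1
        used.add(pos)
        variants.append(VariantRecord(chrom="1", pos=pos, ref="A", alt="T"))
    variants.sort(key=lambda v: v.pos)
    calls = rng.choice([0, 1, 2, -1], size=(20, 50), p=[0.7, 0.15, 0.1, 0.05]).astype(np.int8)
    matrix = GenotypeMatrix(samples, [v.key for v in variants], calls)

    cohort_io.write_vcf(tmp_path / "rt.vcf", variants, matrix)
    cohort_io.write_samples(
        tmp_path / "s.tsv", [SampleRecord(s, "WEP") for s in samples]
    )
    matrix2, stubs2, _ = cohort_io.read_cohort(tmp_path / "rt.vcf", tmp_path / "s.tsv")
    assert [s.key for s in stubs2] == [v.key for v in variants]
    assert np.array_equal(matrix2.calls, matrix.calls)


def _annot_line(v: VariantRecord, flags=None, cadd=24.5, gerp=5.79):
    flags = flags or {}
    cols = [v.chrom, str(v.pos + 1), v.ref, v.alt, "DSP", "missense_variant",
            "MODERATE", str(cadd), str(gerp)]
    cols += [str(int(flags.get(name, False))) for name in DB_NAMES]
    return "\t".join(cols)


ANNOT_HEADER = "\t".join(
    ["chrom", "pos", "ref", "alt", "gene", "effect", "impact", "cadd", "gerp", *DB_NAMES]
)


def test_attach_annotations_populates_all_fields(tmp_path):
    stub = VariantRecord("6", 5_000_100, "A", "G")
    tsv = tmp_path / "ann.tsv"
    tsv.write_text(ANNOT_HEADER + "\n" + _annot_line(stub) + "\n")
    (record,) = cohort_io.attach_annotations([stub], tsv)
    assert record.cadd == 24.5 and record.gerp == 5.79
    assert record.gene == "DSP" and record.impact == "MODERATE"
    assert set(record.db_membership) == set(DB_NAMES)
    assert not any(record.db_membership.values())  # novel-eligible


def test_attach_annotations_carries_membership(tmp_path):
    stub = VariantRecord("6", 5_000_100, "A", "G")
    tsv = tmp_path / "ann.tsv"
    tsv.write_text(ANNOT_HEADER + "\n" + _annot_line(stub, flags={"dbsnp": True}) + "\n")
    (record,) = cohort_io.attach_annotations([stub], tsv)
    assert record.db_membership["dbsnp"] is True


def test_missing_annotation_row_names_the_variant(tmp_path):
    stub = VariantRecord("6", 5_000_100, "A", "G")
    other = VariantRecord("6", 5_000_200, "C", "T")
    tsv = tmp_path / "ann.tsv"
    tsv.write_text(ANNOT_HEADER + "\n" + _annot_line(other) + "\n")
    with pytest.raises(AnnotationError, match="5000101"):
        cohort_io.attach_annotations([stub], tsv)


def test_duplicate_annotation_row_rejected(tmp_path):
    stub = VariantRecord("6", 5_000_100, "A", "G")
    tsv = tmp_path / "ann.tsv"
    tsv.write_text(ANNOT_HEADER + "\n" + _annot_line(stub) + "\n" + _annot_line(stub) + "\n")
    with pytest.raises(AnnotationError, match="duplicate"):
        cohort_io.attach_annotations([stub], tsv)


PHENO_HEADER = "sample_id\tecg\tchest_pain\tparental_heart_disease\tself_reported_conditions\n"


def test_phenotype_ecg_case_folding_and_missing(tmp_path):
    tsv = tmp_path / "ph.tsv"
    tsv.write_text(PHENO_HEADER + "A\tAbnormal\t0\t1\t\nB\t\t1\t0\tAngina; heart attack\n")
    records = cohort_io.read_phenotypes(tsv)
    assert records[0].ecg == "abnormal" and records[0].parental_heart_disease
    assert records[1].ecg == "missing"
    assert records[1].self_reported_conditions == frozenset({"angina", "heart attack"})


def test_phenotype_vocabulary_violation_rejected(tmp_path):
    tsv = tmp_path / "ph.tsv"
    tsv.write_text(PHENO_HEADER + "A\tweird\t0\t0\t\n")
    with pytest.raises(VocabularyError):
        cohort_io.read_phenotypes(tsv)


KIN_HEADER = "sample_a\tsample_b\tphi\n"


def test_kinship_symmetric_edge(tmp_path):
    tsv = tmp_path / "k.tsv"
    tsv.write_text(KIN_HEADER + "A\tB\t0.25\n")
    g = cohort_io.read_kinship(tsv)
    assert g["B"]["A"]["phi"] == 0.25


def test_kinship_bounds_and_self_pair_rejected(tmp_path):
    tsv = tmp_path / "k.tsv"
    tsv.write_text(KIN_HEADER + "A\tB\t0.7\n")
    with pytest.raises(KinshipBoundsError):
        cohort_io.read_kinship(tsv)
    tsv.write_text(KIN_HEADER + "A\tA\t0.25\n")
    with pytest.raises(KinshipBoundsError):
        cohort_io.read_kinship(tsv)


def test_kinship_unknown_sample_rejected(tmp_path):
    tsv = tmp_path / "k.tsv"
    tsv.write_text(KIN_HEADER + "A\tB\t0.25\n")
    with pytest.raises(SampleMismatchError):
        cohort_io.read_kinship(tsv, known_samples={"A"})


def test_phenotype_and_kinship_round_trip(tmp_path):
    records = [
        PhenotypeRecord("A", "borderline", True, False, frozenset({"angina"})),
        PhenotypeRecord("B", "missing", False, True, frozenset()),
    ]
    cohort_io.write_phenotypes(tmp_path / "ph.tsv", records)
    assert cohort_io.read_phenotypes(tmp_path / "ph.tsv") == records

    import networkx as nx

    g = nx.Graph()
    g.add_edge("A", "B", phi=0.125)
    g.add_edge("A", "C", phi=0.25)
    cohort_io.write_kinship(tmp_path / "k.tsv", g)
    g2 = cohort_io.read_kinship(tmp_path / "k.tsv")
    assert {frozenset(e) for e in g2.edges} == {frozenset(e) for e in g.edges}
    assert g2["A"]["B"]["phi"] == 0.125


def test_variant_record_rejects_ref_equal_alt():
    with pytest.raises(ValueError):
        VariantRecord("1", 5, "A", "A")
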