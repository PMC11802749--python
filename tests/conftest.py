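import pytest

from varcurate.fixtures import (
    GeneratorSpec,
    generate_cohort_vcf,
    generate_random_vcf,
    load_cohort_fixture,
    load_gene_panel,
)

MINI_VCF = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total Depth">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | cDNA.pos / cDNA.length | CDS.pos / CDS.length | AA.pos / AA.length | Distance | ERRORS / WARNINGS / INFO'">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\trs1\tA\tG\t50\tPASS\tDP=10;AF=0.5\tGT:DP\t0/1:12\t0/0:9
1\t200\t.\tC\tT,G\t.\tPASS\tDP=20;AF=0.25,0.1;ANN=T|missense_variant|MODERATE|TTN|ENSG00000155657|transcript|T1|protein_coding||||||||\tGT:DP\t1/2:7\t./.:.
2\t300\trs3\tG\tC\t9.5\tq10\tAF=0.9\tGT:DP\t1|1:30\t0|1:22
"""


@pytest.fixture
def mini_vcf(tmp_path):
    path = tmp_path / "mini.vcf"
    path.write_text(MINI_VCF)
    return path


@pytest.fixture(scope="session")
def gene_panel():
    return load_gene_panel()


@pytest.fixture(scope="session")
def cohort_fixture():
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def cohort_vcf(tmp_path_factory):
    """Seeded 96-sample synthetic cohort with 4 decoy records."""
    out = tmp_path_factory.mktemp("cohort") / "cohort.vcf"
    path, truth = generate_cohort_vcf(out, GeneratorSpec(seed=11, n_decoy_variants=4))
    return path, truth


@pytest.fixture(scope="session")
def random_vcf(tmp_path_factory):
    """Random 30-record, 4-sample VCF with 7 panel-gene records planted."""
    out = tmp_path_factory.mktemp("random") / "random.vcf"
    path, truth = generate_random_vcf(
        out, GeneratorSpec(seed=7, n_records=30, n_samples=4, n_panel_records=7)
    )
    return path, truth
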