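"""Packaged reference fixtures and seeded synthetic-data generators.

Two curated fixtures ship with the package (tab-delimited, checksummed):

* a cardiovascular **gene panel** — 136 gene entries with their literature
  rsIDs, split between atrial fibrillation (AF) and heart failure (HF);
* a triaged **cohort table** — 16 clinically significant variants with
  their carrier frequency in a 96-sample cohort, the raw ClinVar-style
  assertion, the associated disease text, and the case study (AF/HF)
  each variant was reported under.

The generators emit synthetic multi-sample cohort VCFs, random VCFs and
mini annotation databases together with a *truth table* of every planted
fact, so downstream filtering/annotation/extraction can be tested
against known ground truth without any external downloads.  The same
spec and seed always produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from varcurate.errors import ConfigError, FormatError
from varcurate.vcf_io import FLAG, PathLike, VariantRecord, VcfHeader, write_vcf

ANN_DESCRIPTION = (
    "Functional annotations: 'Allele | Annotation | Annotation_Impact | "
    "Gene_Name | Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | "
    "Rank | HGVS.c | HGVS.p | cDNA.pos / cDNA.length | CDS.pos / CDS.length | "
    "AA.pos / AA.length | Distance | ERRORS / WARNINGS / INFO'"
)

_BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# packaged fixtures


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    rsids: tuple[str, ...]
    disease: str  # "AF" | "HF"


@dataclass
class GenePanel:
    """The curated gene–variant–disease panel."""

    entries: list[PanelEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def entries_for(self, disease: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.disease == disease]

    @property
    def gene_symbols(self) -> set[str]:
        return {e.gene for e in self.entries}

    @property
    def rsids(self) -> set[str]:
        return {r for e in self.entries for r in e.rsids}


@dataclass(frozen=True)
class CohortRow:
    gene: str
    rsid: str
    frequency: int  # carrier samples out of the 96-sample cohort
    clnsig_raw: str
    disease_text: str
    case_study: str  # "AF" | "HF"


@dataclass
class CohortFixture:
    """The triaged 16-variant cohort table with its AF/HF partition."""

    rows: list[CohortRow]

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def partition(self) -> dict[str, str]:
        return {r.rsid: r.case_study for r in self.rows}

    def rows_for(self, case_study: str) -> list[CohortRow]:
        return [r for r in self.rows if r.case_study == case_study]

    @property
    def max_frequency(self) -> int:
        return max(r.frequency for r in self.rows)


def _fixture_bytes(name: str) -> bytes:
    data = (resources.files("varcurate") / "data" / name).read_bytes()
    checks = json.loads(
        (resources.files("varcurate") / "data" / "checksums.json").read_text()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != checks.get(name):
        raise FormatError(f"packaged fixture {name} is corrupted (checksum mismatch)")
    return data


def load_gene_panel() -> GenePanel:
    """Load the packaged gene panel, verifying its checksum."""
    lines = _fixture_bytes("gene_panel.tsv").decode("utf-8").splitlines()
    entries = []
    for line in lines[1:]:
        gene, rsids, disease = line.split("\t")
        entries.append(PanelEntry(gene, tuple(rsids.split(";")), disease))
    return GenePanel(entries)


def load_cohort_fixture() -> CohortFixture:
    """Load the packaged cohort triage table, verifying its checksum."""
    lines = _fixture_bytes("cohort_table.tsv").decode("utf-8").splitlines()
    rows = []
    for line in lines[1:]:
        gene, rsid, freq, clnsig, disease, case_study = line.split("\t")
        rows.append(CohortRow(gene, rsid, int(freq), clnsig, disease, case_study))
    return CohortFixture(rows)


# ---------------------------------------------------------------------------
# synthetic generators


@dataclass
class GeneratorSpec:
    """Parameters for the synthetic generators.

    Defaults mirror the emulated study conditions: a 96-sample cohort,
    heterozygous carriers, site qualities in the typical short-read
    range, and moderate fractions of dot-missing fields so that
    missing-value handling is always exercised.
    """

    n_samples: int = 96
    n_records: int = 100
    n_decoy_variants: int = 10
    n_panel_records: int = 0
    seed: int = 0
    depth_range: tuple[int, int] = (10, 60)
    qual_range: tuple[float, float] = (30.0, 99.0)
    missing_qual_fraction: float = 0.1
    missing_id_fraction: float = 0.2
    multi_allelic_fraction: float = 0.1
    random_zygosity: bool = False


def _ensembl_id(symbol: str) -> str:
    """Deterministic synthetic Ensembl-style gene ID for a symbol."""
    return f"ENSG{zlib.crc32(symbol.encode()) % 10**11:011d}"


def _ann_entry(alt: str, gene: str) -> str:
    fields = [alt, "intron_variant", "MODIFIER", gene, _ensembl_id(gene),
              "transcript", f"{gene}-201", "protein_coding"] + [""] * 8
    return "|".join(fields)


def _sample_names(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def _cohort_header(n_samples: int, fileformat: str = "VCFv4.2") -> VcfHeader:
    meta = [
        f"##fileformat={fileformat}",
        "##source=varcurate-synthetic",
        f'##INFO=<ID=ANN,Number=.,Type=String,Description="{ANN_DESCRIPTION}">',
        '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total Depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
    ]
    header = VcfHeader(fileformat_version=fileformat, sample_names=_sample_names(n_samples))
    header.meta_lines = meta
    # re-parse own definitions so downstream warnings stay quiet
    from varcurate.vcf_io import _META_DEF_RE, _parse_ann_subfields

    for line in meta:
        m = _META_DEF_RE.match(line)
        if m:
            entry = (m.group("number"), m.group("type"), m.group("desc"))
            if m.group("kind") == "INFO":
                header.info_definitions[m.group("id")] = entry
                if m.group("id") == "ANN":
                    header.ann_subfield_names = _parse_ann_subfields(m.group("desc"))
            else:
                header.format_definitions[m.group("id")] = entry
    return header


def generate_cohort_vcf(
    out_path: PathLike,
    spec: GeneratorSpec | None = None,
    fixture: CohortFixture | None = None,
) -> tuple[Path, dict]:
    """Emit a cohort VCF with one record per fixture row.

    Each variant gets *exactly* its fixture frequency of carrier samples
    (heterozygous by default), its rsID, a ClinVar-style CLNSIG INFO
    value and a functional ANN entry naming its gene.  Decoy records on
    non-panel genes are appended.  Returns the path and a truth table of
    every planted fact.
    """
    spec = spec or GeneratorSpec()
    fixture = fixture or load_cohort_fixture()
    if spec.n_samples < fixture.max_frequency:
        raise ConfigError(
            f"n_samples={spec.n_samples} below the maximum fixture frequency "
            f"{fixture.max_frequency}"
        )
    rng = np.random.default_rng(spec.seed)
    header = _cohort_header(spec.n_samples)
    names = header.sample_names
    records: list[VariantRecord] = []
    truth: dict = {"n_samples": spec.n_samples, "seed": spec.seed, "variants": []}

    def make_record(i, rsid, gene, clnsig, carriers):
        chrom = str(i % 22 + 1)
        pos = 100_000 + i * 1_500
        ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
        qual = float(np.round(rng.uniform(*spec.qual_range), 2))
        carrier_set = set(carriers)
        samples = []
        for s in range(spec.n_samples):
            if s in carrier_set:
                gt = "1/1" if spec.random_zygosity and rng.random() < 0.5 else "0/1"
            else:
                gt = "0/0"
            samples.append(
                {
                    "GT": gt,
                    "DP": str(int(rng.integers(*spec.depth_range))),
                    "GQ": str(int(rng.integers(20, 100))),
                }
            )
        info: dict = {
            "AF": f"{len(carrier_set) / spec.n_samples:.4f}",
            "ANN": _ann_entry(alt, gene),
        }
        if clnsig is not None:
            info["CLNSIG"] = clnsig.replace(" ", "_")
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            id=rsid,
            ref=ref,
            alt=[alt],
            qual=qual,
            filter="PASS",
            info=info,
            format_keys=["GT", "DP", "GQ"],
            samples=samples,
            qual_text=f"{qual:g}",
        )
        return rec

    for i, row in enumerate(fixture.rows):
        carriers = sorted(rng.choice(spec.n_samples, size=row.frequency, replace=False))
        rec = make_record(i, row.rsid, row.gene, row.clnsig_raw, carriers)
        records.append(rec)
        truth["variants"].append(
            {
                "rsid": row.rsid,
                "gene": row.gene,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt[0],
                "clnsig": row.clnsig_raw,
                "carriers": [names[c] for c in carriers],
                "decoy": False,
            }
        )
    for j in range(spec.n_decoy_variants):
        i = len(fixture.rows) + j
        gene = f"DEC{j + 1:03d}"
        n_carriers = int(rng.integers(0, max(1, spec.n_samples // 4) + 1))
        carriers = sorted(rng.choice(spec.n_samples, size=n_carriers, replace=False))
        rec = make_record(i, f"rs9{7_000_000 + j}", gene, None, carriers)
        records.append(rec)
        truth["variants"].append(
            {
                "rsid": rec.id,
                "gene": gene,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt[0],
                "clnsig": None,
                "carriers": [names[c] for c in carriers],
                "decoy": True,
            }
        )
    path = write_vcf(out_path, header, records)
    return path, truth


def generate_random_vcf(
    out_path: PathLike,
    spec: GeneratorSpec | None = None,
    panel_genes: list[str] | None = None,
) -> tuple[Path, dict]:
    """Emit a random multi-sample VCF plus a truth table.

    Random chromosomes/positions/alleles, a configurable fraction of
    dot-missing QUAL and ID fields, a configurable multi-allelic
    fraction, and per-sample GT/DP/GQ.  ``spec.n_panel_records`` records
    carry an ANN entry naming a gene drawn from ``panel_genes``; all
    other records carry decoy genes, so gene-filter oracles can count
    planted hits from the truth table alone.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    if panel_genes is None:
        panel_genes = sorted(load_gene_panel().gene_symbols)
    header = _cohort_header(spec.n_samples)
    names = header.sample_names
    if spec.n_panel_records > spec.n_records:
        raise ConfigError("n_panel_records cannot exceed n_records")
    panel_idx = set(
        rng.choice(spec.n_records, size=spec.n_panel_records, replace=False).tolist()
    )
    records = []
    truth: dict = {
        "n_samples": spec.n_samples,
        "seed": spec.seed,
        "n_panel_records": spec.n_panel_records,
        "variants": [],
    }
    pos = 0
    for i in range(spec.n_records):
        chrom = str(int(rng.integers(1, 23)))
        pos += int(rng.integers(50, 5_000))
        ref, alt1, alt2 = (str(b) for b in rng.choice(_BASES, size=3, replace=False))
        alts = [alt1]
        if rng.random() < spec.multi_allelic_fraction:
            alts.append(alt2)
        rsid = None
        if rng.random() >= spec.missing_id_fraction:
            rsid = f"rs{int(rng.integers(10**6, 10**8))}"
        qual = None
        if rng.random() >= spec.missing_qual_fraction:
            qual = float(np.round(rng.uniform(*spec.qual_range), 2))
        filt = "PASS" if rng.random() < 0.85 else "q10"
        on_panel = i in panel_idx
        gene = (
            str(rng.choice(panel_genes))
            if on_panel
            else f"ZZZ{int(rng.integers(0, 1000)):03d}"
        )
        af = float(np.round(rng.uniform(0, 1), 4))
        info = {
            "AF": f"{af:.4f}",
            "DP": str(int(rng.integers(50, 5_000))),
            "ANN": ",".join(_ann_entry(a, gene) for a in alts),
        }
        samples = []
        gts = []
        for _s in range(spec.n_samples):
            gt = str(rng.choice(["0/0", "0/1", "1/1", "./."], p=[0.55, 0.25, 0.12, 0.08]))
            gts.append(gt)
            samples.append(
                {
                    "GT": gt,
                    "DP": str(int(rng.integers(*spec.depth_range))),
                    "GQ": str(int(rng.integers(20, 100))),
                }
            )
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            id=rsid,
            ref=ref,
            alt=alts,
            qual=qual,
            filter=filt,
            info=info,
            format_keys=["GT", "DP", "GQ"],
            samples=samples,
            qual_text=None if qual is None else f"{qual:g}",
        )
        records.append(rec)
        truth["variants"].append(
            {
                "index": i,
                "rsid": rsid,
                "gene": gene,
                "on_panel": on_panel,
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": list(alts),
                "qual": qual,
                "filter": filt,
                "af": af,
                "gts": gts,
                "depths": [s["DP"] for s in samples],
            }
        )
    path = write_vcf(out_path, header, records)
    return path, truth


def generate_mini_dbs(
    target_truth: dict,
    out_dir: PathLike,
    coverage_fraction: float = 0.5,
    n_extra_entries: int = 5,
    seed: int = 0,
) -> tuple[Path, Path, Path, dict]:
    """Emit dbSNP-like / ClinVar-like VCFs and a score table for a target.

    A seeded fraction of the target's variants is covered by all three
    databases; ``n_extra_entries`` additional entries match nothing.
    Returns the three paths plus a truth table listing, per database,
    the covered variant keys and — for the dbSNP-like database — the IDs
    expected to be assigned to target records lacking one.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    variants = target_truth["variants"]
    n_cov = int(round(coverage_fraction * len(variants)))
    covered_idx = sorted(rng.choice(len(variants), size=n_cov, replace=False).tolist())

    clnsig_pool = [
        "Pathogenic",
        "Likely_pathogenic",
        "Benign",
        "Likely_benign",
        "Benign/Likely_benign",
        "Uncertain_significance",
        "risk_factor",
        "association",
    ]
    db_header = VcfHeader(fileformat_version="VCFv4.2")
    db_header.meta_lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CLNSIG,Number=.,Type=String,Description="Clinical significance">',
        '##INFO=<ID=CLNDN,Number=.,Type=String,Description="Disease name">',
    ]
    db_header.info_definitions = {
        "CLNSIG": (".", "String", "Clinical significance"),
        "CLNDN": (".", "String", "Disease name"),
    }

    dbsnp_records, clinvar_records, score_rows = [], [], []
    truth: dict = {"covered_keys": [], "expected_id_assignments": {}, "clnsig": {}, "scores": {}}
    for i in covered_idx:
        v = variants[i]
        alts = v["alt"] if isinstance(v["alt"], list) else [v["alt"]]
        key = (v["chrom"], v["pos"], v["ref"], alts[0])
        truth["covered_keys"].append(list(key))
        db_id = v["rsid"] or f"rs8{600_000 + i}"
        if v["rsid"] is None:
            truth["expected_id_assignments"][f"{v['chrom']}:{v['pos']}"] = db_id
        dbsnp_records.append(
            VariantRecord(
                chrom=v["chrom"], pos=v["pos"], id=db_id, ref=v["ref"], alt=list(alts),
                qual=None, filter=".", info={},
            )
        )
        clnsig = v.get("clnsig")
        clnsig = clnsig.replace(" ", "_") if clnsig else str(rng.choice(clnsig_pool))
        truth["clnsig"][db_id] = clnsig
        clinvar_records.append(
            VariantRecord(
                chrom=v["chrom"], pos=v["pos"], id=db_id, ref=v["ref"], alt=list(alts),
                qual=None, filter=".", info={"CLNSIG": clnsig, "CLNDN": "synthetic_disease"},
            )
        )
        score = float(np.round(rng.uniform(0, 40), 2))
        truth["scores"][f"{v['chrom']}:{v['pos']}"] = score
        score_rows.append((v["chrom"], v["pos"], v["ref"], alts[0], score))

    max_pos = max((v["pos"] for v in variants), default=0)
    for j in range(n_extra_entries):
        chrom = str(int(rng.integers(1, 23)))
        pos = max_pos + 10_000 + j * 97  # guaranteed off-target
        ref, alt = (str(b) for b in rng.choice(_BASES, size=2, replace=False))
        dbsnp_records.append(
            VariantRecord(chrom=chrom, pos=pos, id=f"rs77{j:05d}", ref=ref, alt=[alt],
                          qual=None, filter=".", info={})
        )
        clinvar_records.append(
            VariantRecord(chrom=chrom, pos=pos, id=f"rs77{j:05d}", ref=ref, alt=[alt],
                          qual=None, filter=".",
                          info={"CLNSIG": str(rng.choice(clnsig_pool)), "CLNDN": "synthetic_disease"})
        )
        score_rows.append((chrom, pos, ref, alt, float(np.round(rng.uniform(0, 40), 2))))

    dbsnp_path = write_vcf(out_dir / "dbsnp_like.vcf", db_header, dbsnp_records)
    clinvar_path = write_vcf(out_dir / "clinvar_like.vcf", db_header, clinvar_records)
    score_path = out_dir / "scores.tsv"
    with open(score_path, "w", encoding="utf-8") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tCADD_PHRED\n")
        for chrom, pos, ref, alt, score in score_rows:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{score}\n")
    return dbsnp_path, clinvar_path, score_path, truth
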