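"""Transform annotated VCFs into AI/ML-ready structures.

Three complementary exports:

* a per-sample **feature table** — one row per sample, one column per
  (variant, FORMAT key) pair, so genotype quality, read depth, phasing
  etc. become plain tabular features;
* a **binary presence matrix** — samples x variants, 1 iff the sample
  carries at least one non-reference allele;
* a **relational export** — four SQLite tables (variants, annotations,
  samples, genotypes) for SQL-based data management pipelines.

Column naming uses the variant's rsID when present and a synthetic
``chrom:pos:ref:alt`` key otherwise, so names are stable whether or not
annotation ran.  Tabular outputs are CSV with the empty field as the
absent marker; a fully missing genotype (``./.``) counts as absence (0)
in the binary matrix by default.
"""

from __future__ import annotations

import logging
import sqlite3
from pathlib import Path

import pandas as pd

from varcurate.errors import FormatError, InputOutputError
from varcurate.vcf_io import (
    FLAG,
    PathLike,
    VariantRecord,
    VcfHeader,
    iter_records,
    read_header,
    write_vcf,
)

logger = logging.getLogger(__name__)


def variant_key(record: VariantRecord) -> str:
    """rsID when present, else ``chrom:pos:ref:alt`` (stable fallback)."""
    if record.id is not None:
        return record.id
    return f"{record.chrom}:{record.pos}:{record.ref}:{','.join(record.alt)}"


def presence(gt_text: str | None) -> int:
    """1 iff the genotype carries at least one non-reference allele.

    ``/`` and ``|`` separators are equivalent; an absent or fully
    missing genotype (``.``, ``./.``) scores 0.  Unparsable allele
    tokens score 0 with a warning.
    """
    if gt_text is None:
        return 0
    for token in gt_text.replace("|", "/").split("/"):
        token = token.strip()
        if token in ("", "."):
            continue
        try:
            if int(token) >= 1:
                return 1
        except ValueError:
            logger.warning("unparsable genotype allele token %r", token)
    return 0


def build_feature_table(
    vcf_path: PathLike, format_keys: list[str] | None = None
) -> pd.DataFrame:
    """Sample x feature matrix of raw per-sample FORMAT values.

    Columns are named ``<variant_key>:<format_key>`` and ordered by
    record order, then FORMAT-key order; missing entries are NA.
    """
    header = read_header(vcf_path)
    if not header.sample_names:
        raise FormatError(f"{vcf_path} has no sample columns; nothing to extract")
    if format_keys is None:
        format_keys = ["GT"]
    for key in format_keys:
        if key not in header.format_definitions:
            logger.warning("FORMAT key %r not declared in header", key)
    columns: list[str] = []
    data: dict[str, list[str | None]] = {}
    for rec in iter_records(vcf_path, header):
        vkey = variant_key(rec)
        for fkey in format_keys:
            col = f"{vkey}:{fkey}"
            columns.append(col)
            data[col] = [sample.get(fkey) for sample in rec.samples]
    table = pd.DataFrame(data, index=list(header.sample_names), columns=columns)
    table.index.name = "sample"
    return table


def build_binary_matrix(vcf_path: PathLike, missing_as_na: bool = False) -> pd.DataFrame:
    """Samples x variants 0/1 carrier matrix from the GT field.

    With ``missing_as_na`` a fully missing genotype becomes NA instead
    of 0.  Column sums equal the number of carrier samples per variant.
    """
    header = read_header(vcf_path)
    if not header.sample_names:
        raise FormatError(f"{vcf_path} has no sample columns; nothing to extract")
    columns: list[str] = []
    data: dict[str, list] = {}
    for rec in iter_records(vcf_path, header):
        vkey = variant_key(rec)
        values = []
        for sample in rec.samples:
            gt = sample.get("GT")
            if missing_as_na and (gt is None or all(t in ("", ".") for t in gt.replace("|", "/").split("/"))):
                values.append(pd.NA)
            else:
                values.append(presence(gt))
        columns.append(vkey)
        data[vkey] = values
    matrix = pd.DataFrame(data, index=list(header.sample_names), columns=columns)
    if not missing_as_na:
        matrix = matrix.astype(int)
    matrix.index.name = "sample"
    for col in matrix.columns:
        logger.debug("carriers(%s) = %s", col, matrix[col].sum())
    return matrix


_SCHEMA = """
CREATE TABLE variants (
    variant_key TEXT PRIMARY KEY,
    chrom TEXT NOT NULL,
    pos INTEGER NOT NULL,
    id TEXT,
    ref TEXT NOT NULL,
    alt TEXT NOT NULL,
    qual REAL,
    filter TEXT
);
CREATE TABLE annotations (
    variant_key TEXT NOT NULL REFERENCES variants(variant_key),
    source TEXT NOT NULL,
    key TEXT NOT NULL,
    value TEXT
);
CREATE TABLE samples (
    sample_name TEXT PRIMARY KEY
);
CREATE TABLE genotypes (
    variant_key TEXT NOT NULL REFERENCES variants(variant_key),
    sample_name TEXT NOT NULL REFERENCES samples(sample_name),
    format_key TEXT NOT NULL,
    value TEXT NOT NULL
);
"""


def export_relational(
    vcf_path: PathLike, db_path: PathLike, overwrite: bool = False
) -> dict[str, int]:
    """Export a VCF into a four-table SQLite database; returns row counts.

    ``annotations`` holds one row per INFO key per variant (flags store
    the value ``"1"``); ``genotypes`` omits absent per-sample values
    rather than storing NULL rows, keeping the table sparse.
    """
    db_path = Path(db_path)
    if db_path.exists():
        if not overwrite:
            raise InputOutputError(
                f"{db_path} already exists; pass overwrite=True to replace it"
            )
        db_path.unlink()
    header = read_header(vcf_path)
    con = sqlite3.connect(db_path)
    try:
        con.executescript(_SCHEMA)
        con.executemany(
            "INSERT INTO samples (sample_name) VALUES (?)",
            [(s,) for s in header.sample_names],
        )
        counts = {"variants": 0, "annotations": 0, "samples": len(header.sample_names), "genotypes": 0}
        for rec in iter_records(vcf_path, header):
            vkey = variant_key(rec)
            con.execute(
                "INSERT OR REPLACE INTO variants VALUES (?,?,?,?,?,?,?,?)",
                (
                    vkey,
                    rec.chrom,
                    rec.pos,
                    rec.id,
                    rec.ref,
                    ",".join(rec.alt),
                    rec.qual,
                    rec.filter,
                ),
            )
            counts["variants"] += 1
            for key, value in rec.info.items():
                con.execute(
                    "INSERT INTO annotations VALUES (?,?,?,?)",
                    (vkey, "INFO", key, "1" if value is FLAG else value),
                )
                counts["annotations"] += 1
            for name, sample in zip(header.sample_names, rec.samples):
                for fkey in rec.format_keys:
                    value = sample.get(fkey)
                    if value is None:
                        continue
                    con.execute(
                        "INSERT INTO genotypes VALUES (?,?,?,?)",
                        (vkey, name, fkey, value),
                    )
                    counts["genotypes"] += 1
        con.commit()
    finally:
        con.close()
    return counts


def reconstruct_from_relational(db_path: PathLike) -> list[dict]:
    """Re-query a relational export back into plain variant dictionaries.

    Used to verify that the export is lossless on the exported fields:
    each dictionary carries the variants row, its INFO annotations and
    the per-sample genotype values.
    """
    con = sqlite3.connect(db_path)
    con.row_factory = sqlite3.Row
    try:
        out = []
        for row in con.execute("SELECT * FROM variants ORDER BY rowid"):
            entry = dict(row)
            entry["annotations"] = {
                r["key"]: r["value"]
                for r in con.execute(
                    "SELECT key, value FROM annotations WHERE variant_key=? AND source='INFO'",
                    (row["variant_key"],),
                )
            }
            entry["genotypes"] = {
                (r["sample_name"], r["format_key"]): r["value"]
                for r in con.execute(
                    "SELECT sample_name, format_key, value FROM genotypes WHERE variant_key=?",
                    (row["variant_key"],),
                )
            }
            out.append(entry)
        return out
    finally:
        con.close()
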