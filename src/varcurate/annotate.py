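"""Native variant annotation and clinical-significance triage.

Annotation is an exact coordinate/allele join: each database entry is
indexed by ``(chrom, pos, ref, alt)`` with multi-allelic entries split
so every key carries a single alternate allele.  Two database shapes are
supported:

* ``vcf_db`` — a VCF-formatted database (dbSNP-like, ClinVar-like); the
  ID column can backfill missing rsIDs and selected INFO keys are
  transferred onto matching records.
* ``score_table`` — a tab-delimited positional score table (dbNSFP-like)
  with columns CHROM, POS, REF, ALT plus named score columns.

Transferred keys are namespaced ``<dbname>_<field>`` so database payloads
can never collide with each other or with pre-existing INFO keys.

Clinical significance follows the ClinVar assertion vocabulary: a
variant is *deleterious* when any assertion token is "pathogenic",
"likely pathogenic", "risk factor" or "association"; *benign* when the
assertions are exclusively benign/likely benign; *unannotated* without
any assertion; *uncertain* otherwise (including conflicting
interpretations).  No indel normalisation (left-alignment) is attempted:
the join is exact on all four key components.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

from varcurate.errors import ConfigError, FormatError, InputOutputError
from varcurate.vcf_io import (
    PathLike,
    VariantRecord,
    iter_records,
    read_header,
    write_vcf,
)
from varcurate._runlog import RunLog, write_manifest

Key = tuple[str, int, str, str]


@dataclass
class AnnotationDb:
    """An indexed annotation source keyed by (chrom, pos, ref, alt)."""

    name: str
    kind: str  # "vcf_db" | "score_table"
    index: dict[Key, dict[str, str]] = field(default_factory=dict)
    ids: dict[Key, str] = field(default_factory=dict)
    transfer_fields: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.index)

    def lookup(self, chrom: str, pos: int, ref: str, alt: str) -> dict[str, str] | None:
        return self.index.get((chrom, pos, ref, alt))

    def lookup_id(self, chrom: str, pos: int, ref: str, alt: str) -> str | None:
        return self.ids.get((chrom, pos, ref, alt))


def load_annotation_db(
    path: PathLike,
    kind: str,
    transfer_fields: list[str] | None = None,
    name: str | None = None,
    runlog: RunLog | None = None,
) -> AnnotationDb:
    """Index an annotation database for exact-key joins.

    Multi-allelic VCF entries are split one key per alternate allele.
    Duplicate keys resolve last-wins with a logged warning; a requested
    transfer field absent from an entry is skipped with a warning.
    """
    if kind not in ("vcf_db", "score_table"):
        raise ConfigError(f"unknown annotation database kind {kind!r}")
    path = Path(path)
    if name is None:
        name = path.name.split(".")[0]
    db = AnnotationDb(name=name, kind=kind, transfer_fields=list(transfer_fields or []))
    warn = runlog.warning if runlog is not None else (lambda _msg: None)

    if kind == "vcf_db":
        header = read_header(path)
        for rec in iter_records(path, header):
            for alt in rec.alt:
                key = (rec.chrom, rec.pos, rec.ref, alt)
                if key in db.index:
                    warn(f"{name}: duplicate entry for {key}, keeping the later one")
                payload: dict[str, str] = {}
                for fld in db.transfer_fields:
                    value = rec.info_value(fld)
                    if value is None:
                        warn(f"{name}: entry {key} lacks transfer field {fld!r}")
                    else:
                        payload[fld] = value
                db.index[key] = payload
                if rec.id is not None:
                    db.ids[key] = rec.id
    else:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            cols = reader.fieldnames or []
            required = {"CHROM", "POS", "REF", "ALT"}
            if not required.issubset(cols):
                raise FormatError(
                    f"score table {path} must have columns CHROM POS REF ALT, got {cols}"
                )
            score_cols = [c for c in cols if c not in required]
            if not db.transfer_fields:
                db.transfer_fields = score_cols
            for row in reader:
                for alt in row["ALT"].split(","):
                    key = (row["CHROM"], int(row["POS"]), row["REF"], alt)
                    if key in db.index:
                        warn(f"{name}: duplicate entry for {key}, keeping the later one")
                    payload = {}
                    for fld in db.transfer_fields:
                        value = row.get(fld)
                        if value in (None, "", "."):
                            warn(f"{name}: entry {key} lacks transfer field {fld!r}")
                        else:
                            payload[fld] = value
                    db.index[key] = payload
    return db


def assign_ids(record: VariantRecord, dbsnp_like: AnnotationDb) -> VariantRecord:
    """Backfill a missing rsID from a dbSNP-like database (in place).

    The first alternate allele with a database match supplies the ID;
    an existing ID is never overwritten.  Applying the operation twice
    is a fixed point.
    """
    if record.id is not None:
        return record
    for alt in record.alt:
        found = dbsnp_like.lookup_id(record.chrom, record.pos, record.ref, alt)
        if found is not None:
            record.id = found
            break
    return record


def annotate_record(record: VariantRecord, dbs: Iterable[AnnotationDb]) -> bool:
    """Transfer matching payload fields onto one record; True if any hit.

    Keys are namespaced ``<dbname>_<field>``; IDs are backfilled from
    any database that carries them.
    """
    hit = False
    for db in dbs:
        if db.ids:
            had_id = record.id is not None
            assign_ids(record, db)
            if not had_id and record.id is not None:
                hit = True
        matched: dict[str, str] | None = None
        for alt in record.alt:
            payload = db.lookup(record.chrom, record.pos, record.ref, alt)
            if payload is not None:
                matched = payload
                break
        if matched is not None:
            for fld, value in matched.items():
                record.info[f"{db.name}_{fld}"] = value
            hit = True
    return hit


def annotate_file(
    in_path: PathLike,
    out_path: PathLike,
    dbs: list[AnnotationDb],
    log_dir: PathLike | None = None,
) -> int:
    """Annotate every record against ``dbs``; returns the matched count.

    With an empty database list annotation is skipped entirely: the
    output is a copy of the input and a notice is logged.  Record order
    and count are never changed.
    """
    runlog = RunLog(log_dir, "annotate")
    header = read_header(in_path)
    out_header = header
    if not dbs:
        runlog.info("no annotation databases specified; annotation skipped")
        write_vcf(out_path, header, iter_records(in_path, header))
        write_manifest(
            log_dir,
            "annotate",
            started_at=runlog.started_at,
            inputs=[str(in_path)],
            outputs=[str(out_path)],
            stats={"records_annotated": 0, "skipped": True},
            warnings=runlog.warnings,
        )
        return 0

    for db in dbs:
        runlog.info(f"database {db.name} ({db.kind}): {len(db)} indexed entries")
        for fld in db.transfer_fields:
            out_header.add_info_definition(
                f"{db.name}_{fld}", "1", "String", f"{fld} transferred from {db.name}"
            )

    annotated = 0

    prefixed = {f"{db.name}_{f}" for db in dbs for f in db.transfer_fields}

    def _stream():
        nonlocal annotated
        for rec in iter_records(in_path, header):
            collisions = prefixed & set(rec.info)
            if annotate_record(rec, dbs):
                annotated += 1
            for k in collisions & set(rec.info):
                runlog.warning(f"INFO key {k} overwritten by database payload")
            yield rec

    write_vcf(out_path, out_header, _stream())
    runlog.info(f"records_annotated={annotated}")
    write_manifest(
        log_dir,
        "annotate",
        started_at=runlog.started_at,
        inputs=[str(in_path)] + [db.name for db in dbs],
        outputs=[str(out_path)],
        stats={"records_annotated": annotated},
        warnings=runlog.warnings,
    )
    return annotated


# ---------------------------------------------------------------------------
# clinical-significance triage

DELETERIOUS_PHRASES = frozenset(
    {"pathogenic", "likely pathogenic", "risk factor", "association"}
)
BENIGN_PHRASES = frozenset({"benign", "likely benign"})


@dataclass(frozen=True)
class SignificanceLabel:
    """Four-way triage category for a ClinVar-style CLNSIG string."""

    category: str  # deleterious | benign | uncertain | unannotated
    raw: str | None

    def __post_init__(self) -> None:
        if self.category not in ("deleterious", "benign", "uncertain", "unannotated"):
            raise ValueError(f"invalid category {self.category!r}")


def classify_significance(clnsig_text: str | None) -> SignificanceLabel:
    """Map a CLNSIG assertion string to a triage category (total function).

    Normalisation: lowercase, underscores to spaces, split on ``/``,
    ``,`` and ``|`` into assertion phrases.  A co-occurring benign token
    never blocks a deleterious one ("Pathogenic/Benign" is deleterious).
    """
    if clnsig_text is None or not clnsig_text.strip():
        return SignificanceLabel("unannotated", clnsig_text)
    normal = clnsig_text.lower().replace("_", " ")
    for sep in ("/", ",", "|"):
        normal = normal.replace(sep, "\x00")
    phrases = {p.strip() for p in normal.split("\x00") if p.strip()}
    if not phrases:
        return SignificanceLabel("unannotated", clnsig_text)
    if phrases & DELETERIOUS_PHRASES:
        return SignificanceLabel("deleterious", clnsig_text)
    if phrases <= BENIGN_PHRASES:
        return SignificanceLabel("benign", clnsig_text)
    return SignificanceLabel("uncertain", clnsig_text)


@dataclass
class TriageRow:
    gene: str
    variant_id: str
    cohort_frequency: int | None
    significance_raw: str | None
    category: str
    disease: str
    case_study: str | None = None


@dataclass
class TriageReport:
    """Unique-variant counts per triage category, plus per-variant rows."""

    counts: dict[str, int]
    rows: list[TriageRow]
    partition_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_unique(self) -> int:
        return sum(self.counts.values())

    def deleterious_in(self, partition: str) -> int:
        return self.partition_counts.get(partition, 0)

    def write_tsv(self, path: PathLike) -> Path:
        """Report rows as TSV: Gene, RSID, Frequency, ClinicalSignificance, Disease."""
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["Gene", "RSID", "Frequency", "ClinicalSignificance", "Disease"])
            for row in self.rows:
                writer.writerow(
                    [
                        row.gene,
                        row.variant_id,
                        "" if row.cohort_frequency is None else row.cohort_frequency,
                        row.significance_raw or "",
                        row.disease,
                    ]
                )
        return path


def triage(
    source,
    disease_partition: Mapping[str, str] | None = None,
    clnsig_key: str = "CLNSIG",
    runlog: RunLog | None = None,
) -> TriageReport:
    """Triage variants into significance categories and count unique IDs.

    ``source`` is either a path to an annotated VCF or a
    :class:`~varcurate.fixtures.CohortFixture`.  Uniqueness is by
    variant ID; a deleterious record without an ID is counted under a
    synthetic ``chrom:pos:ref:alt`` key (logged).  ``disease_partition``
    maps variant IDs to a group name (e.g. ``AF``/``HF``); per-group
    deleterious counts are reported alongside the overall ones.
    """
    rows: list[TriageRow] = []
    if isinstance(source, (str, Path)):
        header = read_header(source)
        for rec in iter_records(source, header):
            raw = None
            for key in rec.info:
                if key == clnsig_key or key.endswith(f"_{clnsig_key}"):
                    raw = rec.info_value(key)
                    break
            vid = rec.id
            if vid is None:
                vid = f"{rec.chrom}:{rec.pos}:{rec.ref}:{','.join(rec.alt)}"
                if runlog is not None and classify_significance(raw).category == "deleterious":
                    runlog.warning(f"deleterious record without ID counted as {vid}")
            gene = ""
            from varcurate.preprocess import genes_of  # local import avoids a cycle

            pairs = genes_of(rec, header)
            if pairs:
                gene = sorted(pairs)[0][0]
            rows.append(
                TriageRow(
                    gene=gene,
                    variant_id=vid,
                    cohort_frequency=None,
                    significance_raw=raw,
                    category=classify_significance(raw).category,
                    disease="",
                )
            )
    else:  # CohortFixture-like: iterable of row objects
        for entry in source.rows:
            rows.append(
                TriageRow(
                    gene=entry.gene,
                    variant_id=entry.rsid,
                    cohort_frequency=entry.frequency,
                    significance_raw=entry.clnsig_raw,
                    category=classify_significance(entry.clnsig_raw).category,
                    disease=entry.disease_text,
                    case_study=entry.case_study,
                )
            )

    # Unique-ID accounting: a variant ID contributes to exactly one
    # category (the most severe seen: deleterious > uncertain > benign >
    # unannotated, so repeated observations cannot double-count).
    severity = {"deleterious": 3, "uncertain": 2, "benign": 1, "unannotated": 0}
    best: dict[str, str] = {}
    for row in rows:
        cur = best.get(row.variant_id)
        if cur is None or severity[row.category] > severity[cur]:
            best[row.variant_id] = row.category
    counts: dict[str, int] = {c: 0 for c in severity}
    for category in best.values():
        counts[category] += 1

    partition_counts: dict[str, int] = {}
    partition = dict(disease_partition or {})
    if not partition:
        # fall back to the case_study attribute carried by fixture rows
        partition = {
            row.variant_id: row.case_study for row in rows if row.case_study is not None
        }
    for vid, category in best.items():
        if category == "deleterious" and vid in partition:
            group = partition[vid]
            partition_counts[group] = partition_counts.get(group, 0) + 1
    return TriageReport(counts=counts, rows=rows, partition_counts=partition_counts)
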