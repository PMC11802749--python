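"""Config-driven retention filtering of VCF streams.

A single JSON configuration drives every criterion: gene panels (symbols
or Ensembl IDs), rsID lists, site quality, an allele-frequency window on
a named INFO key, minimum pathogenicity-score thresholds on arbitrary
numeric INFO keys, INFO-key projection and sample-column projection.

Criteria are evaluated in a fixed, documented order —

    filter_pass_only -> variant_ids -> genes -> qual_min
        -> allele_freq -> score_thresholds

— and a dropped record is attributed to the *first* criterion that
fails, which makes the per-criterion drop counts in :class:`FilterStats`
an exact partition of the dropped records.  A record whose tested field
is absent (dot-encoded) passes iff ``missing_passes`` (default true):
a variant is not discarded for lacking a score its dataset never
annotated.

Files are processed streamingly; with ``workers > 1`` the data body is
cut into record-aligned batches that are filtered on a process pool and
merged back in order, so the output is byte-identical for every worker
count.
"""

from __future__ import annotations

import json
import multiprocessing
import os
from dataclasses import dataclass, field, asdict
from datetime import datetime
from pathlib import Path
from typing import Iterable

from varcurate.errors import ConfigError, InputOutputError
from varcurate.vcf_io import (
    FLAG,
    PathLike,
    VariantRecord,
    VcfHeader,
    open_text,
    parse_record,
    read_header,
)
from varcurate._runlog import RunLog, write_manifest

#: Fixed criterion evaluation order; first failure is the attributed drop.
CRITERION_ORDER = (
    "filter_pass_only",
    "variant_ids",
    "genes",
    "qual_min",
    "allele_freq",
    "score_thresholds",
)

_CONFIG_KEYS = {
    "gene_symbols",
    "gene_symbols_file",
    "ensembl_gene_ids",
    "ensembl_gene_ids_file",
    "variant_ids",
    "variant_ids_file",
    "qual_min",
    "allele_freq",
    "score_thresholds",
    "info_keys_keep",
    "samples_keep",
    "filter_pass_only",
    "missing_passes",
    "workers",
}


@dataclass
class FilterConfig:
    """All retention criteria for one preprocessing run.

    Empty sets / ``None`` values mean the criterion is inactive and
    always passes.  Gene symbols match case-insensitively; Ensembl IDs
    match case-sensitively.
    """

    gene_symbols: set[str] = field(default_factory=set)
    ensembl_gene_ids: set[str] = field(default_factory=set)
    variant_ids: set[str] = field(default_factory=set)
    qual_min: float | None = None
    allele_freq_key: str = "AF"
    allele_freq_min: float | None = None
    allele_freq_max: float | None = None
    score_thresholds: list[tuple[str, float]] = field(default_factory=list)
    info_keys_keep: list[str] | None = None
    samples_keep: list[str] | None = None
    filter_pass_only: bool = False
    missing_passes: bool = True
    workers: int = 1

    def __post_init__(self) -> None:
        if (
            self.allele_freq_min is not None
            and self.allele_freq_max is not None
            and self.allele_freq_min > self.allele_freq_max
        ):
            raise ConfigError(
                "allele_freq_min must be <= allele_freq_max "
                f"({self.allele_freq_min} > {self.allele_freq_max})"
            )
        for bound in (self.allele_freq_min, self.allele_freq_max):
            if bound is not None and not (0.0 <= bound <= 1.0):
                raise ConfigError(f"allele-frequency bound {bound} outside [0, 1]")
        if self.workers < 1:
            raise ConfigError(f"workers must be >= 1, got {self.workers}")
        self.gene_symbols = {s.upper() for s in self.gene_symbols}

    @property
    def genes_active(self) -> bool:
        return bool(self.gene_symbols or self.ensembl_gene_ids)


@dataclass
class FilterStats:
    """Run accounting: records_kept + sum(drops) == records_read."""

    records_read: int = 0
    records_kept: int = 0
    drops_by_criterion: dict[str, int] = field(default_factory=dict)
    started_at: datetime | None = None
    finished_at: datetime | None = None

    def add_drop(self, criterion: str) -> None:
        self.drops_by_criterion[criterion] = self.drops_by_criterion.get(criterion, 0) + 1

    def merge(self, other: "FilterStats") -> None:
        self.records_read += other.records_read
        self.records_kept += other.records_kept
        for k, v in other.drops_by_criterion.items():
            self.drops_by_criterion[k] = self.drops_by_criterion.get(k, 0) + v


def _read_id_list(path: PathLike) -> set[str]:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            return {
                line.strip()
                for line in fh
                if line.strip() and not line.lstrip().startswith("#")
            }
    except OSError as exc:
        raise InputOutputError(f"cannot read identifier list {path}: {exc}") from exc


def config_from_dict(data: dict, base_dir: PathLike | None = None) -> FilterConfig:
    """Build a :class:`FilterConfig` from a parsed JSON document.

    Identifier lists referenced by ``*_file`` keys (one identifier per
    line, ``#`` comments) are loaded relative to ``base_dir`` and merged
    with the inline lists.  Unknown keys are rejected.
    """
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
    base = Path(base_dir) if base_dir is not None else Path(".")

    def merged(inline_key: str, file_key: str) -> set[str]:
        values = set(data.get(inline_key, []))
        if file_key in data:
            ref = Path(data[file_key])
            values |= _read_id_list(ref if ref.is_absolute() else base / ref)
        return values

    af = data.get("allele_freq", {})
    if not isinstance(af, dict) or set(af) - {"key", "min", "max"}:
        raise ConfigError("allele_freq must be an object with keys key/min/max")
    thresholds: list[tuple[str, float]] = []
    for item in data.get("score_thresholds", []):
        if not isinstance(item, dict) or set(item) != {"key", "min"}:
            raise ConfigError("score_thresholds entries must be objects {key, min}")
        thresholds.append((str(item["key"]), float(item["min"])))

    return FilterConfig(
        gene_symbols=merged("gene_symbols", "gene_symbols_file"),
        ensembl_gene_ids=merged("ensembl_gene_ids", "ensembl_gene_ids_file"),
        variant_ids=merged("variant_ids", "variant_ids_file"),
        qual_min=None if data.get("qual_min") is None else float(data["qual_min"]),
        allele_freq_key=str(af.get("key", "AF")),
        allele_freq_min=None if af.get("min") is None else float(af["min"]),
        allele_freq_max=None if af.get("max") is None else float(af["max"]),
        score_thresholds=thresholds,
        info_keys_keep=data.get("info_keys_keep"),
        samples_keep=data.get("samples_keep"),
        filter_pass_only=bool(data.get("filter_pass_only", False)),
        missing_passes=bool(data.get("missing_passes", True)),
        workers=int(data.get("workers", 1)),
    )


def load_filter_config(path: PathLike) -> FilterConfig:
    """Load the single JSON configuration file driving a run."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    except OSError as exc:
        raise InputOutputError(f"cannot read config {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config {path} is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config must be a JSON object")
    return config_from_dict(data, base_dir=Path(path).parent)


def genes_of(record: VariantRecord, header: VcfHeader) -> set[tuple[str, str | None]]:
    """(symbol, ensembl_id) pairs carried by a record's annotations.

    Harvested from every comma-separated ANN entry (subfields Gene_Name
    and Gene_ID located via the header's ANN description, falling back
    to the conventional positions 3 and 4) and from a plain ``GENE``
    INFO key when present.
    """
    pairs: set[tuple[str, str | None]] = set()
    ann = record.info_value("ANN")
    if ann:
        names = header.ann_subfield_names
        try:
            i_sym = names.index("Gene_Name") if "Gene_Name" in names else 3
            i_id = names.index("Gene_ID") if "Gene_ID" in names else 4
        except ValueError:  # pragma: no cover - index() guarded above
            i_sym, i_id = 3, 4
        for entry in ann.split(","):
            sub = entry.split("|")
            if len(sub) <= max(i_sym, i_id):
                continue
            symbol = sub[i_sym].strip()
            gene_id = sub[i_id].strip() or None
            if symbol:
                pairs.add((symbol, gene_id))
    gene_info = record.info_value("GENE")
    if gene_info:
        for symbol in gene_info.split(","):
            if symbol.strip():
                pairs.add((symbol.strip(), None))
    return pairs


def _numeric(text: str | None) -> float | None:
    if text is None:
        return None
    first = text.split(",")[0]
    try:
        return float(first)
    except ValueError:
        return None


def record_passes(
    record: VariantRecord, config: FilterConfig, header: VcfHeader
) -> tuple[bool, str | None]:
    """Evaluate all active criteria; returns (keep, failed_criterion)."""
    missing_ok = config.missing_passes

    if config.filter_pass_only:
        if record.filter == ".":
            if not missing_ok:
                return False, "filter_pass_only"
        elif record.filter != "PASS":
            return False, "filter_pass_only"

    if config.variant_ids:
        if record.id is None:
            if not missing_ok:
                return False, "variant_ids"
        elif record.id not in config.variant_ids:
            return False, "variant_ids"

    if config.genes_active:
        pairs = genes_of(record, header)
        if not pairs:
            if not missing_ok:
                return False, "genes"
        else:
            hit = any(
                symbol.upper() in config.gene_symbols
                or (gene_id is not None and gene_id in config.ensembl_gene_ids)
                for symbol, gene_id in pairs
            )
            if not hit:
                return False, "genes"

    if config.qual_min is not None:
        if record.qual is None:
            if not missing_ok:
                return False, "qual_min"
        elif record.qual < config.qual_min:
            return False, "qual_min"

    if config.allele_freq_min is not None or config.allele_freq_max is not None:
        value = _numeric(record.info_value(config.allele_freq_key))
        if value is None:
            if not missing_ok:
                return False, "allele_freq"
        else:
            lo = config.allele_freq_min if config.allele_freq_min is not None else 0.0
            hi = config.allele_freq_max if config.allele_freq_max is not None else 1.0
            if not (lo <= value <= hi):
                return False, "allele_freq"

    for key, minimum in config.score_thresholds:
        value = _numeric(record.info_value(key))
        if value is None:
            if not missing_ok:
                return False, "score_thresholds"
        elif value < minimum:
            return False, "score_thresholds"

    return True, None


def reduce_record(
    record: VariantRecord, config: FilterConfig, header: VcfHeader
) -> VariantRecord:
    """Project a passing record onto the configured INFO keys and samples."""
    info = record.info
    if config.info_keys_keep is not None:
        keep = set(config.info_keys_keep)
        info = {k: v for k, v in record.info.items() if k in keep}
    samples = record.samples
    format_keys = record.format_keys
    if config.samples_keep is not None:
        keep_set = set(config.samples_keep)
        samples = [
            s for name, s in zip(header.sample_names, record.samples) if name in keep_set
        ]
    if info is record.info and samples is record.samples:
        return record
    return VariantRecord(
        chrom=record.chrom,
        pos=record.pos,
        id=record.id,
        ref=record.ref,
        alt=list(record.alt),
        qual=record.qual,
        filter=record.filter,
        info=info,
        format_keys=list(format_keys),
        samples=samples,
        qual_text=record.qual_text,
    )


# ---------------------------------------------------------------------------
# streaming execution (single- and multi-process)

_worker_state: dict = {}


def _init_worker(header: VcfHeader, config: FilterConfig) -> None:
    _worker_state["header"] = header
    _worker_state["config"] = config


def _process_batch(batch: tuple[int, list[str]]) -> tuple[list[str], dict[str, int], int]:
    """Filter one batch of raw data lines; returns (out_lines, drops, n_read)."""
    header: VcfHeader = _worker_state["header"]
    config: FilterConfig = _worker_state["config"]
    start_lineno, lines = batch
    out: list[str] = []
    drops: dict[str, int] = {}
    for i, line in enumerate(lines):
        record = parse_record(line, header, line_number=start_lineno + i)
        keep, criterion = record_passes(record, config, header)
        if keep:
            out.append(reduce_record(record, config, header).serialize())
        else:
            drops[criterion] = drops.get(criterion, 0) + 1  # type: ignore[index]
    return out, drops, len(lines)


def _iter_batches(path: PathLike, batch_size: int = 2000):
    lineno = 0
    batch: list[str] = []
    start = 1
    with open_text(path) as fh:
        for raw in fh:
            lineno += 1
            if raw.startswith("#") or not raw.strip():
                continue
            if not batch:
                start = lineno
            batch.append(raw)
            if len(batch) >= batch_size:
                yield start, batch
                batch = []
        if batch:
            yield start, batch


def filter_file(
    in_path: PathLike,
    out_path: PathLike,
    config: FilterConfig,
    log_dir: PathLike | None = None,
    compress: bool | None = None,
) -> FilterStats:
    """Filter ``in_path`` into ``out_path`` under ``config``.

    The output is the ordered concatenation of reduced passing records
    and is identical for every worker count.  A timestamped log (when
    ``log_dir`` is given) records the configuration, counts and
    warnings.  On any parse error the partial output is removed.
    """
    runlog = RunLog(log_dir, "preprocess")
    stats = FilterStats(started_at=runlog.started_at)
    header = read_header(in_path)
    if config.samples_keep is not None:
        unknown = set(config.samples_keep) - set(header.sample_names)
        if unknown:
            raise ConfigError(
                f"samples_keep names unknown sample(s): {', '.join(sorted(unknown))}"
            )
    out_header = (
        header.subset_samples(config.samples_keep)
        if config.samples_keep is not None
        else header
    )
    out_path = Path(out_path)
    if compress is None:
        compress = out_path.name.endswith(".gz")
    runlog.info(f"input={in_path} output={out_path} workers={config.workers}")
    runlog.info(f"config={json.dumps(_config_summary(config), sort_keys=True)}")

    import gzip as _gzip

    opener = _gzip.open if compress else open
    try:
        with opener(out_path, "wt", encoding="utf-8", newline="") as out:  # type: ignore[operator]
            for line in out_header.meta_lines:
                out.write(line + "\n")
            out.write(out_header.column_line + "\n")
            if config.workers == 1:
                for start, lines in _iter_batches(in_path):
                    _init_worker(header, config)
                    kept_lines, drops, n_read = _process_batch((start, lines))
                    _accumulate(stats, kept_lines, drops, n_read, out)
            else:
                ctx = multiprocessing.get_context()
                with ctx.Pool(
                    processes=config.workers,
                    initializer=_init_worker,
                    initargs=(header, config),
                ) as pool:
                    for kept_lines, drops, n_read in pool.imap(
                        _process_batch, _iter_batches(in_path)
                    ):
                        _accumulate(stats, kept_lines, drops, n_read, out)
    except Exception as exc:
        if out_path.exists():
            out_path.unlink()
        runlog.error(str(exc))
        write_manifest(
            log_dir,
            "preprocess",
            started_at=runlog.started_at,
            inputs=[str(in_path)],
            outputs=[],
            error=str(exc),
            warnings=runlog.warnings,
        )
        raise

    stats.finished_at = datetime.now()
    runlog.info(
        f"records_read={stats.records_read} records_kept={stats.records_kept} "
        f"drops={stats.drops_by_criterion}"
    )
    write_manifest(
        log_dir,
        "preprocess",
        started_at=runlog.started_at,
        config=_config_summary(config),
        inputs=[str(in_path)],
        outputs=[str(out_path)],
        stats={
            "records_read": stats.records_read,
            "records_kept": stats.records_kept,
            "drops_by_criterion": stats.drops_by_criterion,
        },
        warnings=runlog.warnings,
    )
    return stats


def _accumulate(stats: FilterStats, kept_lines, drops, n_read, out) -> None:
    stats.records_read += n_read
    stats.records_kept += len(kept_lines)
    for k, v in drops.items():
        stats.drops_by_criterion[k] = stats.drops_by_criterion.get(k, 0) + v
    for line in kept_lines:
        out.write(line + "\n")


def _config_summary(config: FilterConfig) -> dict:
    data = asdict(config)
    for key in ("gene_symbols", "ensembl_gene_ids", "variant_ids"):
        data[key] = sorted(data[key])
    return data


def default_workers() -> int:
    """Available CPU count — the recommended multi-process default."""
    return os.cpu_count() or 1
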