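"""Streaming VCF reader/writer with transparent compression handling.

Design points:

* Compression is sniffed from magic bytes, never from the filename, so
  mislabelled files (a gzipped ``.vcf``, a plain ``.vcf.gz``) parse fine.
  BGZF is recognised as the gzip dialect it is and read through the same
  code path.
* Dot-encoded missing values (``.`` in ID, QUAL, FILTER, INFO values and
  per-sample subfields) map to an explicit absent state (``None``),
  distinct from an empty string, so downstream filters stay well defined.
* Records stream one at a time; memory is bounded by a handful of
  records, not the file size.  :func:`plan_chunks` splits the data body
  on line boundaries (offsets in the *uncompressed* byte stream) so that
  chunks can be processed independently and re-concatenated losslessly.
* Coordinates stay 1-based throughout, as in the format itself.
* Parsing then serialising a record is byte-stable: the original QUAL
  spelling and per-sample field truncation are preserved.
"""

from __future__ import annotations

import gzip
import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from varcurate.errors import FormatError, InputOutputError

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Sentinel stored in an INFO map for a valueless flag key.
FLAG = True

_GZIP_MAGIC = b"\x1f\x8b"

_META_DEF_RE = re.compile(
    r"##(?P<kind>INFO|FORMAT)=<ID=(?P<id>[^,>]+),Number=(?P<number>[^,>]+),"
    r"Type=(?P<type>[^,>]+),Description=\"(?P<desc>.*)\""
)


def detect_compression(path: PathLike) -> str:
    """Classify a file as ``plain``, ``gzip`` or ``bgzf`` from its magic bytes.

    BGZF files carry the standard gzip magic plus an extra subfield with
    identifier ``BC``; they are readable by any gzip decompressor.
    """
    try:
        with open(path, "rb") as fh:
            head = fh.read(18)
    except OSError as exc:
        raise InputOutputError(f"cannot read {path}: {exc}") from exc
    if head[:2] != _GZIP_MAGIC:
        return "plain"
    # FLG.FEXTRA set and an extra subfield SI1=66, SI2=67 marks BGZF.
    if len(head) >= 18 and head[3] & 0x04 and head[12:14] == b"BC":
        return "bgzf"
    return "gzip"


def open_text(path: PathLike) -> IO[str]:
    """Open a VCF for reading, decompressing transparently."""
    kind = detect_compression(path)
    if kind == "plain":
        return open(path, "rt", encoding="utf-8", newline="")
    return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8", newline="")


@dataclass
class VcfHeader:
    """Parsed VCF meta-information plus the ``#CHROM`` column line.

    ``ann_subfield_names`` holds the pipe-separated subfield names parsed
    out of the ANN INFO Description (the functional-annotation convention
    used by SnpEff-style annotators); it is empty when no ANN definition
    is present.
    """

    fileformat_version: str
    meta_lines: list[str] = field(default_factory=list)
    info_definitions: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    format_definitions: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    sample_names: list[str] = field(default_factory=list)
    ann_subfield_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.sample_names)) != len(self.sample_names):
            raise FormatError("duplicate sample names in header")

    @property
    def column_line(self) -> str:
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if self.sample_names:
            cols.append("FORMAT")
            cols.extend(self.sample_names)
        return "\t".join(cols)

    def add_info_definition(self, key: str, number: str, type_: str, desc: str) -> None:
        """Append an INFO definition (used when annotation adds new keys)."""
        if key in self.info_definitions:
            return
        self.info_definitions[key] = (number, type_, desc)
        self.meta_lines.append(
            f'##INFO=<ID={key},Number={number},Type={type_},Description="{desc}">'
        )

    def subset_samples(self, keep: list[str]) -> "VcfHeader":
        """A copy of this header restricted to ``keep`` (original order)."""
        kept = [s for s in self.sample_names if s in set(keep)]
        return VcfHeader(
            fileformat_version=self.fileformat_version,
            meta_lines=list(self.meta_lines),
            info_definitions=dict(self.info_definitions),
            format_definitions=dict(self.format_definitions),
            sample_names=kept,
            ann_subfield_names=list(self.ann_subfield_names),
        )


def _parse_ann_subfields(description: str) -> list[str]:
    # SnpEff quotes the subfield list in single quotes inside the
    # Description; fall back to the whole description if unquoted.
    m = re.search(r"'([^']+)'", description)
    inner = m.group(1) if m else description
    if "|" not in inner:
        return []
    return [part.strip() for part in inner.split("|")]


def read_header(source: Union[PathLike, IO[str]]) -> VcfHeader:
    """Parse the ``##`` meta lines and the ``#CHROM`` line of a VCF.

    Raises :class:`FormatError` when the file does not start with
    ``##fileformat`` or lacks a ``#CHROM`` line.
    """
    if hasattr(source, "readline"):
        return _read_header_stream(source)  # type: ignore[arg-type]
    with open_text(source) as fh:
        return _read_header_stream(fh)


def _read_header_stream(fh: IO[str]) -> VcfHeader:
    meta_lines: list[str] = []
    info_defs: dict[str, tuple[str, str, str]] = {}
    format_defs: dict[str, tuple[str, str, str]] = {}
    ann_subfields: list[str] = []
    fileformat = ""
    first = True
    for raw in fh:
        line = raw.rstrip("\n")
        if first:
            if not line.startswith("##fileformat"):
                raise FormatError("VCF must begin with a ##fileformat line")
            fileformat = line.split("=", 1)[1] if "=" in line else ""
            first = False
        if line.startswith("##"):
            meta_lines.append(line)
            m = _META_DEF_RE.match(line)
            if m:
                entry = (m.group("number"), m.group("type"), m.group("desc"))
                if m.group("kind") == "INFO":
                    info_defs[m.group("id")] = entry
                    if m.group("id") == "ANN":
                        ann_subfields = _parse_ann_subfields(m.group("desc"))
                else:
                    format_defs[m.group("id")] = entry
            continue
        if line.startswith("#CHROM"):
            cols = line.split("\t")
            samples = cols[9:] if len(cols) > 9 else []
            return VcfHeader(
                fileformat_version=fileformat,
                meta_lines=meta_lines,
                info_definitions=info_defs,
                format_definitions=format_defs,
                sample_names=samples,
                ann_subfield_names=ann_subfields,
            )
        raise FormatError("unexpected line before #CHROM header")
    raise FormatError("missing #CHROM header line")


@dataclass
class VariantRecord:
    """One VCF data line.

    ``info`` preserves key order; a valueless flag is stored as
    :data:`FLAG` and a dot-missing value (``key=.``) as ``None``.
    ``samples`` holds one ordered map per sample column; subfields given
    as ``.`` are stored as ``None`` and trailing subfields a sample omits
    are simply not present in its map.
    """

    chrom: str
    pos: int
    id: str | None
    ref: str
    alt: list[str]
    qual: float | None
    filter: str
    info: dict[str, Union[str, bool, None]] = field(default_factory=dict)
    format_keys: list[str] = field(default_factory=list)
    samples: list[dict[str, str | None]] = field(default_factory=list)
    qual_text: str | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"POS must be >= 1, got {self.pos}")
        if not self.ref:
            raise FormatError("REF must be non-empty")
        if not self.alt:
            raise FormatError("ALT must be a non-empty list")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, first alt) — convenience for joins."""
        return (self.chrom, self.pos, self.ref, self.alt[0])

    def info_value(self, key: str) -> str | None:
        """The textual value of an INFO key, or None for flags/missing."""
        val = self.info.get(key)
        return val if isinstance(val, str) else None

    def sample_value(self, sample_index: int, fmt_key: str) -> str | None:
        return self.samples[sample_index].get(fmt_key)

    def serialize(self) -> str:
        """Render this record back to a tab-separated VCF data line."""
        if self.qual is None:
            qual = "."
        elif self.qual_text is not None:
            qual = self.qual_text
        else:
            qual = format(self.qual, "g")
        info_parts = []
        for k, v in self.info.items():
            if v is FLAG:
                info_parts.append(k)
            elif v is None:
                info_parts.append(f"{k}=.")
            else:
                info_parts.append(f"{k}={v}")
        fields = [
            self.chrom,
            str(self.pos),
            self.id if self.id is not None else ".",
            self.ref,
            ",".join(self.alt),
            qual,
            self.filter,
            ";".join(info_parts) if info_parts else ".",
        ]
        if self.format_keys:
            fields.append(":".join(self.format_keys))
            for sample in self.samples:
                keys = self.format_keys[: len(sample)] if sample else self.format_keys[:1]
                rendered = [sample.get(k) if sample.get(k) is not None else "." for k in keys]
                fields.append(":".join(rendered) if sample else ".")
        return "\t".join(fields)


def parse_record(
    line: str,
    header: VcfHeader | None = None,
    line_number: int | None = None,
) -> VariantRecord:
    """Parse one data line into a :class:`VariantRecord`.

    When ``header`` is given, undeclared INFO/FORMAT keys are tolerated
    with a logged warning and the sample count is checked.
    """
    where = f" (line {line_number})" if line_number is not None else ""
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 8:
        raise FormatError(
            f"malformed record: expected >= 8 tab-separated fields, got {len(cols)}{where}"
        )
    chrom, pos_s, id_s, ref, alt_s, qual_s, filter_s, info_s = cols[:8]
    try:
        pos = int(pos_s)
    except ValueError as exc:
        raise FormatError(f"non-integer POS {pos_s!r}{where}") from exc

    info: dict[str, Union[str, bool, None]] = {}
    if info_s != ".":
        for item in info_s.split(";"):
            if not item:
                continue
            if "=" in item:
                k, v = item.split("=", 1)
                info[k] = None if v == "." else v
            else:
                info[item] = FLAG
            if header is not None and item.split("=", 1)[0] not in header.info_definitions:
                logger.warning("undeclared INFO key %r%s", item.split("=", 1)[0], where)

    format_keys: list[str] = []
    samples: list[dict[str, str | None]] = []
    if len(cols) > 8:
        format_keys = cols[8].split(":")
        if header is not None:
            for k in format_keys:
                if k not in header.format_definitions:
                    logger.warning("undeclared FORMAT key %r%s", k, where)
        for col in cols[9:]:
            subfields = col.split(":")
            samples.append(
                {
                    format_keys[i]: (None if sub == "." else sub)
                    for i, sub in enumerate(subfields)
                    if i < len(format_keys)
                }
            )
    if header is not None and header.sample_names and len(samples) != len(header.sample_names):
        raise FormatError(
            f"record has {len(samples)} sample columns, header declares "
            f"{len(header.sample_names)}{where}"
        )

    qual = None if qual_s == "." else float(qual_s)
    if qual is not None and qual < 0:
        raise FormatError(f"negative QUAL {qual_s!r}{where}")
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        id=None if id_s == "." else id_s,
        ref=ref,
        alt=alt_s.split(","),
        qual=qual,
        filter=filter_s,
        info=info,
        format_keys=format_keys,
        samples=samples,
        qual_text=None if qual_s == "." else qual_s,
    )


def iter_records(path: PathLike, header: VcfHeader | None = None) -> Iterator[VariantRecord]:
    """Yield records in file order, holding O(1) records in memory."""
    if header is None:
        header = read_header(path)
    with open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if raw.startswith("#") or not raw.strip():
                continue
            yield parse_record(raw, header, line_number=lineno)


def write_vcf(
    path: PathLike,
    header: VcfHeader,
    records: Iterable[VariantRecord],
    compress: bool | None = None,
) -> Path:
    """Write a VCF; ``compress=None`` infers gzip from a ``.gz`` suffix.

    Raises :class:`FormatError` when a record's sample count disagrees
    with the header.
    """
    path = Path(path)
    if compress is None:
        compress = path.name.endswith(".gz")
    opener = gzip.open if compress else open
    n_samples = len(header.sample_names)
    with opener(path, "wt", encoding="utf-8", newline="") as fh:  # type: ignore[operator]
        for line in header.meta_lines:
            fh.write(line + "\n")
        fh.write(header.column_line + "\n")
        for rec in records:
            if n_samples and len(rec.samples) != n_samples:
                raise FormatError(
                    f"record at {rec.chrom}:{rec.pos} has {len(rec.samples)} samples, "
                    f"header declares {n_samples}"
                )
            fh.write(rec.serialize() + "\n")
    return path


@dataclass
class ChunkPlan:
    """A partition of a VCF data body into contiguous line-aligned chunks.

    ``boundaries`` holds ``(start_offset, end_offset, n_records)`` spans
    measured in the uncompressed byte stream; concatenating the chunks in
    order reproduces the record sequence exactly.
    """

    chunk_count: int
    boundaries: list[tuple[int, int, int]]
    total_records: int


def plan_chunks(path: PathLike, target_chunk_count: int) -> ChunkPlan:
    """Split the data body into up to ``target_chunk_count`` chunks.

    Boundaries fall only between data lines.  A file with fewer records
    than chunks yields fewer (possibly one) chunks.
    """
    if target_chunk_count < 1:
        raise ValueError("target_chunk_count must be >= 1")
    line_offsets: list[int] = []
    offset = 0
    with open_text(path) as fh:
        for raw in fh:
            if not raw.startswith("#") and raw.strip():
                line_offsets.append(offset)
            offset += len(raw.encode("utf-8"))
        end = offset
    total = len(line_offsets)
    if total == 0:
        return ChunkPlan(chunk_count=0, boundaries=[], total_records=0)
    n_chunks = min(target_chunk_count, total)
    per = total / n_chunks
    boundaries: list[tuple[int, int, int]] = []
    starts = [round(i * per) for i in range(n_chunks)] + [total]
    for i in range(n_chunks):
        lo, hi = starts[i], starts[i + 1]
        if lo >= hi:
            continue
        start_off = line_offsets[lo]
        end_off = line_offsets[hi] if hi < total else end
        boundaries.append((start_off, end_off, hi - lo))
    return ChunkPlan(chunk_count=len(boundaries), boundaries=boundaries, total_records=total)


def read_chunk(
    path: PathLike, header: VcfHeader, span: tuple[int, int, int]
) -> Iterator[VariantRecord]:
    """Yield the records inside one :class:`ChunkPlan` span."""
    start, stop, _ = span
    kind = detect_compression(path)
    fh: IO[bytes] = open(path, "rb") if kind == "plain" else gzip.open(path, "rb")
    with fh:
        fh.seek(start)
        consumed = start
        for raw in fh:
            if consumed >= stop:
                break
            yield parse_record(raw.decode("utf-8"), header)
            consumed += len(raw)
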