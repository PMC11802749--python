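"""Timestamped per-run log files and run manifests.

Every pipeline stage can attach a :class:`RunLog`; one file is created
per run, named by the ISO-8601 start time, and a JSON manifest is written
on both success and failure so runs can be audited and replicated.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path
from typing import Any


def _now() -> _dt.datetime:
    return _dt.datetime.now()


class RunLog:
    """Append-only timestamped log for one execution."""

    def __init__(self, log_dir: str | Path | None, stage: str) -> None:
        self.stage = stage
        self.started_at = _now()
        self.lines: list[str] = []
        self.warnings: list[str] = []
        self.path: Path | None = None
        if log_dir is not None:
            log_dir = Path(log_dir)
            log_dir.mkdir(parents=True, exist_ok=True)
            stamp = self.started_at.strftime("%Y%m%dT%H%M%S.%f")
            self.path = log_dir / f"{stage}-{stamp}.log"
        self.info(f"stage {stage} started")

    def _emit(self, level: str, message: str) -> None:
        line = f"{_now().isoformat()} {level} {message}"
        self.lines.append(line)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")

    def info(self, message: str) -> None:
        self._emit("INFO", message)

    def warning(self, message: str) -> None:
        self.warnings.append(message)
        self._emit("WARNING", message)

    def error(self, message: str) -> None:
        self._emit("ERROR", message)


def write_manifest(
    log_dir: str | Path | None,
    stage: str,
    *,
    started_at: _dt.datetime,
    config: dict[str, Any] | None = None,
    inputs: list[str] | None = None,
    outputs: list[str] | None = None,
    stats: dict[str, Any] | None = None,
    warnings: list[str] | None = None,
    error: str | None = None,
    tool_version: str | None = None,
) -> Path | None:
    """Write a JSON run manifest; returns its path (None without a log dir)."""
    if log_dir is None:
        return None
    log_dir = Path(log_dir)
    log_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool_version": tool_version,
        "subcommand": stage,
        "started_at": started_at.isoformat(),
        "finished_at": _now().isoformat(),
        "config": config,
        "inputs": inputs or [],
        "outputs": outputs or [],
        "stats": stats or {},
        "warnings": warnings or [],
        "error": error,
        "success": error is None,
    }
    path = log_dir / f"{stage}-{started_at.strftime('%Y%m%dT%H%M%S.%f')}-manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return path
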