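"""Text trace formats (ATF 1.0 dialect and CSV) and run configuration.

Traces are stored as a time column plus one column per sweep, floats
formatted with %.6g so output is byte-deterministic for fixed input.
Metadata round-trips through the ATF header records ("key=value" strings)
or CSV comment lines.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Literal

import numpy as np
import yaml

from .gating import CurrentTrace

__all__ = ["read_trace", "write_trace", "RunConfig", "TraceFormatError"]

_FLOAT_FMT = "%.6g"


class TraceFormatError(ValueError):
    """Malformed trace file; message names the offending line."""


def _format_value(v) -> str:
    if isinstance(v, float):
        return _FLOAT_FMT % v
    return str(v)


def _parse_meta_value(s: str):
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def write_trace(
    trace: CurrentTrace, path: str | Path, format: Literal["atf", "csv"] | None = None
) -> Path:
    """Write a trace as ATF 1.0 or CSV (format inferred from the suffix)."""
    path = Path(path)
    fmt = format or ("atf" if path.suffix.lower() == ".atf" else "csv")
    times = trace.times()
    n_sweeps = trace.n_sweeps
    meta_items = sorted(trace.metadata.items())
    rows = np.column_stack([times] + list(trace.sweeps))
    body = "\n".join(
        "\t".join(_FLOAT_FMT % x for x in row) for row in rows
    )
    if fmt == "atf":
        records = [f'"{k}={_format_value(v)}"' for k, v in meta_items]
        records.append(f'"SampleInterval_s={_FLOAT_FMT % trace.sample_interval}"')
        titles = "\t".join(
            ['"Time (s)"'] + [f'"Trace #{i + 1} (pA)"' for i in range(n_sweeps)]
        )
        header = "\n".join(
            ["ATF\t1.0", f"{len(records)}\t{n_sweeps + 1}", *records, titles]
        )
        path.write_text(header + "\n" + body + "\n")
    elif fmt == "csv":
        comments = [f"# {k}={_format_value(v)}" for k, v in meta_items]
        comments.append(f"# SampleInterval_s={_FLOAT_FMT % trace.sample_interval}")
        titles = ",".join(["time_s"] + [f"sweep_{i + 1:02d}_pa" for i in range(n_sweeps)])
        path.write_text(
            "\n".join(comments + [titles]) + "\n" + body.replace("\t", ",") + "\n"
        )
    else:
        raise ValueError(f"unknown trace format {fmt!r}")
    return path


def _read_atf(path: Path) -> CurrentTrace:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise TraceFormatError(f"{path}:1: missing ATF magic")
    if lines[0].split("\t")[1].strip() != "1.0":
        raise TraceFormatError(f"{path}:1: unsupported ATF version")
    try:
        n_records, n_cols = (int(x) for x in lines[1].split("\t"))
    except (ValueError, IndexError):
        raise TraceFormatError(f"{path}:2: malformed header counts") from None
    meta: dict = {}
    for i in range(n_records):
        rec = lines[2 + i].strip().strip('"')
        if "=" in rec:
            k, v = rec.split("=", 1)
            meta[k] = _parse_meta_value(v)
    data_start = 2 + n_records + 1  # skip the column-title line
    return _assemble(path, lines[data_start:], n_cols, meta, data_start)


def _read_csv(path: Path) -> CurrentTrace:
    lines = path.read_text().splitlines()
    meta: dict = {}
    i = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            break
        rec = line.lstrip("# ").strip()
        if "=" in rec:
            k, v = rec.split("=", 1)
            meta[k] = _parse_meta_value(v)
    header = lines[i].split(",")
    if not header or header[0] != "time_s":
        raise TraceFormatError(f"{path}:{i + 1}: expected 'time_s' header column")
    return _assemble(path, lines[i + 1:], len(header), meta, i + 1, sep=",")


def _assemble(path, data_lines, n_cols, meta, offset, sep="\t") -> CurrentTrace:
    rows = []
    for j, line in enumerate(data_lines):
        if not line.strip():
            continue
        parts = line.split(sep)
        if len(parts) != n_cols:
            raise TraceFormatError(
                f"{path}:{offset + j + 1}: expected {n_cols} columns, found {len(parts)}"
            )
        try:
            rows.append([float(x) for x in parts])
        except ValueError:
            raise TraceFormatError(f"{path}:{offset + j + 1}: non-numeric sample") from None
    if len(rows) < 2:
        raise TraceFormatError(f"{path}: fewer than two data rows")
    arr = np.asarray(rows)
    times = arr[:, 0]
    if np.any(np.diff(times) <= 0):
        raise TraceFormatError(f"{path}: time column is not strictly increasing")
    dt = meta.pop("SampleInterval_s", float(times[1] - times[0]))
    sweeps = [arr[:, k] for k in range(1, n_cols)]
    return CurrentTrace(float(dt), sweeps, metadata=meta)


def read_trace(path: str | Path) -> CurrentTrace:
    """Read an ATF 1.0 or CSV trace written by :func:`write_trace`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    first = path.open().readline()
    if first.startswith("ATF"):
        return _read_atf(path)
    if path.suffix.lower() == ".atf":
        raise TraceFormatError(f"{path}:1: missing ATF magic")
    return _read_csv(path)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Serializable description of one simulation/analysis run."""

    solutions: str = "standard"
    protocol: str = "tail"
    gating_preset: str = "wt"
    buffers: list[dict] = field(default_factory=list)
    qc: dict = field(default_factory=dict)
    seed: int = 0
    output: str = ""

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
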