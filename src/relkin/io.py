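"""Reading and writing cumulative-release tables.

The on-disk format is a small delimited-text table (comma, tab or
whitespace separated) with a mandatory header naming at least ``time`` and
``released`` columns and an optional ``sd`` column.  Comment lines start
with ``#`` and may carry ``key=value`` metadata; ``time_unit`` (minute,
hour or day) and ``label`` are recognised.  A parse-then-serialize round
trip preserves values to 12 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .estimation import ReleaseCurve
from .units import TimeUnit

__all__ = ["ReleaseTableError", "read_release_table", "write_release_table"]

logger = logging.getLogger(__name__)


class ReleaseTableError(ValueError):
    """Malformed release-table file (message names the offending line)."""


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_release_table(path: str | Path) -> ReleaseCurve:
    """Parse a release table into a validated :class:`ReleaseCurve`."""
    path = Path(path)
    metadata: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                for sep in ("=", ":"):
                    if sep in body:
                        key, _, value = body.partition(sep)
                        metadata.setdefault(key.strip().lower(), value.strip())
                        break
                continue
            fields = _split_row(line)
            if header is None:
                header = [f.lower() for f in fields]
                if "time" not in header or "released" not in header:
                    raise ReleaseTableError(
                        f"{path}:{lineno}: header must name 'time' and 'released' "
                        f"columns, got {fields!r}"
                    )
                continue
            rows.append((lineno, fields))
    if header is None:
        raise ReleaseTableError(f"{path}: no header row found")
    if not rows:
        raise ReleaseTableError(f"{path}: no data rows found")

    i_time = header.index("time")
    i_rel = header.index("released")
    i_sd = header.index("sd") if "sd" in header else None

    times, released, sds = [], [], []
    prev_t, prev_line = None, None
    for lineno, fields in rows:
        if len(fields) < len(header):
            raise ReleaseTableError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        try:
            t = float(fields[i_time])
            y = float(fields[i_rel])
            s = float(fields[i_sd]) if i_sd is not None else None
        except ValueError as exc:
            raise ReleaseTableError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
        if not np.isfinite(t) or not np.isfinite(y):
            raise ReleaseTableError(f"{path}:{lineno}: non-finite value")
        if t < 0:
            raise ReleaseTableError(f"{path}:{lineno}: negative time {t}")
        if prev_t is not None and t == prev_t:
            raise ReleaseTableError(
                f"{path}:{lineno}: duplicated time value {t} "
                f"(previously on line {prev_line})"
            )
        if prev_t is not None and t < prev_t:
            raise ReleaseTableError(
                f"{path}:{lineno}: time {t} is not increasing "
                f"(previous value {prev_t} on line {prev_line})"
            )
        prev_t, prev_line = t, lineno
        times.append(t)
        released.append(y)
        if s is not None:
            sds.append(s)

    if "time_unit" in metadata:
        try:
            unit = TimeUnit(metadata["time_unit"].lower())
        except ValueError as exc:
            raise ReleaseTableError(
                f"{path}: unknown time_unit {metadata['time_unit']!r}"
            ) from exc
    else:
        logger.warning("%s: no time_unit metadata, assuming hours", path)
        unit = TimeUnit.HOUR

    try:
        return ReleaseCurve(
            times=np.asarray(times),
            released=np.asarray(released),
            sd=np.asarray(sds) if sds else None,
            label=metadata.get("label", path.stem),
            time_unit=unit,
        )
    except ValueError as exc:
        raise ReleaseTableError(f"{path}: {exc}") from exc


def write_release_table(curve: ReleaseCurve, path: str | Path) -> None:
    """Serialize a curve as a commented CSV table (shortest exact float repr)."""
    path = Path(path)
    cols = ["time", "released"] + (["sd"] if curve.sd is not None else [])
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# time_unit={curve.time_unit.value}\n")
        if curve.label:
            fh.write(f"# label={curve.label}\n")
        fh.write(",".join(cols) + "\n")
        for i in range(curve.n):
            row = [repr(float(curve.times[i])), repr(float(curve.released[i]))]
            if curve.sd is not None:
                row.append(repr(float(curve.sd[i])))
            fh.write(",".join(row) + "\n")
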