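"""Tab-separated I/O for TACs, blood series, HPLC fraction tables, input
functions and fit tables.

All tables are UTF-8 TSV.  Lines starting with ``#`` carry ``key: value``
metadata (isotope, decay-correction flag, ...) and are written before the
header.  Written tables re-parse to identical values for finite entries.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .data import BloodSeries, FrameSchedule, TimeActivityCurve, ValidationError

__all__ = [
    "ParseError",
    "read_tac_table",
    "write_tac_table",
    "read_blood_table",
    "write_blood_table",
    "read_fit_table",
    "write_fit_table",
]


class ParseError(ValueError):
    """Malformed table; carries the 1-based line number where known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}" if path is not None else "<table>"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{loc}: {message}")
        self.line = line


def _read_table(path) -> tuple[pd.DataFrame, dict, int]:
    """Read a TSV with ``#`` metadata lines; returns (frame, meta, n_header_lines)."""
    path = Path(path)
    meta: dict[str, str] = {}
    n_meta = 0
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    for line in text.splitlines():
        if not line.startswith("#"):
            break
        n_meta += 1
        body = line.lstrip("#").strip()
        if ":" in body:
            key, _, val = body.partition(":")
            meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(
            _io.StringIO(text), sep="\t", comment="#", float_precision="round_trip"
        )
    except Exception as exc:  # malformed header / ragged rows
        raise ParseError(str(exc), path) from exc
    return df, meta, n_meta + 1  # meta lines + header line


def _write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Regional TAC tables: frame_start_s, frame_end_s, one column per region.
# ---------------------------------------------------------------------------

def write_tac_table(tacs: list[TimeActivityCurve], path, meta: dict | None = None) -> None:
    """Write frame-based TACs sharing one schedule to a region-per-column TSV."""
    if not tacs:
        raise ValueError("no curves to write")
    sched = tacs[0].schedule
    if sched is None:
        raise ValueError("write_tac_table expects frame-based curves")
    cols = {"frame_start_s": sched.start, "frame_end_s": sched.end}
    for tac in tacs:
        if tac.schedule is None or tac.schedule.n_frames != sched.n_frames or not np.allclose(
            tac.schedule.start, sched.start
        ):
            raise ValueError("all curves must share one frame schedule")
        cols[tac.region or f"region_{len(cols) - 1}"] = tac.activity
    base_meta = {"decay_corrected": str(all(t.decay_corrected for t in tacs)).lower()}
    base_meta.update(meta or {})
    _write_table(pd.DataFrame(cols), path, base_meta)


def read_tac_table(path) -> list[TimeActivityCurve]:
    """Read a region-per-column TAC TSV into one curve per region column.

    The frame schedule is validated (contiguity, positive durations); a
    violation is reported with the offending line number.
    """
    df, meta, header_lines = _read_table(path)
    for col in ("frame_start_s", "frame_end_s"):
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}", path)
    start = df["frame_start_s"].to_numpy(dtype=float)
    end = df["frame_end_s"].to_numpy(dtype=float)
    if np.any(end <= start):
        i = int(np.argmax(end <= start))
        raise ParseError("non-positive frame duration", path, header_lines + 1 + i)
    gaps = ~np.isclose(start[1:], end[:-1], rtol=0.0, atol=1e-9)
    if np.any(gaps):
        i = int(np.argmax(gaps)) + 1
        raise ParseError(
            "frames overlap or leave a gap (schedule must be contiguous)",
            path,
            header_lines + 1 + i,
        )
    try:
        sched = FrameSchedule(start=start, end=end)
    except ValidationError as exc:
        raise ParseError(str(exc), path) from exc
    corrected = meta.get("decay_corrected", "true").lower() != "false"
    out = []
    for col in df.columns:
        if col in ("frame_start_s", "frame_end_s"):
            continue
        act = df[col].to_numpy(dtype=float)
        out.append(
            TimeActivityCurve(
                activity=np.nan_to_num(act, nan=np.nan),
                schedule=sched,
                decay_corrected=corrected,
                region=str(col),
                missing=~np.isfinite(act),
            )
        )
    if not out:
        raise ParseError("no region columns found", path)
    return out


# ---------------------------------------------------------------------------
# Blood tables: time_s, whole_blood_kBq_ml, plasma_kBq_ml, source.
# ---------------------------------------------------------------------------

def write_blood_table(blood: BloodSeries, path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        {
            "time_s": blood.times,
            "whole_blood_kBq_ml": blood.whole_blood,
            "plasma_kBq_ml": blood.plasma,
            "source": blood.source,
        }
    )
    _write_table(df, path, meta)


def read_blood_table(path) -> BloodSeries:
    df, _, header_lines = _read_table(path)
    required = ("time_s", "whole_blood_kBq_ml", "plasma_kBq_ml", "source")
    for col in required:
        if col not in df.columns:
            raise ParseError(f"missing required column {col!r}", path)
    t = df["time_s"].to_numpy(dtype=float)
    src = df["source"].astype(str).to_numpy()
    for s in np.unique(src):
        ts = t[src == s]
        if ts.size > 1:
            d = np.diff(ts)
            if np.any(d <= 0):
                rows = np.flatnonzero(src == s)
                i = int(rows[int(np.argmax(d <= 0)) + 1])
                raise ParseError(
                    f"non-monotone times within source {s!r}", path, header_lines + 1 + i
                )
    try:
        return BloodSeries(
            times=t,
            whole_blood=df["whole_blood_kBq_ml"].to_numpy(dtype=float),
            plasma=df["plasma_kBq_ml"].to_numpy(dtype=float),
            source=src,
        )
    except ValidationError as exc:
        raise ParseError(str(exc), path) from exc


# ---------------------------------------------------------------------------
# Fit tables: plain DataFrame round-trip (region, model, estimates, %SE, QC).
# ---------------------------------------------------------------------------

def write_fit_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_table(table, path, meta)


def read_fit_table(path) -> pd.DataFrame:
    df, _, _ = _read_table(path)
    return df
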