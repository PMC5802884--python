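"""Reading, writing and schedule-alignment of count traces.

Traces travel as two-column delimited text (time_s, counts) at 0.1-s
steps, optionally preceded by ``#`` comment/header lines, with a JSON
metadata sidecar.  Schedules travel as YAML listing order index,
wavelength, level, start time and duration per segment.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .types import (
    BIN_WIDTH,
    AlignedTrial,
    CountTrace,
    ExposureSchedule,
    ExposureSegment,
)

__all__ = [
    "read_trace",
    "write_trace",
    "read_schedule",
    "write_schedule",
    "segment_trial",
]

logger = logging.getLogger(__name__)

_SPACING_TOL = 1e-6  # s


class TraceFormatError(ValueError):
    """A trace file violates the expected two-column 0.1-s format."""


class AlignmentError(ValueError):
    """A trace cannot be tiled by its schedule."""


def read_trace(path: Union[str, Path]) -> CountTrace:
    """Read a two-column (time_s, counts) trace file.

    Comment lines starting with ``#`` are ignored, so header-prefixed
    exports parse identically to bare ones.  Validates a uniform 0.1-s
    bin spacing (tolerance 1e-6 s) and non-negative counts; a JSON
    sidecar ``<path>.meta.json``, if present, populates the metadata.
    """
    path = Path(path)
    times: list[float] = []
    counts: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.replace(",", "\t").split()
            if len(fields) < 2:
                raise TraceFormatError(
                    f"{path}:{lineno}: expected two columns, got {stripped!r}"
                )
            try:
                t, c = float(fields[0]), float(fields[1])
            except ValueError as exc:
                raise TraceFormatError(f"{path}:{lineno}: non-numeric row") from exc
            if times and abs((t - times[-1]) - BIN_WIDTH) > _SPACING_TOL:
                raise TraceFormatError(
                    f"{path}:{lineno}: irregular bin spacing "
                    f"({t - times[-1]:.6g} s, expected {BIN_WIDTH} s)"
                )
            if c < 0:
                raise TraceFormatError(f"{path}:{lineno}: negative count {c}")
            times.append(t)
            counts.append(c)
    if not counts:
        raise TraceFormatError(f"{path}: no data rows")
    metadata = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return CountTrace(values=np.array(counts), t0=times[0], metadata=metadata)


def write_trace(
    trace: CountTrace, path: Union[str, Path], sidecar: bool = True
) -> Path:
    """Write a trace as two-column text with a ``#`` header line.

    Values round-trip bit-identically through :func:`read_trace` (times
    use 17 significant digits).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("# time_s\tcounts\n")
        for i, v in enumerate(trace.values):
            fh.write(f"{trace.t0 + i * BIN_WIDTH:.6f}\t{float(v)!r}\n")
    if sidecar and trace.metadata:
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta_path.write_text(json.dumps(trace.metadata, indent=2, default=str))
    return path


def write_schedule(schedule: ExposureSchedule, path: Union[str, Path]) -> Path:
    """Write a schedule as YAML (order index, wavelength, level, start, duration)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    starts = schedule.segment_starts()
    doc = {
        "seed": schedule.seed,
        "segments": [
            {
                "index": seg.index,
                "phase": seg.phase,
                "wavelength_nm": seg.wavelength,
                "level": seg.level,
                "start_s": float(start),
                "duration_s": float(seg.duration),
            }
            for seg, start in zip(schedule.segments, starts)
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_schedule(path: Union[str, Path]) -> ExposureSchedule:
    """Read a YAML schedule written by :func:`write_schedule`."""
    doc = yaml.safe_load(Path(path).read_text())
    segments = tuple(
        ExposureSegment(
            index=int(s["index"]),
            phase=s["phase"],
            wavelength=None if s.get("wavelength_nm") is None else int(s["wavelength_nm"]),
            level=s.get("level"),
            duration=float(s.get("duration_s", 60.0)),
        )
        for s in doc["segments"]
    )
    return ExposureSchedule(segments, seed=doc.get("seed"))


def segment_trial(
    trace: CountTrace, schedule: ExposureSchedule
) -> AlignedTrial:
    """Tile a trace into per-segment slices according to its schedule.

    Segment boundaries fall exactly on bin edges because all durations
    are multiples of the 0.1-s bin.  Trailing samples beyond the
    schedule are dropped with a warning; a trace shorter than the
    schedule raises :class:`AlignmentError` reporting the deficit.
    """
    needed = schedule.n_bins
    have = len(trace)
    if have < needed:
        deficit = (needed - have) * BIN_WIDTH
        raise AlignmentError(
            f"trace ({have * BIN_WIDTH:.1f} s) is {deficit:.1f} s shorter "
            f"than its schedule ({needed * BIN_WIDTH:.1f} s)"
        )
    if have > needed:
        extra = have - needed
        msg = f"dropping {extra} trailing bins ({extra * BIN_WIDTH:.1f} s) beyond the schedule"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    slices = []
    cursor = 0
    for seg in schedule.segments:
        slices.append((cursor, cursor + seg.n_bins))
        cursor += seg.n_bins
    return AlignedTrial(trace=trace, schedule=schedule, slices=tuple(slices))
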