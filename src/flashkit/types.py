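"""Core domain containers for flash-train recordings and exposure schedules.

The experimental unit is a single restrained firefly recorded by a
spectrometer at a fixed 100-ms averaging interval while an overhead LED
steps through a schedule of dark and monochromatic-light segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

#: Width of one spectrometer averaging bin, in seconds.
BIN_WIDTH = 0.1

#: The eight stimulus wavelengths (nm), near-UV through red.
DEFAULT_WAVELENGTHS = (444, 463, 488, 515, 533, 597, 628, 663)

#: Stimulus intensity levels; "bright" is one order of magnitude above "dim".
LEVELS = ("dim", "bright")


class ScheduleError(ValueError):
    """An exposure schedule violates its structural invariants."""


@dataclass(frozen=True)
class ExposureSegment:
    """One contiguous dark or light segment of a trial.

    Parameters
    ----------
    index : int
        1-based ordinal position within the trial.
    phase : {"dark", "light"}
    wavelength : int, optional
        Stimulus wavelength in nm; required for light segments, forbidden
        for dark segments.
    level : {"dim", "bright"}, optional
        Stimulus intensity level; required for light, forbidden for dark.
    duration : float
        Segment length in seconds (default 60).
    """

    index: int
    phase: str
    wavelength: Optional[int] = None
    level: Optional[str] = None
    duration: float = 60.0

    def __post_init__(self) -> None:
        if self.phase not in ("dark", "light"):
            raise ScheduleError(f"unknown phase {self.phase!r}")
        if self.duration <= 0:
            raise ScheduleError("segment duration must be positive")
        if self.phase == "light":
            if self.wavelength is None or self.level is None:
                raise ScheduleError("light segments need wavelength and level")
            if self.level not in LEVELS:
                raise ScheduleError(f"unknown level {self.level!r}")
        else:
            if self.wavelength is not None or self.level is not None:
                raise ScheduleError("dark segments carry no wavelength/level")

    @property
    def is_light(self) -> bool:
        return self.phase == "light"

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / BIN_WIDTH))


@dataclass(frozen=True)
class ExposureSchedule:
    """Ordered dark/light segments making up one trial.

    Invariants (checked by :meth:`validate`): segments strictly alternate
    dark and light starting dark; each (wavelength, level) pair occurs
    exactly once; the two levels of a wavelength occupy consecutive light
    slots (each wavelength forms a dark-light-dark-light block).
    """

    segments: tuple[ExposureSegment, ...]
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        segs = self.segments
        if not segs:
            raise ScheduleError("schedule has no segments")
        for pos, seg in enumerate(segs, start=1):
            if seg.index != pos:
                raise ScheduleError(f"segment index {seg.index} at position {pos}")
            want = "dark" if pos % 2 == 1 else "light"
            if seg.phase != want:
                raise ScheduleError(
                    f"segment {pos} is {seg.phase}, expected {want} "
                    "(dark and light must alternate, dark first)"
                )
        lights = self.light_segments
        pairs = [(s.wavelength, s.level) for s in lights]
        if len(set(pairs)) != len(pairs):
            raise ScheduleError("duplicate (wavelength, level) exposure")
        # both levels of a wavelength must be adjacent among light slots
        for i in range(0, len(lights) - 1, 2):
            if lights[i].wavelength != lights[i + 1].wavelength:
                raise ScheduleError(
                    "dim and bright exposures of a wavelength must be consecutive"
                )

    @property
    def light_segments(self) -> list[ExposureSegment]:
        return [s for s in self.segments if s.is_light]

    @property
    def total_duration(self) -> float:
        """Trial length in seconds."""
        return float(sum(s.duration for s in self.segments))

    @property
    def n_bins(self) -> int:
        return sum(s.n_bins for s in self.segments)

    def segment_starts(self) -> list[float]:
        """Start time (s) of every segment, in order."""
        starts, t = [], 0.0
        for seg in self.segments:
            starts.append(t)
            t += seg.duration
        return starts

    def light_order(self) -> dict[int, int]:
        """Map segment index -> 1-based order among light exposures."""
        return {s.index: k for k, s in enumerate(self.light_segments, start=1)}


@dataclass
class CountTrace:
    """A photometric count series sampled at fixed 100-ms bins.

    ``values[i]`` is the average relative intensity (counts) over the bin
    ``[t0 + i*0.1, t0 + (i+1)*0.1)`` seconds.
    """

    values: np.ndarray
    t0: float = 0.0
    bin_width: float = BIN_WIDTH
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if abs(self.bin_width - BIN_WIDTH) > 1e-9:
            raise ValueError(f"bin width must be {BIN_WIDTH} s")
        if np.any(self.values < 0):
            raise ValueError("counts must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Trace length in seconds."""
        return len(self.values) * self.bin_width

    @property
    def times(self) -> np.ndarray:
        """Left edge (s) of every bin."""
        return self.t0 + np.arange(len(self.values)) * self.bin_width


@dataclass(frozen=True)
class FlashEvent:
    """One detected flash: an above-floor run of bins and its peak."""

    peak_bin: int
    peak_time: float
    peak_counts: float
    onset_bin: int
    offset_bin: int

    def __post_init__(self) -> None:
        if not (self.onset_bin <= self.peak_bin <= self.offset_bin):
            raise ValueError("peak must lie within [onset, offset]")

    @property
    def duration_ms(self) -> float:
        """Flash duration: number of above-floor bins times 100 ms."""
        return (self.offset_bin - self.onset_bin + 1) * BIN_WIDTH * 1000.0


@dataclass(frozen=True)
class MorphologySummary:
    """Per-segment flash morphology statistics.

    Means are computed only over detected events; ``mean_peak_intensity``
    and ``mean_duration_ms`` are ``None`` when no flash was detected, and
    ``mean_ipi_ms`` is ``None`` with fewer than two flashes.  A segment in
    which the specimen ceased flashing therefore propagates missing values,
    never zeros.
    """

    n_flashes: int
    flash_rate: float
    effective_duration_s: float
    mean_peak_intensity: Optional[float] = None
    mean_duration_ms: Optional[float] = None
    mean_ipi_ms: Optional[float] = None


@dataclass(frozen=True)
class AlignedTrial:
    """A trace tiled into per-segment slices by its schedule.

    ``slices[k] = (start, end)`` are 0-based half-open bin indices of
    segment ``k``; consecutive slices abut, so concatenating them
    reproduces the trace prefix exactly.
    """

    trace: CountTrace
    schedule: ExposureSchedule
    slices: tuple[tuple[int, int], ...]

    def segment_values(self, k: int) -> np.ndarray:
        start, end = self.slices[k]
        return self.trace.values[start:end]

    def __iter__(self):
        for seg, (start, end) in zip(self.schedule.segments, self.slices):
            yield seg, self.trace.values[start:end]


def as_sequence(x: Sequence[int]) -> tuple[int, ...]:
    return tuple(int(v) for v in x)
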