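"""Flash detection and morphology statistics for photometric count traces.

The per-segment pipeline: drop the 15-s adaptation window after each
illumination change, zero the recording against its own baseline (the
spectrometer's noise pedestal), then isolate flash peaks as local maxima
of contiguous runs of bins above the 200-count noise floor.  Counts at
or below the floor are treated as noise and never contribute events.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import BIN_WIDTH, AlignedTrial, CountTrace, FlashEvent, MorphologySummary

__all__ = [
    "trim_adaptation",
    "zero_baseline",
    "detect_flashes",
    "summarize_morphology",
    "morphology_table",
]

#: Counts at or below this value are excluded as spectrometer noise.
DEFAULT_NOISE_FLOOR = 200.0

#: Adaptation window discarded at the start of every segment, seconds.
DEFAULT_ADAPTATION_S = 15.0

#: Two peaks within one above-floor run are separate flashes only if the
#: valley between them drops below this fraction of the smaller peak.
SPLIT_DIP_FRACTION = 0.5


def _values(trace: Union[CountTrace, np.ndarray, Sequence[float]]) -> np.ndarray:
    if isinstance(trace, CountTrace):
        return trace.values
    return np.asarray(trace, dtype=float)


def trim_adaptation(
    trace: Union[CountTrace, np.ndarray],
    adaptation_s: float = DEFAULT_ADAPTATION_S,
) -> np.ndarray:
    """Drop the first ``adaptation_s`` seconds of a segment trace.

    The window after an illumination change, during which the specimen
    re-adapts, is excluded from analysis.  Raises ``ValueError`` if the
    segment is not strictly longer than the adaptation window.
    """
    x = _values(trace)
    if adaptation_s < 0:
        raise ValueError("adaptation window must be non-negative")
    n_drop = int(round(adaptation_s / BIN_WIDTH))
    if len(x) <= n_drop:
        raise ValueError(
            f"segment of {len(x) * BIN_WIDTH:.1f} s is not longer than the "
            f"{adaptation_s:.1f} s adaptation window"
        )
    return x[n_drop:]


def zero_baseline(
    trace: Union[CountTrace, np.ndarray],
    method: Literal["percentile", "min"] = "percentile",
    percentile: float = 5.0,
) -> np.ndarray:
    """Zero a recording against its own baseline estimate.

    The baseline is the ``percentile``-th percentile of the recording's
    values (default 5th — robust as long as flashes occupy a minority of
    bins), or the minimum with ``method="min"``.  The estimate is
    subtracted from every bin and negatives are clipped to zero.
    """
    x = _values(trace)
    if x.size == 0:
        raise ValueError("cannot zero an empty trace")
    if method == "percentile":
        baseline = float(np.percentile(x, percentile))
    elif method == "min":
        baseline = float(x.min())
    else:
        raise ValueError(f"unknown zeroing method {method!r}")
    return np.clip(x - baseline, 0.0, None)


def _local_maxima(x: np.ndarray) -> list[int]:
    """Strict local maxima of a short array; plateaus yield their first bin.

    Array boundaries count as lower neighbours, so a monotone run has a
    single maximum at its higher end.
    """
    peaks: list[int] = []
    i, n = 0, len(x)
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        left_ok = i == 0 or x[i - 1] < x[i]
        right_ok = j == n - 1 or x[j + 1] < x[i]
        if left_ok and right_ok:
            peaks.append(i)  # earliest bin of a plateau wins
        i = j + 1
    return peaks


def detect_flashes(
    trace: Union[CountTrace, np.ndarray],
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    split_dip_fraction: float = SPLIT_DIP_FRACTION,
    t0: float = 0.0,
) -> list[FlashEvent]:
    """Detect flash events in a zeroed trace.

    A candidate event is a maximal contiguous run of bins strictly above
    ``noise_floor`` (a bin equal to the floor is noise).  Each run
    contributes one event per retained local maximum: two maxima within
    a run are distinct flashes only when the valley between them falls
    below ``split_dip_fraction`` of the smaller maximum, in which case
    the run is split at the valley bin (the valley bin closes the
    earlier event).  Events are returned in time order.
    """
    x = _values(trace)
    above = x > noise_floor
    if not above.any():
        return []
    # run boundaries of the above-floor mask
    padded = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    run_starts = np.flatnonzero(padded == 1)
    run_ends = np.flatnonzero(padded == -1)  # exclusive

    events: list[FlashEvent] = []
    for start, end in zip(run_starts, run_ends):
        run = x[start:end]
        maxima = _local_maxima(run)
        # merge maxima not separated by a deep enough valley
        groups: list[tuple[int, int]] = []  # (peak_idx, event_start) within run
        seg_start = 0
        peak = maxima[0]
        for cand in maxima[1:]:
            valley_slice = run[peak + 1 : cand]
            valley = valley_slice.min() if valley_slice.size else run[cand]
            if valley < split_dip_fraction * min(run[peak], run[cand]):
                split = peak + 1 + int(np.argmin(valley_slice))
                groups.append((peak, seg_start))
                seg_start = split + 1  # valley bin closes the earlier event
                peak = cand
            elif run[cand] > run[peak]:
                peak = cand
        groups.append((peak, seg_start))
        for k, (peak_idx, ev_start) in enumerate(groups):
            ev_end = groups[k + 1][1] - 1 if k + 1 < len(groups) else len(run) - 1
            events.append(
                FlashEvent(
                    peak_bin=start + peak_idx,
                    peak_time=t0 + (start + peak_idx) * BIN_WIDTH,
                    peak_counts=float(run[peak_idx]),
                    onset_bin=start + ev_start,
                    offset_bin=start + ev_end,
                )
            )
    return events


def summarize_morphology(
    events: Sequence[FlashEvent],
    effective_duration_s: float,
    per_minute: bool = True,
) -> MorphologySummary:
    """Summarize detected flashes of one segment.

    ``flash_rate`` is the event count normalized to peaks/min over the
    effective (post-trim) window, or the raw count with
    ``per_minute=False``.  Interpulse interval is measured from the
    offset of one flash to the onset of the next.  With no events the
    rate is 0 and intensity/duration/IPI are absent (``None``), so
    cessation propagates as missing data, never as zero intensity.
    """
    if effective_duration_s <= 0:
        raise ValueError("effective duration must be positive")
    n = len(events)
    rate = n * 60.0 / effective_duration_s if per_minute else float(n)
    if n == 0:
        return MorphologySummary(
            n_flashes=0, flash_rate=rate, effective_duration_s=effective_duration_s
        )
    mean_peak = float(np.mean([e.peak_counts for e in events]))
    mean_dur = float(np.mean([e.duration_ms for e in events]))
    mean_ipi: Optional[float] = None
    if n >= 2:
        ipis = [
            (events[k + 1].onset_bin - events[k].offset_bin) * BIN_WIDTH * 1000.0
            for k in range(n - 1)
        ]
        mean_ipi = float(np.mean(ipis))
    return MorphologySummary(
        n_flashes=n,
        flash_rate=rate,
        effective_duration_s=effective_duration_s,
        mean_peak_intensity=mean_peak,
        mean_duration_ms=mean_dur,
        mean_ipi_ms=mean_ipi,
    )


def morphology_table(
    trial: AlignedTrial,
    specimen: Optional[str] = None,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    adaptation_s: float = DEFAULT_ADAPTATION_S,
    zero_method: Literal["percentile", "min"] = "percentile",
    per_minute: bool = True,
) -> pd.DataFrame:
    """Run trim -> zero -> detect -> summarize over every segment.

    Returns one row per segment: specimen, segment_index, phase,
    wavelength, level, light_order (1-based order among light exposures,
    NA for dark), the morphology statistics and the effective duration.
    Missing statistics (cessation) stay NaN.
    """
    order = trial.schedule.light_order()
    rows = []
    for seg, values in trial:
        trimmed = trim_adaptation(values, adaptation_s)
        zeroed = zero_baseline(trimmed, method=zero_method)
        events = detect_flashes(zeroed, noise_floor=noise_floor)
        effective = seg.duration - adaptation_s
        summary = summarize_morphology(events, effective, per_minute=per_minute)
        rows.append(
            {
                "specimen": specimen
                or trial.trace.metadata.get("specimen", "specimen_01"),
                "segment_index": seg.index,
                "phase": seg.phase,
                "wavelength": seg.wavelength,
                "level": seg.level,
                "light_order": order.get(seg.index),
                "n_flashes": summary.n_flashes,
                "mean_peak_intensity": summary.mean_peak_intensity,
                "flash_rate": summary.flash_rate,
                "mean_duration_ms": summary.mean_duration_ms,
                "mean_ipi_ms": summary.mean_ipi_ms,
                "effective_duration_s": summary.effective_duration_s,
            }
        )
    df = pd.DataFrame(rows)
    df["light_order"] = df["light_order"].astype("Float64")
    return df
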