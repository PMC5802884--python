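"""Synthetic spectrometer recordings of firefly alarm-flash trains.

The generator emulates the study conditions: a restrained male firefly
emits fast alarm flashes (~200 ms wide, 200-300 ms gaps) in bursts
separated by sporadic pauses, recorded as 100-ms-averaged counts while a
schedule of 1-min dark and monochromatic-light segments plays overhead.
Ambient light modulates behavior through a :class:`ResponseProfile` of
per-(wavelength, level) intensity and frequency multipliers plus a
cessation probability (specimens sometimes stop signaling entirely under
bright short-wavelength light).

Flash timing is a two-state burst/pause renewal process.  Within a
burst, successive onsets are separated by the pulse duration plus a
uniform gap.  Burst lengths are geometric; pause lengths exponential,
with the pause mean solved in closed form so the long-run flash rate
equals ``base_rate`` times the current frequency multiplier.  Frequency
multipliers below one also shorten the mean burst length in proportion
(floor of one flash), so that reduced signaling manifests as sparser,
shorter bursts with longer pauses rather than as rarer full-length
bursts — matching the observed rise in interpulse interval under light
and keeping per-segment rates estimable.

All randomness flows from a single seed through ``numpy``
``SeedSequence`` spawning: one child stream each for cessation draws,
flash timing/amplitude, and detector noise, so e.g. disabling noise does
not perturb flash placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import reference
from .types import (
    BIN_WIDTH,
    DEFAULT_WAVELENGTHS,
    CountTrace,
    ExposureSchedule,
    ExposureSegment,
    ScheduleError,
)

__all__ = [
    "FlashKinetics",
    "ResponseCell",
    "ResponseProfile",
    "SimulationTruth",
    "SimulatedTrial",
    "generate_schedule",
    "simulate_flash_train",
    "simulate_study",
]

# Floor (s) for the solved pause mean; reached only if a frequency
# multiplier pushes the target rate near the within-burst maximum.
_MIN_PAUSE_S = 0.05

# Timing floor for the underlying renewal process when the frequency
# multiplier is ~0; emission is suppressed separately.
_MIN_RATE_MULT = 0.01


@dataclass(frozen=True)
class FlashKinetics:
    """Physical and behavioral parameters of the simulated flash train.

    Parameters
    ----------
    pulse_duration_ms : float
        Width of one flash pulse (raised-cosine support), default 200 ms.
    interpulse_gap_ms : (float, float)
        Uniform range of the dark gap between consecutive flashes within
        a burst, default (200, 300) ms.
    base_rate : float
        Long-run dark flash rate, peaks/min (default 43.167).
    base_peak_amplitude : float
        Dark-adapted peak intensity of one flash, counts (default 5420).
    amplitude_cv : float
        Coefficient of variation of the per-flash lognormal amplitude
        jitter (mean 1); 0 disables jitter.
    burst_mean_length : float
        Mean flashes per burst in darkness (geometric distribution).
    pause_mean_length : float, optional
        Mean inter-burst pause in darkness, seconds.  ``None`` (default)
        solves it so the long-run rate equals ``base_rate``.
    noise_mean, noise_sd : float
        Additive detector noise per bin: Gaussian, clipped at zero.
        Defaults 50 / 30 counts keep noise below the 200-count floor
        with probability > 0.999.
    adaptation_tau : float
        Time constant (s) of the exponential behavioral transient after
        every segment change, default 5 s.
    """

    pulse_duration_ms: float = 200.0
    interpulse_gap_ms: tuple[float, float] = (200.0, 300.0)
    base_rate: float = 43.167
    base_peak_amplitude: float = 5420.0
    amplitude_cv: float = 0.25
    burst_mean_length: float = 2.0
    pause_mean_length: Optional[float] = None
    noise_mean: float = 50.0
    noise_sd: float = 30.0
    adaptation_tau: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.interpulse_gap_ms
        if self.pulse_duration_ms <= 0:
            raise ValueError("pulse duration must be positive")
        if not lo < hi:
            raise ValueError("interpulse gap range must satisfy low < high")
        if lo < 0:
            raise ValueError("interpulse gaps must be non-negative")
        if self.base_rate <= 0 or self.base_peak_amplitude <= 0:
            raise ValueError("base rate and amplitude must be positive")
        if self.amplitude_cv < 0 or self.noise_sd < 0 or self.noise_mean < 0:
            raise ValueError("dispersion parameters must be non-negative")
        if self.burst_mean_length < 1:
            raise ValueError("mean burst length must be at least one flash")
        if self.adaptation_tau <= 0:
            raise ValueError("adaptation tau must be positive")
        if self.pause_mean_for(1.0) <= 0:
            raise ValueError(
                "base_rate incompatible with burst structure: solved pause "
                "mean is not positive"
            )
        # detector noise must stay under the 200-count exclusion threshold
        if self.noise_sd > 0 and self.noise_mean + 3.1 * self.noise_sd > 200.0:
            raise ValueError("noise exceeds the 200-count floor too often")

    @property
    def pulse_duration_s(self) -> float:
        return self.pulse_duration_ms / 1000.0

    @property
    def mean_interonset_s(self) -> float:
        """Mean onset-to-onset spacing within a burst, seconds."""
        lo, hi = self.interpulse_gap_ms
        return (self.pulse_duration_ms + (lo + hi) / 2.0) / 1000.0

    def burst_length_for(self, rate_multiplier: float) -> float:
        """Mean burst length under a frequency multiplier (floor 1)."""
        return max(1.0, self.burst_mean_length * min(rate_multiplier, 1.0))

    def pause_mean_for(self, rate_multiplier: float) -> float:
        """Mean pause (s) giving long-run rate ``base_rate * multiplier``.

        One burst/pause cycle holds on average L flashes and lasts
        ``(L-1) * mean_interonset + pulse + pause`` seconds; equate
        L / cycle-time to the target rate and solve for the pause.
        """
        m = max(rate_multiplier, _MIN_RATE_MULT)
        if m == 1.0 and self.pause_mean_length is not None:
            return self.pause_mean_length
        target_per_s = self.base_rate * m / 60.0
        length = self.burst_length_for(m)
        busy = (length - 1.0) * self.mean_interonset_s + self.pulse_duration_s
        return max(length / target_per_s - busy, _MIN_PAUSE_S)

    def without_noise(self) -> "FlashKinetics":
        return replace(self, noise_mean=0.0, noise_sd=0.0)


@dataclass(frozen=True)
class ResponseCell:
    """Behavioral response to one (wavelength, level) exposure."""

    intensity_multiplier: float = 1.0
    frequency_multiplier: float = 1.0
    cessation_probability: float = 0.0

    def __post_init__(self) -> None:
        if self.intensity_multiplier < 0 or self.frequency_multiplier < 0:
            raise ValueError("multipliers must be non-negative")
        if not 0.0 <= self.cessation_probability <= 1.0:
            raise ValueError("cessation probability must lie in [0, 1]")


_DARK_CELL = ResponseCell()


@dataclass(frozen=True)
class ResponseProfile:
    """Ground-truth behavioral multipliers per (wavelength, level).

    Dark segments always map to the identity cell (1, 1, 0).  The
    *expected observed* rate ratio of a cell is
    ``(1 - cessation_probability) * frequency_multiplier`` because
    segments in which the specimen ceases contribute zero flashes to the
    group mean; the expected intensity ratio is the intensity multiplier
    alone, since segments without flashes contribute no intensity value.
    """

    cells: Mapping[tuple[int, str], ResponseCell] = field(default_factory=dict)

    def cell(self, segment: ExposureSegment) -> ResponseCell:
        if not segment.is_light:
            return _DARK_CELL
        return self.cells.get((segment.wavelength, segment.level), _DARK_CELL)

    def expected_rate_ratio(self, wavelength: int, level: str) -> float:
        c = self.cells.get((wavelength, level), _DARK_CELL)
        return (1.0 - c.cessation_probability) * c.frequency_multiplier

    def expected_intensity_ratio(self, wavelength: int, level: str) -> float:
        return self.cells.get((wavelength, level), _DARK_CELL).intensity_multiplier

    @classmethod
    def null(
        cls, wavelengths: Sequence[int] = DEFAULT_WAVELENGTHS
    ) -> "ResponseProfile":
        """Identity profile: ambient light has no behavioral effect."""
        return cls(
            {
                (int(w), lvl): ResponseCell()
                for w in wavelengths
                for lvl in ("dim", "bright")
            }
        )

    @classmethod
    def from_reference(
        cls, cessation_probability: Optional[float] = None
    ) -> "ResponseProfile":
        """Profile reproducing the published degree-of-change table.

        Intensity multipliers equal the printed intensity ratios (group
        intensity means exclude segments without flashes).  For bright
        exposures at responsive wavelengths (<= 533 nm) half the males
        ceased signaling; those cells get ``cessation_probability``
        (default 0.5) and a conditional frequency multiplier
        ``printed_ratio / (1 - cessation)`` so the expected observed
        rate ratio still equals the printed column.  Pass
        ``cessation_probability=0`` for a cessation-free profile whose
        frequency multipliers are exactly the printed ratios.
        """
        if cessation_probability is None:
            cessation_probability = reference.CESSATION_FRACTION
        table = reference.reference_effect_table()
        cells: dict[tuple[int, str], ResponseCell] = {}
        for row in table.itertuples():
            ceases = (
                row.level == "bright"
                and row.wavelength <= reference.RESPONSIVE_MAX_NM
                and cessation_probability > 0
            )
            c = cessation_probability if ceases else 0.0
            cells[(int(row.wavelength), row.level)] = ResponseCell(
                intensity_multiplier=row.doc_intensity,
                frequency_multiplier=row.doc_rate / (1.0 - c) if c < 1 else 0.0,
                cessation_probability=c,
            )
        return cls(cells)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded alongside a simulated trace."""

    pulse_times: np.ndarray  # onset of every emitted pulse, s
    pulse_amplitudes: np.ndarray  # rendered peak-bin amplitude, counts
    ceased_segments: tuple[int, ...]  # 1-based indices of suppressed segments


@dataclass(frozen=True)
class SimulatedTrial:
    """One simulated specimen: schedule, trace, and its ground truth."""

    specimen: str
    schedule: ExposureSchedule
    trace: CountTrace
    truth: SimulationTruth
    rate_offset: float
    amplitude_offset: float


def generate_schedule(
    wavelengths: Sequence[int] = DEFAULT_WAVELENGTHS,
    seed: Optional[int] = None,
    segment_duration: float = 60.0,
) -> ExposureSchedule:
    """Build a randomized alternating dark/light exposure schedule.

    Wavelength order is a uniform random permutation; within each
    wavelength the dim/bright order is randomized independently.  Every
    light exposure is preceded by a dark segment of equal duration, so a
    trial lasts ``4 * segment_duration`` per wavelength (32 min for the
    standard eight wavelengths).
    """
    wls = [int(w) for w in wavelengths]
    if not wls:
        raise ValueError("need at least one wavelength")
    if len(set(wls)) != len(wls):
        raise ValueError(f"duplicate wavelengths in {wls}")
    rng = np.random.default_rng(seed)
    order = [wls[i] for i in rng.permutation(len(wls))]
    segments: list[ExposureSegment] = []
    idx = 0
    for wl in order:
        levels = ["dim", "bright"] if rng.random() < 0.5 else ["bright", "dim"]
        for lvl in levels:
            idx += 1
            segments.append(
                ExposureSegment(idx, "dark", duration=segment_duration)
            )
            idx += 1
            segments.append(
                ExposureSegment(
                    idx, "light", wavelength=wl, level=lvl, duration=segment_duration
                )
            )
    return ExposureSchedule(tuple(segments), seed=seed)


def _render_pulse(
    signal: np.ndarray, onset_s: float, amplitude: float, pulse_s: float
) -> float:
    """Add one raised-cosine pulse to the binned signal.

    The continuous pulse is averaged analytically within each 100-ms bin
    and then scaled so that its maximum bin equals ``amplitude`` — the
    recorded peak of a flash is its nominal amplitude regardless of how
    the pulse straddles bin edges.  Returns the rendered peak value.
    """
    w = BIN_WIDTH
    first = int(math.floor(onset_s / w))
    last = int(math.floor((onset_s + pulse_s) / w))
    last = min(last, len(signal) - 1)
    if first >= len(signal) or last < first:
        return 0.0
    edges = np.arange(first, last + 2) * w
    lo = np.clip(edges[:-1], onset_s, onset_s + pulse_s) - onset_s
    hi = np.clip(edges[1:], onset_s, onset_s + pulse_s) - onset_s
    # antiderivative of (1 - cos(2*pi*t/T))/2
    two_pi = 2.0 * math.pi / pulse_s
    integ = 0.5 * ((hi - lo) - (np.sin(two_pi * hi) - np.sin(two_pi * lo)) / two_pi)
    bin_means = integ / w
    peak = bin_means.max()
    if peak <= 0:
        return 0.0
    scaled = bin_means * (amplitude / peak)
    signal[first : last + 1] += scaled
    return float(scaled.max())


class _SegmentContext:
    """Per-segment multipliers with exponential adaptation blending."""

    def __init__(
        self,
        schedule: ExposureSchedule,
        profile: ResponseProfile,
        tau: float,
        ceased: Sequence[bool],
    ) -> None:
        self.starts = np.asarray(schedule.segment_starts())
        self.tau = tau
        self.int_mult = np.array(
            [profile.cell(s).intensity_multiplier for s in schedule.segments]
        )
        self.freq_mult = np.array(
            [profile.cell(s).frequency_multiplier for s in schedule.segments]
        )
        self.ceased = np.asarray(ceased, dtype=bool)

    def _index(self, t: float) -> int:
        k = int(np.searchsorted(self.starts, t, side="right")) - 1
        return max(k, 0)

    def _blend(self, t: float, values: np.ndarray) -> float:
        k = self._index(t)
        cur = values[k]
        if k == 0:
            return float(cur)
        decay = math.exp(-(t - self.starts[k]) / self.tau)
        return float(cur + (values[k - 1] - cur) * decay)

    def intensity(self, t: float) -> float:
        return self._blend(t, self.int_mult)

    def frequency(self, t: float) -> float:
        return self._blend(t, self.freq_mult)

    def suppressed(self, t: float) -> bool:
        return bool(self.ceased[self._index(t)])


def _draw_pause(
    rng: np.random.Generator,
    t: float,
    mean_at,
    starts: np.ndarray,
    tau: float,
    step: float = 0.25,
    cap: float = 3600.0,
) -> float:
    """Sample a pause from the time-varying exponential hazard.

    The instantaneous pause-end hazard is ``1 / mean_at(t')``;
    integrating it forward from ``t`` until it accumulates a
    unit-exponential deviate keeps the realized flash rate tracking the
    behavioral transient — and any segment change the pause spans —
    instead of freezing the rate at draw time.  The integral advances in
    ``step``-s increments through transient regions and jumps in closed
    form once the hazard is constant (more than ~5 time constants past
    the last segment change and short of the next one).
    """
    target = rng.exponential()
    acc = 0.0
    p = 0.0
    while p < cap:
        now = t + p
        k = int(np.searchsorted(starts, now, side="right")) - 1
        last = starts[max(k, 0)]
        nxt = starts[k + 1] if k + 1 < len(starts) else math.inf
        mean_cur = mean_at(now)
        if now - last > 5 * tau:  # hazard constant until the next boundary
            jump = (target - acc) * mean_cur
            if now + jump < nxt:
                return p + jump
            acc += (nxt - now) / mean_cur
            p = nxt - t
            continue
        inc = step / mean_cur
        if acc + inc >= target:
            return p + (target - acc) * mean_cur
        acc += inc
        p += step
    return cap


def simulate_flash_train(
    schedule: ExposureSchedule,
    kinetics: Optional[FlashKinetics] = None,
    profile: Optional[ResponseProfile] = None,
    seed: Optional[int] = None,
    rate_offset: float = 1.0,
    amplitude_offset: float = 1.0,
    return_truth: bool = False,
    metadata: Optional[dict] = None,
):
    """Simulate one spectrometer recording of a scheduled trial.

    Parameters
    ----------
    schedule : ExposureSchedule
    kinetics : FlashKinetics, optional
        Defaults emulate the dark-adapted alarm-flash train.
    profile : ResponseProfile, optional
        Behavioral response to light; default is the identity profile.
    seed : int, optional
        Master seed; split into cessation/process/noise streams.
    rate_offset, amplitude_offset : float
        Individual-level multiplicative offsets on flash rate and
        amplitude (used by :func:`simulate_study`).
    return_truth : bool
        Also return the :class:`SimulationTruth` ground truth.

    Returns
    -------
    CountTrace, or ``(CountTrace, SimulationTruth)``.
    """
    kinetics = kinetics or FlashKinetics()
    profile = profile or ResponseProfile()
    ss = np.random.SeedSequence(seed)
    rng_cease, rng_proc, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )

    # cessation: one draw per segment with a positive cessation probability
    ceased = []
    for seg in schedule.segments:
        p = profile.cell(seg).cessation_probability
        ceased.append(p > 0 and rng_cease.random() < p)
    ctx = _SegmentContext(schedule, profile, kinetics.adaptation_tau, ceased)

    total = schedule.total_duration
    n_bins = schedule.n_bins
    signal = np.zeros(n_bins)
    pulse_s = kinetics.pulse_duration_s
    gap_lo, gap_hi = (g / 1000.0 for g in kinetics.interpulse_gap_ms)
    if kinetics.amplitude_cv > 0:
        sigma = math.sqrt(math.log1p(kinetics.amplitude_cv**2))
    else:
        sigma = 0.0

    pulse_times: list[float] = []
    pulse_amps: list[float] = []

    def pause_mean_at(tt: float) -> float:
        return kinetics.pause_mean_for(ctx.frequency(tt) * rate_offset)

    starts = ctx.starts
    tau = kinetics.adaptation_tau
    t = _draw_pause(rng_proc, 0.0, pause_mean_at, starts, tau)
    while t < total:
        m = ctx.frequency(t) * rate_offset
        n_burst = int(rng_proc.geometric(1.0 / kinetics.burst_length_for(m)))
        for j in range(n_burst):
            if t >= total:
                break
            if not ctx.suppressed(t) and ctx.frequency(t) > 1e-9:
                amp = (
                    kinetics.base_peak_amplitude
                    * ctx.intensity(t)
                    * amplitude_offset
                )
                if sigma > 0:
                    amp *= rng_proc.lognormal(-0.5 * sigma**2, sigma)
                else:
                    rng_proc.lognormal(0.0, 1.0)  # keep stream aligned
                rendered = _render_pulse(signal, t, amp, pulse_s)
                pulse_times.append(t)
                pulse_amps.append(rendered)
            else:
                rng_proc.lognormal(0.0, 1.0)
            if j < n_burst - 1:
                t += pulse_s + rng_proc.uniform(gap_lo, gap_hi)
        t += pulse_s
        t += _draw_pause(rng_proc, min(t, total), pause_mean_at, starts, tau)

    if kinetics.noise_sd > 0 or kinetics.noise_mean > 0:
        noise = rng_noise.normal(kinetics.noise_mean, kinetics.noise_sd, n_bins)
        signal = signal + np.clip(noise, 0.0, None)

    meta = dict(metadata or {})
    meta.setdefault("seed", seed)
    trace = CountTrace(values=signal, metadata=meta)
    if return_truth:
        truth = SimulationTruth(
            pulse_times=np.asarray(pulse_times),
            pulse_amplitudes=np.asarray(pulse_amps),
            ceased_segments=tuple(
                seg.index for seg, c in zip(schedule.segments, ceased) if c
            ),
        )
        return trace, truth
    return trace


def simulate_study(
    n_individuals: int,
    kinetics: Optional[FlashKinetics] = None,
    profile: Optional[ResponseProfile] = None,
    seed: Optional[int] = None,
    wavelengths: Sequence[int] = DEFAULT_WAVELENGTHS,
    individual_rate_sd: float = 0.2,
    individual_amplitude_sd: float = 0.2,
) -> list[SimulatedTrial]:
    """Simulate a multi-specimen study with per-individual random effects.

    Each specimen gets an independent randomized schedule and trace.
    Individual baseline offsets on flash rate and amplitude are lognormal
    with unit mean and the given log-scale standard deviations,
    reflecting the high natural variation of the species.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    kinetics = kinetics or FlashKinetics()
    profile = profile or ResponseProfile()
    trials: list[SimulatedTrial] = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_individuals)):
        sched_ss, train_ss, eff_ss = child.spawn(3)
        sched_seed = int(sched_ss.generate_state(1)[0] % (2**31))
        schedule = generate_schedule(wavelengths, seed=sched_seed)
        rng_eff = np.random.default_rng(eff_ss)
        rate_off = float(
            rng_eff.lognormal(-0.5 * individual_rate_sd**2, individual_rate_sd)
        )
        amp_off = float(
            rng_eff.lognormal(
                -0.5 * individual_amplitude_sd**2, individual_amplitude_sd
            )
        )
        train_seed = int(train_ss.generate_state(1)[0] % (2**31))
        specimen = f"specimen_{i + 1:02d}"
        trace, truth = simulate_flash_train(
            schedule,
            kinetics,
            profile,
            seed=train_seed,
            rate_offset=rate_off,
            amplitude_offset=amp_off,
            return_truth=True,
            metadata={"specimen": specimen, "schedule_seed": sched_seed},
        )
        trials.append(
            SimulatedTrial(specimen, schedule, trace, truth, rate_off, amp_off)
        )
    return trials
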