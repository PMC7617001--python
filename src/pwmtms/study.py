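"""Synthetic within-subject two-device MEP study generator.

Emulates a 12-participant crossover experiment in which each participant's
resting motor threshold (RMT), input–output (IO) curve and MEP latencies
are measured with a conventional monophasic stimulator ("magstim") and a
PWM-based device ("ptms"), with all intensities expressed on the
conventional device's %MSO scale.  The generative structure encodes the
study's reported statistical features:

* Magstim-condition RMTs are drawn from a truncated normal
  (mean 41.34, SD 6.07 %MSO on the interval (20, 80));
* the PWM-condition RMT is lower for *every* participant by a strictly
  positive truncated-normal difference (mean 3.34, SD 1.5 %MSO);
* the four-parameter sigmoid IO curve on log10 amplitude shares its floor,
  ceiling and width (hence its midpoint slope) across devices within a
  participant — only the midpoint shifts with the device RMT;
* MEP latencies are device-independent within a participant;
* EMG traces carry a 100 ms Gaussian pre-stimulus baseline and a biphasic
  MEP wavelet (two opposed half-sines, 8 ms total) at the participant's
  latency.

The response probability is anchored so that a trial at the true RMT
produces a ≥ 50 µV peak-to-peak MEP with probability one half, making the
5-of-10 staircase estimator unbiased by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import truncnorm

__all__ = [
    "CohortConfig",
    "ParticipantModel",
    "EMGTrace",
    "TrialRecord",
    "criterion_anchor",
    "generate_cohort",
    "simulate_trial",
    "generate_rmt_session",
    "generate_io_session",
    "DEVICES",
]

DEVICES = ("magstim", "ptms")

#: staircase success criterion on the *measured* peak-to-peak, µV
_CRITERION_UV = 50.0


@dataclass
class CohortConfig:
    """Generative parameters of the synthetic cohort.

    The RMT means/SDs are the study-condition values on the conventional
    device's %MSO scale; the difference draw is truncated strictly positive
    so every participant's PWM-condition RMT is below their conventional
    one.  IO floor/ceiling/width are the shared-slope sigmoid parameters on
    log10 µV; latencies are in milliseconds and device-independent.
    """

    n_participants: int = 12
    magstim_rmt_mean: float = 41.34     # %MSO
    magstim_rmt_sd: float = 6.07
    rmt_bounds: tuple[float, float] = (20.0, 80.0)
    rmt_difference_mean: float = 3.34   # %MSO, magstim − ptms
    rmt_difference_sd: float = 1.5
    io_floor: float = 0.7               # log10 µV (5 µV noise-floor amplitude)
    io_ceiling_mean: float = 3.45       # log10 µV (~2.8 mV saturation)
    io_ceiling_sd: float = 0.15
    io_width_mean: float = 7.0          # %MSO
    io_width_sd: float = 0.7
    latency_mean: float = 22.0          # ms
    latency_sd: float = 1.5
    trial_log_sd: float = 0.25          # trial-to-trial SD of log10 amplitude
    emg_noise_sd: float = 5.0           # µV
    sampling_rate: float = 5000.0       # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("magstim_rmt_sd", "rmt_difference_sd", "io_ceiling_sd",
                     "io_width_sd", "latency_sd", "trial_log_sd",
                     "emg_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.rmt_bounds
        if not lo < hi:
            raise ValueError("impossible RMT truncation bounds")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


@dataclass
class ParticipantModel:
    """Ground-truth parameters of one synthetic participant."""

    participant_id: int
    rmt: dict[str, float]           # device -> true RMT, %MSO
    io_floor: float                 # log10 µV, shared across devices
    io_ceiling: float               # log10 µV, shared across devices
    io_width: float                 # %MSO, shared across devices
    io_midpoint: dict[str, float]   # device -> midpoint, %MSO
    latency: float                  # ms, shared across devices
    trial_log_sd: float
    emg_noise_sd: float
    sampling_rate: float

    def __post_init__(self) -> None:
        for dev in DEVICES:
            if self.io_midpoint[dev] < self.rmt[dev]:
                raise ValueError("IO midpoint must be at or above the RMT")

    def io_value(self, device: str, intensity: float) -> float:
        """Median log10 peak-to-peak amplitude (µV) at an intensity."""
        from scipy.special import ndtr

        z = (intensity - self.io_midpoint[device]) / self.io_width
        return self.io_floor + (self.io_ceiling - self.io_floor) * ndtr(z)

    @property
    def midpoint_slope(self) -> float:
        """Shared IO midpoint slope, log10 µV per %MSO."""
        return (self.io_ceiling - self.io_floor) / (
            self.io_width * math.sqrt(2.0 * math.pi)
        )


@dataclass
class EMGTrace:
    """One EMG sweep with a 100 ms pre-stimulus baseline."""

    sampling_rate: float       # Hz
    samples: np.ndarray        # µV
    stimulus_index: int        # sample of stimulus delivery

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples must be finite")
        n_pre = int(round(0.1 * self.sampling_rate))
        if self.stimulus_index != n_pre:
            raise ValueError("the pre-stimulus segment must be exactly 100 ms")


@dataclass
class TrialRecord:
    """One stimulus delivery."""

    participant: int
    device: str
    intensity: float           # %MSO (conventional-device equivalent)
    trace: EMGTrace
    interval: float            # inter-pulse interval, s

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValueError(f"device must be one of {DEVICES}")
        if not 0.0 < self.intensity <= 100.0:
            raise ValueError("intensity must lie in (0, 100] %MSO")
        if not 4.25 <= self.interval <= 6.0:
            raise ValueError("inter-pulse interval must lie in [4.25, 6] s")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd == 0.0:
        if not lo < mean < hi:
            raise ValueError("degenerate draw outside truncation bounds")
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


_ANCHOR_CACHE: dict[tuple, float] = {}


def criterion_anchor(config: CohortConfig) -> float:
    """log10 amplitude the IO curve must take at the true RMT.

    A trial "succeeds" when the *measured* peak-to-peak of its EMG sweep
    reaches 50 µV, and the measurement (max − min over the post-stimulus
    window) is inflated by the baseline noise riding on the wavelet.  This
    routine therefore solves, by bisection over a fixed bank of seeded
    noise and trial-noise draws, for the IO-curve level at which the
    measured criterion is reached with probability one half — anchoring the
    5-of-10 staircase at the true RMT by construction.  The result depends
    only on the noise model (EMG noise SD, sampling rate, trial noise SD,
    latency) and is cached.
    """
    key = (config.emg_noise_sd, config.sampling_rate, config.trial_log_sd,
           config.latency_mean)
    if key in _ANCHOR_CACHE:
        return _ANCHOR_CACHE[key]
    if config.emg_noise_sd == 0.0 and config.trial_log_sd == 0.0:
        _ANCHOR_CACHE[key] = math.log10(_CRITERION_UV)
        return _ANCHOR_CACHE[key]
    fs = config.sampling_rate
    # measurement window, 15-45 ms post-stimulus (the analysis default)
    n_lo, n_hi = int(round(15e-3 * fs)), int(round(45e-3 * fs))
    t_ms = np.arange(n_lo, n_hi) / fs * 1e3
    shape = _mep_wavelet_shape(t_ms, config.latency_mean)
    rng = np.random.default_rng(987654321)
    n_draws = 6000
    noise = rng.normal(0.0, config.emg_noise_sd, size=(n_draws, t_ms.size))
    eps = rng.normal(0.0, config.trial_log_sd, size=n_draws)

    def exceed_fraction(log_median: float) -> float:
        amps = 10.0 ** (log_median + eps)
        seg = amps[:, None] * shape[None, :] + noise
        p2p = seg.max(axis=1) - seg.min(axis=1)
        return float(np.mean(p2p >= _CRITERION_UV))

    lo, hi = math.log10(5.0), math.log10(_CRITERION_UV)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if exceed_fraction(mid) > 0.5:
            hi = mid
        else:
            lo = mid
    _ANCHOR_CACHE[key] = 0.5 * (lo + hi)
    return _ANCHOR_CACHE[key]


def generate_cohort(config: CohortConfig) -> list[ParticipantModel]:
    """Draw a fully seeded cohort of participants.

    The IO midpoint of each device condition is placed so that a trial at
    the device's true RMT yields a measured peak-to-peak of at least 50 µV
    with probability one half (see :func:`criterion_anchor`), anchoring the
    staircase estimator at the true RMT.
    """
    anchor = criterion_anchor(config)
    rng = np.random.default_rng(config.seed)
    lo, hi = config.rmt_bounds
    rmt_mag = _truncated_normal(rng, config.magstim_rmt_mean,
                                config.magstim_rmt_sd, lo, hi,
                                config.n_participants)
    diff = _truncated_normal(rng, config.rmt_difference_mean,
                             config.rmt_difference_sd, 0.0, np.inf,
                             config.n_participants)
    ceilings = config.io_ceiling_mean + config.io_ceiling_sd * rng.standard_normal(
        config.n_participants
    )
    widths = np.maximum(
        config.io_width_mean + config.io_width_sd * rng.standard_normal(
            config.n_participants
        ),
        2.0,
    )
    latencies = config.latency_mean + config.latency_sd * rng.standard_normal(
        config.n_participants
    )
    cohort = []
    for k in range(config.n_participants):
        rmt = {"magstim": float(rmt_mag[k]), "ptms": float(rmt_mag[k] - diff[k])}
        ceiling = float(max(ceilings[k], config.io_floor + 1.0))
        width = float(widths[k])
        # anchor: measured criterion probability is 1/2 at the true RMT
        q = (anchor - config.io_floor) / (ceiling - config.io_floor)
        if not 0.0 < q < 0.5:
            raise ValueError("IO ceiling too low to anchor the 50 µV criterion")
        offset = -width * float(ndtri(q))      # > 0, so midpoint ≥ RMT
        midpoints = {dev: rmt[dev] + offset for dev in DEVICES}
        cohort.append(
            ParticipantModel(
                participant_id=k,
                rmt=rmt,
                io_floor=config.io_floor,
                io_ceiling=ceiling,
                io_width=width,
                io_midpoint=midpoints,
                latency=float(max(latencies[k], 12.0)),
                trial_log_sd=config.trial_log_sd,
                emg_noise_sd=config.emg_noise_sd,
                sampling_rate=config.sampling_rate,
            )
        )
    return cohort


def _mep_wavelet_shape(t_ms: np.ndarray, onset_ms: float) -> np.ndarray:
    """Unit-p2p biphasic wavelet: two opposed half-sines, 8 ms total."""
    phase = (t_ms - onset_ms) / 8.0          # wavelet spans [onset, onset + 8 ms)
    return np.where(
        (phase >= 0.0) & (phase < 1.0),
        0.5 * np.sin(2.0 * np.pi * phase),
        0.0,
    )


def _mep_wavelet(n: int, fs: float, onset_ms: float, amplitude_uv: float) -> np.ndarray:
    """Biphasic wavelet with peak-to-peak ``amplitude_uv``."""
    t_ms = np.arange(n) / fs * 1e3
    return amplitude_uv * _mep_wavelet_shape(t_ms, onset_ms)


def simulate_trial(
    p: ParticipantModel,
    device: str,
    intensity: float,
    rng: np.random.Generator,
    post_ms: float = 100.0,
) -> TrialRecord:
    """Simulate one stimulus delivery and its EMG sweep.

    The MEP log10 amplitude is the participant's IO curve at the intensity
    plus Gaussian trial noise; the sweep is baseline Gaussian EMG noise over
    the whole window plus the biphasic wavelet at the participant's latency.
    Far sub-threshold intensities thus yield noise-dominated traces.
    """
    if device not in DEVICES:
        raise ValueError(f"device must be one of {DEVICES}")
    fs = p.sampling_rate
    n_pre = int(round(0.1 * fs))
    n = n_pre + int(round(post_ms / 1e3 * fs))
    log_amp = p.io_value(device, intensity) + rng.normal(0.0, p.trial_log_sd)
    amp = 10.0 ** log_amp
    samples = rng.normal(0.0, p.emg_noise_sd, size=n) if p.emg_noise_sd > 0 else np.zeros(n)
    post_t0 = n_pre / fs * 1e3
    samples += _mep_wavelet(n, fs, post_t0 + p.latency, amp)
    trace = EMGTrace(sampling_rate=fs, samples=samples, stimulus_index=n_pre)
    return TrialRecord(
        participant=p.participant_id,
        device=device,
        intensity=float(intensity),
        trace=trace,
        interval=float(rng.uniform(4.25, 6.0)),
    )


def generate_rmt_session(
    p: ParticipantModel,
    device: str,
    rng: np.random.Generator,
    start: float | None = None,
    step: float = 1.0,
    max_blocks: int = 30,
) -> list[TrialRecord]:
    """Emit the trial stream of one RMT determination session.

    Trials come in 10-pulse blocks whose intensities follow the 5-of-10
    staircase protocol, with block decisions based on the measured
    peak-to-peak amplitudes of the generated traces (exactly what the
    analysis-side replay will see).  The default starting intensity is five
    steps above the participant's (rounded) true threshold, emulating an
    operator starting from a clearly suprathreshold hotspot intensity.
    """
    from .analysis import RMT_CRITERION_UV, measure_peak_to_peak, run_staircase

    if start is None:
        start = float(round(p.rmt[device])) + 5.0
    trials: list[TrialRecord] = []

    def block_runner(x: float) -> int:
        n_succ = 0
        for _ in range(10):
            tr = simulate_trial(p, device, x, rng)
            trials.append(tr)
            if measure_peak_to_peak(tr.trace).peak_to_peak >= RMT_CRITERION_UV:
                n_succ += 1
        return n_succ

    run_staircase(block_runner, start, step=step, max_blocks=max_blocks)
    return trials


def generate_io_session(
    p: ParticipantModel,
    device: str,
    rng: np.random.Generator,
    start: float = 30.0,
    max_intensity: float = 57.0,
    step: float = 3.0,
    n_per_intensity: int = 15,
) -> list[TrialRecord]:
    """Emit the trial stream of one IO-curve session.

    Intensities ascend from ``start`` to ``max_intensity`` in fixed steps
    (default 3 %MSO, capped at the PWM device's maximum-equivalent
    intensity) with ``n_per_intensity`` trials at each.
    """
    trials: list[TrialRecord] = []
    x = float(start)
    while x <= max_intensity + 1e-9:
        for _ in range(n_per_intensity):
            trials.append(simulate_trial(p, device, x, rng))
        x += step
    return trials
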