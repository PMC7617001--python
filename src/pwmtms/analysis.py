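"""MEP measurement and statistics pipeline.

Implements the measurement chain of a two-device motor-evoked-potential
(MEP) study: peak-to-peak amplitude with the 20 µV reporting floor, EMG
onset latency against the 100 ms pre-stimulus baseline, the 5-of-10
staircase estimate of the resting motor threshold (RMT), the four-parameter
sigmoid fit of the input–output (IO) curve on log amplitude, and the
two-level repeated-measures comparisons (which for two conditions reduce
exactly to the squared paired t-test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import ndtr

from .study import EMGTrace, TrialRecord

__all__ = [
    "MEPMeasurement",
    "RMTEstimate",
    "IOCurveFit",
    "StatsResult",
    "StatsReport",
    "StaircaseError",
    "measure_peak_to_peak",
    "detect_latency",
    "run_staircase",
    "determine_rmt",
    "blocks_from_trials",
    "fit_io_curve",
    "rm_anova_two_level",
    "cohens_d",
    "latency_by_amplitude",
    "LATENCY_AMPLITUDE_TARGETS",
]

#: reporting floor for peak-to-peak amplitudes, µV
AMPLITUDE_FLOOR_UV = 20.0
#: success criterion of the RMT staircase, µV peak-to-peak
RMT_CRITERION_UV = 50.0
#: default post-stimulus measurement window, ms
DEFAULT_WINDOW_MS = (15.0, 45.0)
#: amplitude targets for the latency comparison, µV
LATENCY_AMPLITUDE_TARGETS = (50.0, 500.0, 1000.0)


@dataclass
class MEPMeasurement:
    """Peak-to-peak measurement of one trial."""

    trial_id: int
    peak_to_peak: float            # µV, floored at 20 µV
    floored: bool
    latency: float | None = None   # ms post-stimulus
    latency_detected: bool = False


@dataclass
class RMTEstimate:
    """Staircase estimate of the resting motor threshold."""

    participant: int
    device: str
    rmt: float                             # %MSO
    intensities: list[float]               # visited, chronological
    successes: list[int]                   # per visited block, out of 10
    n_blocks: int = 0

    def __post_init__(self) -> None:
        self.n_blocks = len(self.intensities)


@dataclass
class IOCurveFit:
    """Four-parameter sigmoid fit of the IO curve on log10 amplitude.

    The model is ``y(x) = floor + (ceiling - floor) * Phi((x - midpoint)/width)``
    with ``Phi`` the standard normal CDF ("Gaussian-type" sigmoid); the slope
    at the midpoint is ``(ceiling - floor) / (width * sqrt(2*pi))`` in
    log10 µV per %MSO.
    """

    floor: float
    ceiling: float
    midpoint: float        # %MSO
    width: float           # %MSO
    midpoint_slope: float  # log10 µV per %MSO
    rss: float
    converged: bool

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.floor + (self.ceiling - self.floor) * ndtr(
            (np.asarray(x, dtype=float) - self.midpoint) / self.width
        )


@dataclass
class StatsResult:
    """One repeated-measures comparison."""

    name: str
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    n: int
    mean_a: float
    mean_b: float
    capped: bool = False   # zero-variance differences: F reported as capped


@dataclass
class StatsReport:
    """Study-level statistics."""

    rmt: StatsResult
    rmt_cohens_d: float
    io_slope: StatsResult | None
    latency: dict[float, StatsResult]
    group_means: dict[str, float] = field(default_factory=dict)
    group_sds: dict[str, float] = field(default_factory=dict)


class StaircaseError(RuntimeError):
    """The staircase did not terminate within the block budget."""


def measure_peak_to_peak(
    trace: EMGTrace,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    trial_id: int = 0,
) -> MEPMeasurement:
    """Peak-to-peak amplitude within a post-stimulus window.

    Values below the 20 µV reporting floor are set to 20 µV and flagged,
    the smallest amplitude distinguishable from EMG noise.
    """
    fs_ms = trace.sampling_rate / 1e3      # samples per ms
    lo = trace.stimulus_index + int(round(window_ms[0] * fs_ms))
    hi = trace.stimulus_index + int(round(window_ms[1] * fs_ms))
    if lo < trace.stimulus_index or hi > trace.samples.size or lo >= hi:
        raise ValueError("measurement window lies outside the post-stimulus span")
    seg = trace.samples[lo:hi]
    p2p = float(seg.max() - seg.min())
    floored = p2p < AMPLITUDE_FLOOR_UV
    return MEPMeasurement(trial_id, max(p2p, AMPLITUDE_FLOOR_UV), floored)


def detect_latency(
    trace: EMGTrace,
    min_duration_ms: float = 1.0,
) -> tuple[float | None, bool]:
    """Onset latency: first sustained crossing of the baseline threshold.

    The threshold is the mean plus two standard deviations of the rectified
    100 ms pre-stimulus EMG.  The latency is the first post-stimulus time at
    which the rectified EMG stays above the threshold for at least
    ``min_duration_ms`` continuously (set it to 0 for a pure
    first-crossing rule).  Returns ``(latency_ms, detected)``.
    """
    n_pre = trace.stimulus_index
    fs_ms = trace.sampling_rate / 1e3
    if n_pre < int(round(100.0 * fs_ms)):
        raise ValueError("a full 100 ms pre-stimulus segment is required")
    rect = np.abs(trace.samples)
    base = rect[:n_pre]
    threshold = float(base.mean() + 2.0 * base.std())
    post = rect[n_pre:]
    above = post > threshold
    need = max(1, int(math.ceil(min_duration_ms * fs_ms)))
    if need > 1:
        run = np.convolve(above.astype(int), np.ones(need, dtype=int), "valid")
        hits = np.flatnonzero(run == need)
    else:
        hits = np.flatnonzero(above)
    if hits.size == 0:
        return None, False
    return float(hits[0] / fs_ms), True


def run_staircase(
    block_runner: Callable[[float], int],
    start: float,
    step: float = 1.0,
    max_blocks: int = 30,
) -> tuple[float, list[tuple[float, int]]]:
    """Drive the 5-of-10 RMT staircase protocol.

    ``block_runner(intensity)`` delivers a block of 10 pulses and returns
    the number of trials with peak-to-peak ≥ 50 µV.  A block with ≥ 5
    successes steps the intensity down, otherwise up; the staircase
    terminates at the lowest intensity with ≥ 5/10 whose next-lower visited
    intensity had < 5/10.  Returns the RMT and the chronological
    ``(intensity, successes)`` history.

    Raises
    ------
    StaircaseError
        If the staircase does not terminate within ``max_blocks`` blocks.
    """
    visited: dict[float, int] = {}
    history: list[tuple[float, int]] = []
    x = float(start)
    for _ in range(max_blocks):
        s = int(block_runner(x))
        if not 0 <= s <= 10:
            raise ValueError("a block has between 0 and 10 successes")
        visited[x] = s
        history.append((x, s))
        if s >= 5:
            below = visited.get(x - step)
            if below is not None and below < 5:
                return x, history
            x -= step
        else:
            above = visited.get(x + step)
            if above is not None and above >= 5:
                return x + step, history
            x += step
        x = min(max(x, 1.0), 100.0)
    raise StaircaseError(
        f"staircase did not terminate within {max_blocks} blocks; history: {history}"
    )


def blocks_from_trials(
    trials: Sequence[TrialRecord],
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    criterion_uv: float = RMT_CRITERION_UV,
) -> list[tuple[float, int]]:
    """Group a chronological trial stream into 10-pulse blocks and score them."""
    if len(trials) % 10 != 0:
        raise ValueError("an RMT session consists of whole 10-pulse blocks")
    blocks = []
    for k in range(0, len(trials), 10):
        chunk = trials[k : k + 10]
        intensities = {t.intensity for t in chunk}
        if len(intensities) != 1:
            raise ValueError("each 10-pulse block must use a single intensity")
        n_succ = sum(
            measure_peak_to_peak(t.trace, window_ms).peak_to_peak >= criterion_uv
            for t in chunk
        )
        blocks.append((chunk[0].intensity, n_succ))
    return blocks


def determine_rmt(
    blocks: Sequence[tuple[float, int]],
    participant: int = 0,
    device: str = "",
    step: float = 1.0,
    max_blocks: int = 30,
) -> RMTEstimate:
    """Replay a recorded block sequence through the staircase protocol.

    ``blocks`` is the chronological ``(intensity, successes)`` record of a
    session (e.g. from :func:`blocks_from_trials`).  The sequence must
    follow the staircase rule; the estimate is the protocol's terminal
    intensity.
    """
    it = iter(blocks)

    def runner(x: float) -> int:
        try:
            intensity, succ = next(it)
        except StopIteration:
            raise StaircaseError("session ended before the staircase terminated")
        if intensity != x:
            raise ValueError(
                f"session does not follow the staircase protocol: expected a "
                f"block at {x}, found {intensity}"
            )
        return succ

    rmt, history = run_staircase(runner, blocks[0][0], step=step,
                                 max_blocks=max_blocks)
    return RMTEstimate(
        participant=participant,
        device=device,
        rmt=rmt,
        intensities=[b[0] for b in history],
        successes=[b[1] for b in history],
    )


def _sigmoid(x: np.ndarray, floor: float, ceiling: float, mid: float,
             width: float) -> np.ndarray:
    return floor + (ceiling - floor) * ndtr((x - mid) / width)


def fit_io_curve(
    intensities: Sequence[float],
    log_amplitudes: Sequence[float],
) -> IOCurveFit:
    """Least-squares four-parameter sigmoid fit of an IO curve.

    ``log_amplitudes`` are log10 peak-to-peak amplitudes (floored
    measurements included as their floored value).  The fit is multi-start:
    a grid of midpoint/width initializations is refined with bounded
    least squares and the lowest residual solution is kept.
    """
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(log_amplitudes, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need at least 4 (intensity, amplitude) points")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct intensities")
    if np.ptp(y) < 1e-9:
        return IOCurveFit(float(y[0]), float(y[0]), float(np.median(x)), 1.0,
                          0.0, float(np.sum((y - y.mean()) ** 2)), False)

    lo = np.array([y.min() - 1.0, y.min(), x.min() - 10.0, 0.5])
    hi = np.array([y.max(), y.max() + 2.0, x.max() + 10.0, 50.0])
    best: optimize.OptimizeResult | None = None
    for m0 in np.quantile(x, [0.25, 0.5, 0.75]):
        for w0 in (2.0, 5.0, 10.0):
            p0 = np.clip(
                np.array([y.min(), y.max(), m0, w0]), lo + 1e-9, hi - 1e-9
            )
            try:
                res = optimize.least_squares(
                    lambda p: _sigmoid(x, *p) - y, p0, bounds=(lo, hi),
                    method="trf",
                )
            except Exception:
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res
    if best is None:
        return IOCurveFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False)
    floor, ceiling, mid, width = best.x
    slope = (ceiling - floor) / (width * math.sqrt(2.0 * math.pi))
    return IOCurveFit(
        floor=float(floor), ceiling=float(ceiling), midpoint=float(mid),
        width=float(width), midpoint_slope=float(slope),
        rss=float(2.0 * best.cost), converged=bool(ceiling > floor),
    )


def rm_anova_two_level(
    a: Sequence[float], b: Sequence[float], name: str = ""
) -> StatsResult:
    """Two-level within-subject (repeated-measures) ANOVA.

    For a two-level within-subject factor the RM-ANOVA F statistic with
    degrees of freedom (1, n-1) equals the squared paired t statistic, and
    that identity is how it is computed here.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need complete pairs, n >= 3")
    n = a.size
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d.mean(), 0.0):
            return StatsResult(name, 0.0, (1, n - 1), 1.0, n,
                               float(a.mean()), float(b.mean()))
        return StatsResult(name, np.inf, (1, n - 1), 0.0, n,
                           float(a.mean()), float(b.mean()), capped=True)
    t = d.mean() / (sd / math.sqrt(n))
    f = t * t
    p = float(stats.f.sf(f, 1, n - 1))
    return StatsResult(name, float(f), (1, n - 1), p, n,
                       float(a.mean()), float(b.mean()))


def cohens_d(
    a: Sequence[float], b: Sequence[float], variant: str = "pooled"
) -> float:
    """Cohen's d for paired condition means.

    ``variant="pooled"`` uses ``(mean_a - mean_b) / sqrt((s_a^2 + s_b^2)/2)``;
    ``variant="difference"`` standardizes by the SD of the paired
    differences instead.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need complete pairs, n >= 2")
    num = a.mean() - b.mean()
    if variant == "pooled":
        s = math.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    elif variant == "difference":
        s = (a - b).std(ddof=1)
    else:
        raise ValueError("variant must be 'pooled' or 'difference'")
    if s == 0.0:
        raise ValueError("zero pooled standard deviation")
    return float(num / s)


def latency_by_amplitude(
    amplitudes: Sequence[float],
    latencies: Sequence[float | None],
    targets: Sequence[float] = LATENCY_AMPLITUDE_TARGETS,
    band: float = 1.5,
) -> dict[float, float]:
    """Mean detected latency in multiplicative amplitude bands.

    Trials are binned by peak-to-peak amplitude into bands
    ``[target/band, target*band]`` around each target; the mean latency of
    detected trials in each populated band is returned.
    """
    amp = np.asarray(amplitudes, dtype=float)
    out: dict[float, float] = {}
    for tgt in targets:
        sel = [
            lat
            for a, lat in zip(amp, latencies)
            if lat is not None and tgt / band <= a <= tgt * band
        ]
        if sel:
            out[tgt] = float(np.mean(sel))
    return out
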