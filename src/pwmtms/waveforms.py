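"""Coil waveform synthesis for conventional and PWM-based magnetic stimulators.

The conventional monophasic TMS pulse is modelled as an underdamped series
RLC capacitor discharge (capacitor ``C`` charged to ``initial_voltage``,
discharged through the coil inductance ``L`` and resistance ``R``) followed,
from the coil-current peak onward, by an exponential current decay through a
freewheel path of resistance ``freewheel_resistance``.  The PWM-based device
("pTMS") approximates the resulting coil-voltage waveform with a five-level
staircase produced by two cascaded H-bridge cells sharing a DC-link voltage
``V``: the available output levels are exactly {-2V, -V, 0, +V, +2V}.

Units are chosen so that the equations are unit-consistent without
conversion factors: time in microseconds, inductance in microhenries,
capacitance in microfarads, resistance in ohms, voltage in volts and current
in amperes (then ``L di/dt`` is in volts and ``C dv/dt`` in amperes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SampledWaveform",
    "DeviceConfig",
    "PWMConfig",
    "SwitchingPlan",
    "synth_magstim_monophasic",
    "synth_pwm_pulse",
    "coil_current_from_voltage",
    "calibrate_intensity_scale",
]

_KINDS = ("voltage", "current", "didt")


@dataclass
class SampledWaveform:
    """A uniformly sampled waveform.

    Parameters
    ----------
    dt
        Sampling step in microseconds (> 0).
    samples
        Amplitude values: volts for ``kind="voltage"``, amperes for
        ``kind="current"``, amperes/microsecond for ``kind="didt"``.
    kind
        One of ``voltage``, ``current`` or ``didt``.
    label
        Free-text description.
    """

    dt: float
    samples: np.ndarray
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.samples.ndim != 1 or self.samples.size < 64:
            raise ValueError("waveform needs at least 64 samples in a 1-d array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")
        if self.kind == "current" and self.samples[0] != 0.0:
            raise ValueError("a current waveform must start at 0 A")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in microseconds."""
        return self.n * self.dt

    def times(self) -> np.ndarray:
        """Sample times in microseconds (first sample at t = 0)."""
        return np.arange(self.n) * self.dt

    def scaled(self, k: float, label: str | None = None) -> "SampledWaveform":
        """Return a copy with all samples multiplied by ``k``."""
        return SampledWaveform(
            self.dt, self.samples * k, self.kind,
            label if label is not None else self.label,
        )


@dataclass
class DeviceConfig:
    """Discharge-circuit constants of a conventional monophasic stimulator.

    The defaults describe a Magstim 200^2-class circuit.  The capacitance is
    set so that the dominant low-frequency component of the synthesized
    coil-voltage pulse sits near 2.46 kHz, which puts the 13th multiple at
    the 32 kHz switching frequency of the PWM device.
    """

    capacitance: float = 367.0        # µF
    inductance: float = 16.35         # µH
    coil_resistance: float = 0.08     # Ω
    initial_voltage: float = 2800.0   # V (100 % stimulator output)
    freewheel_resistance: float = 0.0908  # Ω, gives L/R_fw ≈ 180 µs tail

    def __post_init__(self) -> None:
        for name in ("capacitance", "inductance", "coil_resistance",
                     "initial_voltage", "freewheel_resistance"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.initial_voltage > 2800.0:
            raise ValueError("initial_voltage exceeds the 2800 V device bound")

    @property
    def is_underdamped(self) -> bool:
        return self.coil_resistance ** 2 < 4.0 * self.inductance / self.capacitance


@dataclass
class PWMConfig:
    """Modulation parameters of the five-level PWM stimulator (pTMS)."""

    n_levels: int = 5
    dc_link_voltage: float = 800.0    # V per cascaded cell
    switching_frequency: float = 32.0  # kHz
    pulse_duration: float | None = None  # µs; None = modulate the full target
    placement: str = "centered"

    def __post_init__(self) -> None:
        if self.n_levels != 5:
            raise ValueError("the cascaded two-cell topology produces exactly 5 levels")
        if not self.dc_link_voltage > 0:
            raise ValueError("dc_link_voltage must be positive")
        if 2.0 * self.dc_link_voltage > 1600.0:
            raise ValueError("peak output 2*dc_link_voltage exceeds the 1600 V bound")
        if not self.switching_frequency > 0:
            raise ValueError("switching_frequency must be positive")
        if self.placement not in ("centered", "leading-edge"):
            raise ValueError("placement must be 'centered' or 'leading-edge'")

    @property
    def levels(self) -> np.ndarray:
        """Available output levels in volts, ascending."""
        v = self.dc_link_voltage
        return np.array([-2 * v, -v, 0.0, v, 2 * v])

    @property
    def switching_period(self) -> float:
        """Switching period in microseconds."""
        return 1e3 / self.switching_frequency


@dataclass
class SwitchingPlan:
    """Per-period switching decisions of a PWM synthesis.

    Each switching period is described by the pair of adjacent levels that
    brackets the period-averaged target and the duty cycle of the upper
    level.  The plan is the exact (continuous-time) description; the sampled
    voltage returned alongside it renders the plan on the target's grid.
    """

    period: float                     # µs
    start_times: np.ndarray           # µs, one per period
    level_lo: np.ndarray              # V
    level_hi: np.ndarray              # V
    duty: np.ndarray                  # duty of level_hi, in [0, 1]
    placement: str
    n_saturated: int = 0

    def __post_init__(self) -> None:
        if np.any(self.duty < 0) or np.any(self.duty > 1):
            raise ValueError("duty cycles must lie in [0, 1]")

    @property
    def n_periods(self) -> int:
        return self.start_times.size

    def volt_seconds(self) -> np.ndarray:
        """Exact volt-time integral of each period, in V·µs."""
        return self.period * (self.level_lo +
                              self.duty * (self.level_hi - self.level_lo))


def synth_magstim_monophasic(
    config: DeviceConfig,
    dt: float = 0.05,
    lead_us: float = 62.5,
    tail_time_constants: float = 8.0,
) -> tuple[SampledWaveform, SampledWaveform]:
    """Synthesize the conventional monophasic coil pulse.

    Phase 1 is the closed-form underdamped series-RLC discharge; it ends at
    the coil-current peak (the zero of ``L di/dt``), after which the current
    freewheels with time constant ``L / (R + R_fw)`` and the coil terminal
    voltage equals ``-R_fw * i``.  The returned voltage is the coil terminal
    voltage ``v = L di/dt + R i`` throughout.

    Parameters
    ----------
    config
        Circuit constants; must describe an underdamped circuit.
    dt
        Sampling step in µs; must be ≤ 1 µs and fine enough to resolve the
        current rise (≥ 20 samples to the current peak).
    lead_us
        Zero-padded lead-in before the discharge, so the record contains the
        whole pulse (and aligns with a whole number of PWM switching periods
        at the defaults).
    tail_time_constants
        Freewheel time constants covered after the current peak (≥ 5).
    """
    if dt > 1.0:
        raise ValueError("dt must be at most 1 µs")
    if tail_time_constants < 5.0:
        raise ValueError("the record must cover at least 5 decay time constants")
    L, C, R = config.inductance, config.capacitance, config.coil_resistance
    if not config.is_underdamped:
        raise ValueError(
            "overdamped circuit (R^2 >= 4 L / C): the monophasic model "
            "requires an underdamped discharge"
        )
    alpha = R / (2.0 * L)                      # 1/µs
    w0 = 1.0 / math.sqrt(L * C)                # rad/µs
    wd = math.sqrt(w0 * w0 - alpha * alpha)
    t_peak = math.atan2(wd, alpha) / wd        # first zero of L di/dt
    if dt > t_peak / 20.0:
        raise ValueError(
            f"dt = {dt} µs too coarse to resolve the {t_peak:.1f} µs current rise"
        )
    v0 = config.initial_voltage
    tau2 = L / (R + config.freewheel_resistance)
    t_end = t_peak + tail_time_constants * tau2

    n_lead = int(round(lead_us / dt))
    t = np.arange(int(math.ceil(t_end / dt)) + 1) * dt
    rise = t <= t_peak

    # phase 1: i = V0/(wd L) e^{-a t} sin(wd t); v = v_C
    i1 = v0 / (wd * L) * np.exp(-alpha * t[rise]) * np.sin(wd * t[rise])
    v1 = v0 * np.exp(-alpha * t[rise]) * (
        np.cos(wd * t[rise]) + (alpha / wd) * np.sin(wd * t[rise])
    )
    i_pk = v0 / (wd * L) * math.exp(-alpha * t_peak) * math.sin(wd * t_peak)
    # phase 2: freewheel decay from the exact peak time
    i2 = i_pk * np.exp(-(t[~rise] - t_peak) / tau2)
    v2 = -config.freewheel_resistance * i2

    lead = np.zeros(n_lead)
    i = np.concatenate([lead, i1, i2])
    v = np.concatenate([lead, v1, v2])
    voltage = SampledWaveform(dt, v, "voltage", "magstim monophasic coil voltage")
    current = SampledWaveform(dt, i, "current", "magstim monophasic coil current")
    return voltage, current


def synth_pwm_pulse(
    target: SampledWaveform, pwm: PWMConfig
) -> tuple[SwitchingPlan, SampledWaveform]:
    """Approximate a target voltage waveform with five-level PWM.

    Regular-sampled modulation: in each switching period the period-average
    of the target selects the adjacent level pair that brackets it, and the
    duty cycle of the upper level is chosen so that the volt-time integral of
    the PWM output over the period equals the target's exactly (for targets
    within the ±2V range).  Out-of-range period averages saturate at the
    extreme level; their count is recorded on the returned plan.
    """
    if target.kind != "voltage":
        raise ValueError("PWM target must be a voltage waveform")
    period = pwm.switching_period
    n_per = period / target.dt
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            "switching period must be an integer multiple of the target dt"
        )
    n_per = int(round(n_per))

    samples = target.samples
    if pwm.pulse_duration is not None:
        n_mod = int(round(pwm.pulse_duration / target.dt))
        samples = samples[:n_mod]
    n_periods = int(math.ceil(samples.size / n_per))
    padded = np.zeros(n_periods * n_per)
    padded[: samples.size] = samples

    means = padded.reshape(n_periods, n_per).mean(axis=1)
    levels = pwm.levels
    v_max = levels[-1]

    lo = np.empty(n_periods)
    hi = np.empty(n_periods)
    duty = np.empty(n_periods)
    n_sat = 0
    for j, u in enumerate(means):
        if u >= v_max:
            lo[j] = hi[j] = v_max
            duty[j] = 1.0
            if u > v_max:
                n_sat += 1
            continue
        if u <= -v_max:
            lo[j] = hi[j] = -v_max
            duty[j] = 1.0
            if u < -v_max:
                n_sat += 1
            continue
        k = int(np.searchsorted(levels, u, side="right")) - 1
        lo[j], hi[j] = levels[k], levels[k + 1]
        duty[j] = (u - lo[j]) / (hi[j] - lo[j])
    if n_sat:
        import warnings

        warnings.warn(
            f"{n_sat} switching period(s) exceeded the ±{v_max:.0f} V range "
            "and were saturated",
            stacklevel=2,
        )

    plan = SwitchingPlan(
        period=period,
        start_times=np.arange(n_periods) * period,
        level_lo=lo,
        level_hi=hi,
        duty=duty,
        placement=pwm.placement,
        n_saturated=n_sat,
    )

    # Render on the target grid: upper level during the on-window, with the
    # on-window centered in the period (or starting at its leading edge).
    out = np.empty(n_periods * n_per)
    for j in range(n_periods):
        block = np.full(n_per, lo[j])
        n_on = int(round(duty[j] * n_per))
        if pwm.placement == "centered":
            s = (n_per - n_on) // 2
        else:
            s = 0
        block[s : s + n_on] = hi[j]
        out[j * n_per : (j + 1) * n_per] = block
    # keep the rendered record the same length as the full target
    if out.size < target.samples.size:
        out = np.concatenate([out, np.zeros(target.samples.size - out.size)])
    voltage = SampledWaveform(target.dt, out, "voltage", "five-level PWM coil voltage")
    return plan, voltage


def coil_current_from_voltage(
    voltage: SampledWaveform, config: DeviceConfig
) -> SampledWaveform:
    """Integrate the coil current from a terminal-voltage waveform.

    Solves ``di/dt = (v - R i) / L`` with ``i(0) = 0`` by the implicit
    trapezoidal rule at the waveform's own step (unconditionally stable, so
    staircase PWM voltages integrate without ringing).
    """
    if voltage.kind != "voltage":
        raise ValueError("input must be a voltage waveform")
    L, R = config.inductance, config.coil_resistance
    dt = voltage.dt
    v = voltage.samples
    from scipy.signal import lfilter

    a = 1.0 - R * dt / (2.0 * L)
    b = 1.0 + R * dt / (2.0 * L)
    c = dt / (2.0 * L)
    # i_{k+1} = (a i_k + c (v_k + v_{k+1})) / b  — a first-order recursion
    i = np.empty_like(v)
    i[0] = 0.0
    i[1:] = lfilter([c / b], [1.0, -a / b], v[:-1] + v[1:])
    return SampledWaveform(dt, i, "current", f"current from '{voltage.label}'")


def calibrate_intensity_scale(
    wave_a: SampledWaveform, wave_b: SampledWaveform
) -> float:
    """Ratio of positive peak coil voltages, ``max(a) / max(b)``.

    Used to express the PWM device's intensity on the conventional device's
    percent-of-maximum-stimulator-output scale by matching positive peak
    coil voltages.
    """
    if wave_a.kind != "voltage" or wave_b.kind != "voltage":
        raise ValueError("intensity calibration requires two voltage waveforms")
    pa, pb = wave_a.samples.max(), wave_b.samples.max()
    if pa <= 0 or pb <= 0:
        raise ValueError("both waveforms must have a positive peak")
    return float(pa / pb)
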