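"""Magnitude spectra of coil-voltage pulses and harmonic summaries.

A TMS pulse is a transient with compact support, so its spectrum is computed
as the discrete Fourier transform of the zero-padded record with a
rectangular window.  "Fundamental" here means the dominant low-frequency
component — the global magnitude maximum over f > 0 — and all magnitudes are
expressed as a percentage of it, which is the convention used when comparing
the switching harmonics of a PWM device against a conventional one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq
from scipy.signal import find_peaks

from .waveforms import SampledWaveform

__all__ = ["Spectrum", "HarmonicSummary", "compute_spectrum", "harmonic_summary"]

#: minimum zero-padded record length (µs) → ≤ 0.05 kHz frequency resolution
_MIN_PADDED_US = 20_000.0


@dataclass
class Spectrum:
    """One-sided magnitude spectrum normalized to the fundamental.

    ``frequencies`` are in kilohertz on a uniform grid; ``magnitude`` is in
    percent of the fundamental; ``magnitude_abs`` keeps the raw DFT
    magnitudes (in V·µs for a voltage waveform) for energy checks.
    """

    frequencies: np.ndarray
    magnitude: np.ndarray
    fundamental_frequency: float
    fundamental_magnitude: float
    magnitude_abs: np.ndarray

    def __post_init__(self) -> None:
        df = np.diff(self.frequencies)
        if np.any(df <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if df[0] > 0.1 + 1e-12:
            raise ValueError("frequency resolution must be at most 0.1 kHz")

    @property
    def resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def at(self, frequency: float) -> float:
        """Percent-of-fundamental magnitude at the nearest grid point."""
        idx = int(np.argmin(np.abs(self.frequencies - frequency)))
        return float(self.magnitude[idx])


@dataclass
class HarmonicSummary:
    """Largest above-fundamental harmonic of one spectrum, probed in another."""

    largest_harmonic_frequency: float     # kHz
    largest_harmonic_magnitude: float     # % of fundamental
    comparison_magnitude_at_frequency: float  # % of the other's fundamental
    harmonic_found: bool = True


def compute_spectrum(
    wave: SampledWaveform, min_padded_us: float = _MIN_PADDED_US
) -> Spectrum:
    """Magnitude spectrum of a pulse, in percent of the fundamental.

    The record must contain the whole pulse: samples at both ends larger
    than 1 % of the peak magnitude are rejected because truncating an
    undecayed tail (or a pulse that starts before the record) would smear
    leakage across the spectrum.  ``min_padded_us`` controls the zero-padded
    length (default 20 ms → 0.05 kHz resolution).
    """
    x = wave.samples
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("cannot compute a spectrum of an all-zero waveform")
    if abs(x[0]) > 0.01 * peak or abs(x[-1]) > 0.01 * peak:
        raise ValueError(
            "waveform is not decayed at the record boundaries "
            "(|end samples| > 1% of peak); pad the record first"
        )
    if min_padded_us < 10_000.0:
        raise ValueError("padded length below 10 ms gives > 0.1 kHz resolution")
    n = next_fast_len(max(x.size, int(np.ceil(min_padded_us / wave.dt))))
    mag = np.abs(rfft(x, n=n)) * wave.dt          # V·µs for a voltage input
    freq = rfftfreq(n, d=wave.dt) * 1e3           # µs grid → kHz
    k0 = 1 + int(np.argmax(mag[1:]))              # fundamental: global max, f > 0
    fund = mag[k0]
    return Spectrum(
        frequencies=freq,
        magnitude=100.0 * mag / fund,
        fundamental_frequency=float(freq[k0]),
        fundamental_magnitude=float(fund),
        magnitude_abs=mag,
    )


def harmonic_summary(
    spec: Spectrum, other: Spectrum, search_floor: float = 10.0
) -> HarmonicSummary:
    """Locate the largest harmonic of ``spec`` above ``search_floor`` (kHz)
    and probe ``other`` at that frequency.

    The harmonic is the largest *local* magnitude maximum above the floor,
    which skips the monotone skirt of the fundamental lobe.  If no local
    maximum exists above the floor the summary flags the harmonic as absent
    and reports the largest bin instead.
    """
    if spec.frequencies.size != other.frequencies.size or not np.allclose(
        spec.frequencies, other.frequencies
    ):
        raise ValueError("both spectra must share the same frequency grid")
    if search_floor <= spec.fundamental_frequency:
        raise ValueError("search_floor must lie above the fundamental")
    mask = spec.frequencies >= search_floor
    mag = spec.magnitude[mask]
    peaks, _ = find_peaks(mag)
    if peaks.size == 0:
        idx = int(np.argmax(mag))
        found = False
    else:
        idx = int(peaks[np.argmax(mag[peaks])])
        found = True
    offset = int(np.argmax(mask))
    k = offset + idx
    f_h = float(spec.frequencies[k])
    return HarmonicSummary(
        largest_harmonic_frequency=f_h,
        largest_harmonic_magnitude=float(spec.magnitude[k]),
        comparison_magnitude_at_frequency=other.at(f_h),
        harmonic_found=found,
    )
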