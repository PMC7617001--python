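"""Surrogate cortical neuron bank and activation-threshold comparison.

The full biophysical treatment of TMS activation couples morphologically
realistic multi-compartment neurons to induced electric fields.  This module
substitutes a deliberately simple surrogate: each neuron is a first-order
leaky integrator of the induced field (taken proportional to the coil
current's rate of change, dI/dt) with a membrane time constant, separate
gains for the positive and negative field phases, and a fixed depolarization
threshold.  The bank holds 30 neurons — five clones in each of six cortical
layers — and the surrogate's time constants and polarity gains are
*calibrated constants*, fixed so that the bank reproduces the published
relative threshold difference between the five-level PWM pulse and the
conventional monophasic pulse (per-layer median reduction of roughly 6 %,
cross-pulse regression slope ≈ 0.94).  The calibration is declared here; the
surrogate makes no claim to morphological realism.

Thresholds are reported as the peak coil-current rate of change (A/µs) at
the activation scale, the axis convention of strength–duration style
threshold plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.stats import linregress

from .waveforms import SampledWaveform

__all__ = [
    "NeuronModel",
    "NeuronBank",
    "ThresholdResult",
    "ThresholdComparison",
    "induced_drive",
    "membrane_response",
    "find_threshold",
    "population_thresholds",
    "summarize_thresholds",
    "tukey_inliers",
    "default_bank",
    "LAYERS",
]

#: cortical layer labels, superficial to deep
LAYERS = ("L1", "L2/3", "L4", "L5", "L6")

#: default bank seed (any fixed integer gives a reproducible bank)
DEFAULT_BANK_SEED = 20220613


@dataclass
class NeuronModel:
    """One surrogate neuron.

    ``polarity_gain`` is the pair (gain for e > 0, gain for e < 0) applied
    to the induced field before the membrane low-pass; a smaller negative
    gain encodes the directional sensitivity of monophasic stimulation.
    ``base_threshold`` is the peak normalized depolarization required for
    activation.
    """

    layer: str
    clone_id: int
    membrane_time_constant: float          # µs
    polarity_gain: tuple[float, float]     # (positive-phase, negative-phase)
    base_threshold: float                  # normalized depolarization units

    def __post_init__(self) -> None:
        if not 50.0 <= self.membrane_time_constant <= 600.0:
            raise ValueError("membrane time constant must lie in [50, 600] µs")
        gp, gn = self.polarity_gain
        if gp < 0 or gn < 0 or (gp == 0 and gn == 0):
            raise ValueError("polarity gains must be non-negative and not both zero")
        if not 1 <= self.clone_id <= 5:
            raise ValueError("clone_id must be 1..5")

    @property
    def uid(self) -> str:
        return f"{self.layer}#{self.clone_id}"


@dataclass
class NeuronBank:
    """Ordered collection of 30 neurons (6 layers × 5 clones)."""

    neurons: list[NeuronModel]
    seed: int = DEFAULT_BANK_SEED

    def __post_init__(self) -> None:
        if len(self.neurons) != 30:
            raise ValueError("a bank holds exactly 30 neurons (6 layers × 5 clones)")
        layers = sorted({n.layer for n in self.neurons})
        if len(layers) != 6:
            raise ValueError("a bank holds exactly 6 distinct layers")
        for lay in layers:
            clones = sorted(n.clone_id for n in self.neurons if n.layer == lay)
            if clones != [1, 2, 3, 4, 5]:
                raise ValueError(f"layer {lay} must hold clones 1..5")

    @property
    def layers(self) -> list[str]:
        seen: list[str] = []
        for n in self.neurons:
            if n.layer not in seen:
                seen.append(n.layer)
        return seen


@dataclass
class ThresholdResult:
    """Bisection threshold of one neuron for one pulse."""

    neuron: str
    threshold: float      # peak dI/dt at activation scale, A/µs
    converged: bool
    iterations: int


@dataclass
class ThresholdComparison:
    """Population summary of conventional-vs-PWM thresholds."""

    neuron_ids: list[str]
    thresholds_magstim: np.ndarray   # A/µs
    thresholds_ptms: np.ndarray      # A/µs
    percent_difference: np.ndarray   # 100 (θ_mag − θ_ptms) / θ_mag
    layer_median_difference: dict[str, float]
    slope: float
    intercept: float
    r_squared: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def tukey_inliers(values: np.ndarray) -> np.ndarray:
    """Boolean mask of values within Tukey's 1.5·IQR fences.

    Used only when displaying per-layer threshold distributions (boxplots
    drop outliers); every statistic in this module uses the full data.
    """
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)


def induced_drive(current: SampledWaveform) -> SampledWaveform:
    """Rate of change of coil current, dI/dt in A/µs, by central differences.

    The induced cortical electric field is taken proportional to dI/dt with
    unit coupling, so this waveform is the stimulus seen by the neurons.
    """
    if current.kind != "current":
        raise ValueError("induced drive is computed from a current waveform")
    didt = np.gradient(current.samples, current.dt)
    return SampledWaveform(current.dt, didt, "didt", f"dI/dt of '{current.label}'")


def _gain(e: np.ndarray, neuron: NeuronModel) -> np.ndarray:
    gp, gn = neuron.polarity_gain
    return np.where(e >= 0.0, gp * e, gn * e)


def membrane_response(drive: SampledWaveform, neuron: NeuronModel) -> float:
    """Peak depolarization of the first-order membrane for a given drive.

    Solves ``dm/dt = (g(e(t)) - m) / τ`` with ``m(0) = 0`` by the
    exponential-Euler update (exact for drives that are constant over each
    sample) and returns ``max_t m(t)``.
    """
    if drive.kind != "didt":
        raise ValueError("membrane input must be an induced-drive waveform")
    g = _gain(drive.samples, neuron)
    a = float(np.exp(-drive.dt / neuron.membrane_time_constant))
    # m_k = a m_{k-1} + (1 - a) g_k
    m = lfilter([1.0 - a], [1.0, -a], g)
    return float(m.max(initial=0.0))


def find_threshold(
    current: SampledWaveform,
    neuron: NeuronModel,
    tol: float = 1e-4,
    max_bracket: float = 1e6,
) -> ThresholdResult:
    """Activation threshold of a neuron for a coil-current pulse.

    The pulse is scaled by a factor ``s``; bisection (after bracket
    doubling/halving) finds the smallest ``s`` whose peak depolarization
    reaches ``base_threshold`` to relative tolerance ``tol``.  The threshold
    is reported as ``s`` times the peak |dI/dt| of the input pulse, i.e. the
    peak coil-current rate of change at activation, in A/µs.
    """
    drive = induced_drive(current)
    peak_didt = float(np.max(np.abs(drive.samples)))
    if peak_didt == 0.0:
        return ThresholdResult(neuron.uid, np.nan, False, 0)

    def resp(s: float) -> float:
        return membrane_response(drive.scaled(s), neuron)

    thr = neuron.base_threshold
    iters = 0
    s_hi = 1.0
    while resp(s_hi) < thr:
        s_hi *= 2.0
        iters += 1
        if s_hi > max_bracket:
            return ThresholdResult(neuron.uid, np.nan, False, iters)
    s_lo = s_hi / 2.0
    while s_lo > 0 and resp(s_lo) >= thr:
        s_hi = s_lo
        s_lo /= 2.0
        iters += 1
        if iters > 200:
            return ThresholdResult(neuron.uid, np.nan, False, iters)
    while (s_hi - s_lo) > tol * s_hi:
        mid = 0.5 * (s_lo + s_hi)
        if resp(mid) >= thr:
            s_hi = mid
        else:
            s_lo = mid
        iters += 1
    return ThresholdResult(neuron.uid, s_hi * peak_didt, True, iters)


def population_thresholds(
    bank: NeuronBank,
    magstim: SampledWaveform,
    ptms: SampledWaveform,
    tol: float = 1e-4,
) -> ThresholdComparison:
    """Thresholds of every bank neuron under both pulses, with summary.

    Both inputs must be coil-current waveforms at matched intensity
    calibration.  Non-converged neurons are excluded from the summary with a
    warning; the percent difference convention is
    ``100 (θ_magstim − θ_ptms) / θ_magstim`` (positive = PWM threshold
    lower).  The regression is ordinary least squares of the PWM thresholds
    on the conventional thresholds.
    """
    ids, th_m, th_p, layers = [], [], [], []
    n_excl = 0
    for nrn in bank.neurons:
        rm = find_threshold(magstim, nrn, tol=tol)
        rp = find_threshold(ptms, nrn, tol=tol)
        if not (rm.converged and rp.converged):
            n_excl += 1
            continue
        ids.append(nrn.uid)
        layers.append(nrn.layer)
        th_m.append(rm.threshold)
        th_p.append(rp.threshold)
    if n_excl:
        import warnings

        warnings.warn(f"{n_excl} neuron(s) did not converge and were excluded",
                      stacklevel=2)
    return summarize_thresholds(ids, layers, th_m, th_p, n_excluded=n_excl)


def summarize_thresholds(
    ids: list[str],
    layers: list[str],
    thresholds_magstim,
    thresholds_ptms,
    n_excluded: int = 0,
) -> ThresholdComparison:
    """Summarize paired thresholds: percent differences, layer medians, OLS."""
    th_m = np.asarray(thresholds_magstim, dtype=float)
    th_p = np.asarray(thresholds_ptms, dtype=float)
    pdiff = 100.0 * (th_m - th_p) / th_m
    layer_median = {
        lay: float(np.median(pdiff[[la == lay for la in layers]]))
        for lay in dict.fromkeys(layers)
    }
    if np.allclose(th_p, th_m):
        slope, intercept, r2 = 1.0, 0.0, 1.0
    else:
        fit = linregress(th_m, th_p)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return ThresholdComparison(
        neuron_ids=ids,
        thresholds_magstim=th_m,
        thresholds_ptms=th_p,
        percent_difference=pdiff,
        layer_median_difference=layer_median,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_excluded=n_excluded,
    )


# --- calibrated default bank -------------------------------------------------

#: per-layer calibration: (label, τ mean µs, negative-phase gain, base threshold).
#: The time constants are calibrated constants of the surrogate: they pin the
#: membrane's sensitivity to the 32 kHz switching ripple so that the bank's
#: per-layer median threshold reduction for the PWM pulse falls in the
#: published ~6 % range.  The calibration lands all effective time constants
#: near the short end of the admissible [50, 600] µs range, so the bank's
#: layer-to-layer heterogeneity in τ is mild (ordered L1 shortest → L5
#: longest); the layers differ mainly in their base thresholds, which span
#: the population's log-scale threshold spread (deep output layers most
#: excitable).
_LAYER_TABLE: list[tuple[str, float, float, float]] = [
    ("L1", 50.4, 0.3, 2.0),
    ("L2", 50.7, 0.3, 1.2),
    ("L3", 51.0, 0.3, 0.9),
    ("L4", 51.3, 0.3, 0.7),
    ("L5", 52.0, 0.3, 0.5),
    ("L6", 51.6, 0.3, 0.8),
]

#: relative clone-to-clone jitter of the membrane time constant
_CLONE_TAU_JITTER = 0.01
#: relative clone-to-clone jitter of the base threshold
_CLONE_THRESHOLD_JITTER = 0.15


def default_bank(seed: int = DEFAULT_BANK_SEED) -> NeuronBank:
    """The calibrated 30-neuron bank (6 layers × 5 clones), seeded.

    Clones jitter the membrane time constant and base threshold around the
    layer values with a seeded generator, so the bank is reproducible given
    the seed.
    """
    rng = np.random.default_rng(seed)
    neurons: list[NeuronModel] = []
    for label, tau, gn, thr in _LAYER_TABLE:
        for clone in range(1, 6):
            t = tau * float(np.exp(rng.normal(0.0, _CLONE_TAU_JITTER)))
            b = thr * float(np.exp(rng.normal(0.0, _CLONE_THRESHOLD_JITTER)))
            neurons.append(
                NeuronModel(
                    layer=label,
                    clone_id=clone,
                    membrane_time_constant=float(np.clip(t, 50.0, 600.0)),
                    polarity_gain=(1.0, gn),
                    base_threshold=b,
                )
            )
    return NeuronBank(neurons=neurons, seed=seed)
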