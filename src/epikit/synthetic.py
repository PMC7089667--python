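"""Synthetic inputs with known ground truth for every analysis in the package.

Four generators emulate the data the pipeline consumes:

* chronic single-channel ECoG sessions — 1/f^beta background noise,
  band-limited to the telemetry band (1–160 Hz at 256 Hz sampling), with
  embedded high-amplitude rhythmic seizure events of known start/end;
* current-clamp sweep sets from an exponential integrate-and-fire (EIF)
  model neuron with known input resistance, membrane time constant and
  spike times;
* paired excitatory/inhibitory conductance templates (24 epileptiform
  bursts) for the activity clamp;
* object-exploration bout logs for the discrimination index.

The seizure morphology (a 5 Hz rhythmic discharge with 2nd/3rd harmonics and
a short amplitude ramp at each edge) is a stand-in giving the classifier
realistic spectral contrast; it does not model chemoconvulsant EEG.  The EIF
neuron likewise exists to provide exact spike-time / passive-property ground
truth, not biophysical fidelity.

Every generator is a pure function of its parameters including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.ndimage import gaussian_filter1d

from .ecog_io import ICTAL, AnnotationSet, EcogRecording
from .ephys import StepProtocol, SweepSet

__all__ = [
    "EcogGenParams",
    "ModelCellParams",
    "SweepGroundTruth",
    "ExplorationLog",
    "generate_ecog_session",
    "generate_current_clamp_sweeps",
    "generate_conductance_templates",
    "generate_exploration_log",
    "integrate_eif",
]


# ---------------------------------------------------------------------------
# ECoG sessions


@dataclass
class EcogGenParams:
    """Parameters of a synthetic ECoG session.

    ``seizure_events`` is a list of ``(start_s, duration_s)`` pairs; events
    must be sorted, non-overlapping and lie within the session.
    ``ictal_amplitude_ratio`` is the target RMS of an ictal interval divided
    by the background RMS.
    """

    duration_s: float
    fs: float = 256.0
    background_rms: float = 50.0  # µV
    spectral_exponent: float = 1.0
    seizure_events: list[tuple[float, float]] = field(default_factory=list)
    ictal_freq_hz: float = 5.0
    ictal_amplitude_ratio: float = 6.0
    band: tuple[float, float] = (1.0, 160.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.ictal_amplitude_ratio <= 1:
            raise ValueError("ictal_amplitude_ratio must exceed 1")
        prev_end = 0.0
        for start, dur in self.seizure_events:
            if dur <= 0:
                raise ValueError(f"event at {start} s has non-positive duration")
            if start < prev_end:
                raise ValueError(
                    f"seizure events overlap or are unsorted near {start} s"
                )
            if start < 0 or start + dur > self.duration_s:
                raise ValueError(f"event ({start}, {dur}) outside the session")
            prev_end = start + dur


def _one_over_f_background(
    n: int, fs: float, rms: float, beta: float, band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited 1/f^beta Gaussian noise, normalized to the target RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = band[0], min(band[1], fs / 2)
    shape = np.zeros_like(f)
    inside = (f >= lo) & (f <= hi)
    shape[inside] = f[inside] ** (-beta / 2.0)
    x = np.fft.irfft(spec * shape, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return x


def _seizure_waveform(
    n: int, fs: float, f0: float, target_rms: float, rng: np.random.Generator,
) -> np.ndarray:
    """Rhythmic discharge: base frequency + 2nd/3rd harmonics, edge ramps."""
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, size=3)
    w = (
        np.sin(2 * np.pi * f0 * t + phases[0])
        + 0.5 * np.sin(2 * np.pi * 2 * f0 * t + phases[1])
        + 0.33 * np.sin(2 * np.pi * 3 * f0 * t + phases[2])
    )
    # slow spike-and-wave-like amplitude modulation
    w *= 1.0 + 0.3 * np.sin(2 * np.pi * 0.7 * t + phases[0])
    dur = n / fs
    ramp_s = min(1.5, dur / 4.0)
    env = np.ones(n)
    k = max(1, int(round(ramp_s * fs)))
    env[:k] = np.linspace(0.0, 1.0, k)
    env[-k:] = np.linspace(1.0, 0.0, k)
    w *= env
    w *= target_rms / np.sqrt(np.mean(w**2))
    return w


def generate_ecog_session(params: EcogGenParams) -> tuple[EcogRecording, AnnotationSet]:
    """Generate one ECoG session plus its ground-truth annotations.

    The discharge is added on top of the continuing background with an RMS of
    ``sqrt(ratio^2 - 1)`` background units, so the total RMS over each ictal
    interval is ``ictal_amplitude_ratio`` times the background RMS.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    x = _one_over_f_background(
        n, params.fs, params.background_rms, params.spectral_exponent,
        params.band, rng,
    )
    intervals: list[tuple[float, float, str]] = []
    discharge_rms = params.background_rms * np.sqrt(
        params.ictal_amplitude_ratio**2 - 1.0
    )
    for start, dur in params.seizure_events:
        i0 = int(round(start * params.fs))
        i1 = int(round((start + dur) * params.fs))
        x[i0:i1] += _seizure_waveform(
            i1 - i0, params.fs, params.ictal_freq_hz, discharge_rms, rng
        )
        intervals.append((start, start + dur, ICTAL))
    rec = EcogRecording(samples=x, fs=params.fs)
    return rec, AnnotationSet(intervals=intervals, provenance="human")


# ---------------------------------------------------------------------------
# EIF model neuron


@dataclass
class ModelCellParams:
    """Exponential integrate-and-fire neuron with a stereotyped spike shape.

    Membrane dynamics: ``tau dV/dt = -(V - E_L) + sharpness * exp((V - V_T) /
    sharpness) + R * I``.  When V reaches the blow-up cutoff (``spike_threshold
    + 5 * sharpness``) a spike is pasted: a linear rise at ``rise_rate`` to
    ``peak_v``, a linear repolarization at ``repolarization_rate`` down to
    ``reset_potential``, then an absolute refractory hold.  Spike ground-truth
    times are the pasted peaks.
    """

    resting_potential: float = -70.0  # mV
    input_resistance: float = 150.0  # MΩ
    membrane_tau: float = 15.0  # ms
    spike_threshold: float = -45.0  # mV (EIF soft threshold V_T)
    reset_potential: float = -65.0  # mV
    refractory: float = 2.0  # ms
    sharpness: float = 2.0  # mV (EIF Delta_T)
    rise_rate: float = 400.0  # mV/ms, spike upstroke
    repolarization_rate: float = 100.0  # mV/ms, spike downstroke
    peak_v: float = 35.0  # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.membrane_tau <= 0:
            raise ValueError("membrane_tau must be positive")
        if self.input_resistance <= 0:
            raise ValueError("input_resistance must be positive")
        if self.reset_potential >= self.spike_threshold:
            raise ValueError("reset_potential must lie below spike_threshold")


@njit(cache=True)
def _eif_kernel(
    i_ext, g_exc, g_inh, e_exc, e_inh, extra_g, e_extra,
    dt, e_l, r_mv_per_pa, tau, v_t, delta_t, v_reset, refrac_steps,
    v_cut, v_peak, rise_rate, repol_rate, v0,
):  # pragma: no cover - exercised via integrate_eif
    n = i_ext.size
    v = np.empty(n)
    spike_idx = np.empty(n, dtype=np.int64)
    n_spk = 0
    vi = v0
    phase = 0  # 0 integrate, 1 rise, 2 fall, 3 refractory
    hold = 0
    for i in range(n):
        if phase == 0:
            i_syn = (
                g_exc[i] * (e_exc - vi)
                + g_inh[i] * (e_inh - vi)
                + extra_g * (e_extra - vi)
            )
            drive = (
                -(vi - e_l)
                + delta_t * np.exp((vi - v_t) / delta_t)
                + r_mv_per_pa * (i_ext[i] + i_syn)
            )
            vi = vi + dt * drive / tau
            if not np.isfinite(vi) or vi > 500.0:
                return v, spike_idx[:n_spk], -(i + 1)
            if vi >= v_cut:
                phase = 1
        elif phase == 1:
            vi = vi + rise_rate * dt
            if vi >= v_peak:
                vi = v_peak
                spike_idx[n_spk] = i
                n_spk += 1
                phase = 2
        elif phase == 2:
            vi = vi - repol_rate * dt
            if vi <= v_reset:
                vi = v_reset
                phase = 3
                hold = refrac_steps
        else:
            hold -= 1
            if hold <= 0:
                phase = 0
        v[i] = vi
    return v, spike_idx[:n_spk], 0


def integrate_eif(
    cell: ModelCellParams,
    dt_ms: float,
    i_ext: np.ndarray | None = None,
    g_exc: np.ndarray | None = None,
    g_inh: np.ndarray | None = None,
    e_exc_mv: float = 0.0,
    e_inh_mv: float = -75.0,
    extra_g_ns: float = 0.0,
    e_extra_mv: float = -90.0,
    n_steps: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the EIF cell with injected current and/or conductances.

    ``i_ext`` is in pA; conductances in nS (``g * (E - V)`` then gives pA).
    Returns the voltage trace (mV) and spike peak times (ms).  Raises
    ``FloatingPointError`` naming the step if the integration diverges.
    """
    if n_steps is None:
        for arr in (i_ext, g_exc, g_inh):
            if arr is not None:
                n_steps = len(arr)
                break
        else:
            raise ValueError("need i_ext, g_exc, g_inh or n_steps")
    zeros = np.zeros(n_steps)
    i_ext = zeros if i_ext is None else np.ascontiguousarray(i_ext, dtype=float)
    g_exc = zeros if g_exc is None else np.ascontiguousarray(g_exc, dtype=float)
    g_inh = zeros if g_inh is None else np.ascontiguousarray(g_inh, dtype=float)
    v, spikes, status = _eif_kernel(
        i_ext, g_exc, g_inh, e_exc_mv, e_inh_mv, float(extra_g_ns), e_extra_mv,
        float(dt_ms), cell.resting_potential,
        cell.input_resistance * 1e-3,  # MΩ * pA -> µV, scaled to mV
        cell.membrane_tau, cell.spike_threshold, cell.sharpness,
        cell.reset_potential, max(1, int(round(cell.refractory / dt_ms))),
        cell.spike_threshold + 5.0 * cell.sharpness, cell.peak_v,
        cell.rise_rate, cell.repolarization_rate, cell.resting_potential,
    )
    if status < 0:
        raise FloatingPointError(
            f"EIF integration diverged at step {-status - 1} (dt={dt_ms} ms)"
        )
    return v, spikes * dt_ms


# ---------------------------------------------------------------------------
# Current-clamp sweeps


@dataclass
class SweepGroundTruth:
    """True model-cell quantities behind a generated sweep set."""

    spike_times_ms: list[np.ndarray]
    input_resistance_mohm: float
    tau_ms: float
    capacitance_pf: float
    rheobase_pa: float | None
    resting_potential_mv: float


def _voltage_noise(n: int, dt_ms: float, rms_mv: float, rng: np.random.Generator) -> np.ndarray:
    """Additive white Gaussian voltage noise.

    At the default 0.2 mV RMS and 0.02 ms sampling the central-difference
    dV/dt noise is ~7 mV/ms — well below the 20 mV/ms spike criterion, so
    the noise does not confound AP detection.
    """
    if rms_mv == 0:
        return np.zeros(n)
    return rms_mv * rng.standard_normal(n)


def generate_current_clamp_sweeps(
    protocol: StepProtocol,
    cell: ModelCellParams,
    noise_rms_mv: float = 0.2,
    dt_ms: float = 0.02,
) -> tuple[SweepSet, SweepGroundTruth]:
    """Simulate the step protocol on the EIF cell.

    Subthreshold sweeps follow ``V(t) = V_rest + I R (1 - exp(-t/tau))`` (up to
    the integration step and the vanishing EIF exponential term) plus optional
    additive voltage noise.  The ground truth carries exact spike peak times,
    the true R, tau and C = tau / R, and the rheobase read off the simulated
    spike counts.
    """
    rng = np.random.default_rng(cell.seed)
    n = int(round(protocol.sweep_duration_ms / dt_ms))
    onset = int(round(protocol.step_onset_ms / dt_ms))
    offset = onset + int(round(protocol.step_duration_ms / dt_ms))
    amplitudes = protocol.amplitudes_pa()
    voltages = np.empty((len(amplitudes), n))
    currents = np.zeros((len(amplitudes), n))
    spike_times: list[np.ndarray] = []
    for k, amp in enumerate(amplitudes):
        i_ext = np.zeros(n)
        i_ext[onset:offset] = amp
        v, spk = integrate_eif(cell, dt_ms, i_ext=i_ext)
        v = v + _voltage_noise(n, dt_ms, noise_rms_mv, rng)
        voltages[k] = v
        currents[k] = i_ext
        spike_times.append(spk)
    rheo = None
    for amp, spk in zip(amplitudes, spike_times):
        if spk.size > 0:
            rheo = float(amp)
            break
    truth = SweepGroundTruth(
        spike_times_ms=spike_times,
        input_resistance_mohm=cell.input_resistance,
        tau_ms=cell.membrane_tau,
        capacitance_pf=cell.membrane_tau / cell.input_resistance * 1e3,
        rheobase_pa=rheo,
        resting_potential_mv=cell.resting_potential,
    )
    return SweepSet(voltages=voltages, currents=currents, dt_ms=dt_ms,
                    protocol=protocol), truth


# ---------------------------------------------------------------------------
# Conductance templates (activity clamp)


def generate_conductance_templates(
    n_bursts: int = 24,
    burst_duration_s: float = 0.3,
    peak_g_exc: float = 12.0,
    peak_g_inh: float = 4.0,
    gap_s: float = 0.7,
    lead_s: float = 0.5,
    iteration_hz: float = 15000.0,
    seed: int = 0,
):
    """Generate paired excitatory/inhibitory burst conductance templates.

    Each burst is a Hann envelope times a slow positive modulation; the
    inhibitory series lags the excitatory one by ~3 ms, as inhibition follows
    recurrent excitation during an epileptiform barrage.  The default peaks
    are excitation-dominated (E/I 3:1) so the combined synaptic reversal
    (~−34 mV after junction correction) lies above a typical spike threshold
    — the barrage must be pro-convulsive for a conductance threshold to
    exist.  The global maximum
    of each series equals its requested peak exactly (when positive).
    Returns a :class:`~epikit.activity_clamp.ConductanceTemplate` sampled at
    the activity-clamp iteration rate.
    """
    from .activity_clamp import ConductanceTemplate  # deferred: avoids cycle

    if n_bursts < 1:
        raise ValueError("n_bursts must be >= 1")
    if peak_g_exc < 0 or peak_g_inh < 0:
        raise ValueError("peak conductances must be non-negative")
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / iteration_hz
    burst_n = int(round(burst_duration_s * iteration_hz))
    gap_n = int(round(gap_s * iteration_hz))
    lead_n = int(round(lead_s * iteration_hz))
    total = lead_n + n_bursts * burst_n + (n_bursts - 1) * gap_n + lead_n
    g_exc = np.zeros(total)
    g_inh = np.zeros(total)
    bounds: list[tuple[float, float]] = []
    env = np.hanning(burst_n)
    lag = int(round(3.0 / dt_ms))  # 3 ms E->I lag
    sigma = max(1.0, 10.0 / dt_ms)  # ~10 ms modulation scale
    scales = rng.uniform(0.75, 1.0, size=n_bursts)
    scales[rng.integers(n_bursts)] = 1.0
    for b in range(n_bursts):
        i0 = lead_n + b * (burst_n + gap_n)
        mod_e = 1.0 + 0.15 * gaussian_filter1d(rng.standard_normal(burst_n), sigma)
        mod_i = 1.0 + 0.15 * gaussian_filter1d(rng.standard_normal(burst_n), sigma)
        g_exc[i0 : i0 + burst_n] = env * np.clip(mod_e, 0.3, None) * scales[b]
        seg = env * np.clip(mod_i, 0.3, None) * scales[b]
        g_inh[i0 + lag : i0 + lag + burst_n] = seg
        bounds.append((i0 * dt_ms / 1000.0, (i0 + burst_n + lag) * dt_ms / 1000.0))
    for g, peak in ((g_exc, peak_g_exc), (g_inh, peak_g_inh)):
        m = g.max()
        if peak > 0 and m > 0:
            g *= peak / m
        else:
            g[:] = 0.0
    return ConductanceTemplate(
        g_exc=g_exc, g_inh=g_inh, dt_ms=dt_ms, burst_bounds_s=bounds
    )


# ---------------------------------------------------------------------------
# Exploration logs


@dataclass
class ExplorationLog:
    """Bout-level object-exploration log.

    ``bouts`` holds ``(object_id, start_s, duration_s)`` with object ids
    ``altered`` / ``unchanged``.  ``no_exploration`` flags an empty session.
    """

    bouts: list[tuple[str, float, float]] = field(default_factory=list)
    no_exploration: bool = False

    def total(self, object_id: str) -> float:
        return float(sum(d for o, _, d in self.bouts if o == object_id))


def generate_exploration_log(
    t_altered: float, t_unchanged: float, seed: int = 0, mean_bout_s: float = 2.0
) -> ExplorationLog:
    """Split requested per-object exploration totals into interleaved bouts."""
    if t_altered < 0 or t_unchanged < 0:
        raise ValueError("exploration totals must be non-negative")
    if t_altered == 0 and t_unchanged == 0:
        return ExplorationLog(bouts=[], no_exploration=True)
    rng = np.random.default_rng(seed)
    pieces: list[tuple[str, float]] = []
    for obj, total in (("altered", t_altered), ("unchanged", t_unchanged)):
        if total == 0:
            continue
        k = max(1, int(round(total / mean_bout_s)))
        frac = rng.dirichlet(np.ones(k) * 4.0)
        pieces.extend((obj, float(total * f)) for f in frac)
    order = rng.permutation(len(pieces))
    t = 0.0
    bouts = []
    for j in order:
        obj, dur = pieces[j]
        bouts.append((obj, t, dur))
        t += dur + float(rng.uniform(0.5, 3.0))
    return ExplorationLog(bouts=bouts)
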