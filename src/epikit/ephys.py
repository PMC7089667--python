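"""Automated current-clamp analysis: AP detection, firing curves, passives.

An event is counted as an action potential if the trace crosses 0 mV upward
and the preceding rising phase reaches dV/dt > 20 mV/ms; detection applies to
sweeps with injected current in the 0–500 pA range.  Passive membrane
properties come from the hyperpolarizing steps of the protocol: per-step
input resistance is the steady-state ΔV/ΔI, the reported R averages the two
most negative steps and the first subthreshold positive step, tau is a
single-exponential fit of the voltage relaxation on the largest
hyperpolarizing step, and capacitance = tau / R.

Units: voltage mV, current pA, time ms, resistance MΩ, capacitance pF.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "StepProtocol",
    "SweepSet",
    "APEvent",
    "PassiveProperties",
    "FiringCurve",
    "detect_aps",
    "ap_half_width",
    "firing_curve",
    "passive_properties",
    "write_sweeps",
    "read_sweeps",
]

SLOPE_CRITERION_MV_PER_MS = 20.0
CROSS_LEVEL_MV = 0.0
DETECT_CURRENT_RANGE_PA = (0.0, 500.0)


@dataclass
class StepProtocol:
    """Square current-step protocol: 250-ms steps from −20 pA in 10 pA increments."""

    step_duration_ms: float = 250.0
    start_amplitude_pa: float = -20.0
    increment_pa: float = 10.0
    n_steps: int = 25
    step_onset_ms: float = 50.0
    tail_ms: float = 100.0
    holding_potential_mv: float = -70.0

    def __post_init__(self) -> None:
        if self.increment_pa <= 0:
            raise ValueError("increment_pa must be positive")
        if self.step_duration_ms <= 0:
            raise ValueError("step_duration_ms must be positive")

    def amplitudes_pa(self) -> np.ndarray:
        return self.start_amplitude_pa + self.increment_pa * np.arange(self.n_steps)

    @property
    def sweep_duration_ms(self) -> float:
        return self.step_onset_ms + self.step_duration_ms + self.tail_ms


@dataclass
class SweepSet:
    """Stacked current-clamp sweeps: voltage (mV) and injected current (pA)."""

    voltages: np.ndarray  # (n_sweeps, n_samples)
    currents: np.ndarray  # (n_sweeps, n_samples)
    dt_ms: float
    protocol: StepProtocol

    def __post_init__(self) -> None:
        self.voltages = np.atleast_2d(np.asarray(self.voltages, dtype=float))
        self.currents = np.atleast_2d(np.asarray(self.currents, dtype=float))
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltage and current arrays must have equal shape")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")

    @property
    def n_sweeps(self) -> int:
        return self.voltages.shape[0]

    def step_amplitude_pa(self, k: int) -> float:
        """Injected amplitude of sweep ``k`` read off the current trace."""
        i = self.currents[k]
        nz = i[np.abs(i) > 1e-12]
        return float(nz[0]) if nz.size else 0.0


@dataclass
class APEvent:
    """One detected action potential and its measured properties."""

    peak_time_ms: float
    threshold_time_ms: float
    threshold_v_mv: float
    peak_v_mv: float
    half_width_ms: float
    max_rise_slope_mv_per_ms: float


def _dvdt(v: np.ndarray, dt_ms: float) -> np.ndarray:
    """dV/dt by central differences (one-sided at the ends)."""
    return np.gradient(v, dt_ms)


def detect_aps(
    sweep_v: np.ndarray,
    dt_ms: float,
    injected_current_pa: float | None = None,
    slope_criterion: float = SLOPE_CRITERION_MV_PER_MS,
    cross_level: float = CROSS_LEVEL_MV,
) -> list[APEvent]:
    """Detect action potentials in one voltage sweep.

    One event per upward crossing of ``cross_level`` whose preceding rising
    phase reaches ``dV/dt > slope_criterion``; the next event is not
    registered until the voltage falls back below the crossing level.  The
    threshold point is found by walking backward from the crossing through
    the contiguous run of samples with ``dV/dt >= slope_criterion``.  If
    ``injected_current_pa`` is given and lies outside 0–500 pA the sweep is
    ineligible and no events are returned.
    """
    v = np.asarray(sweep_v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("sweep contains non-finite samples")
    if dt_ms > 0.1:
        warnings.warn(
            f"dt = {dt_ms} ms is coarse for AP detection (want <= 0.1 ms)",
            stacklevel=2,
        )
    if injected_current_pa is not None and not (
        DETECT_CURRENT_RANGE_PA[0] <= injected_current_pa <= DETECT_CURRENT_RANGE_PA[1]
    ):
        return []
    dvdt = _dvdt(v, dt_ms)
    above = v >= cross_level
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    events: list[APEvent] = []
    for c in crossings:
        # peak: maximum until the trace falls back below the crossing level
        fall = np.flatnonzero(v[c:] < cross_level)
        end = c + (fall[0] if fall.size else v.size - c)
        peak_i = c + int(np.argmax(v[c:end])) if end > c else c
        # rising-phase slope check, walking back from the crossing
        j = c
        while j > 0 and dvdt[j - 1] >= slope_criterion:
            j -= 1
        rise_max = float(np.max(dvdt[j : peak_i + 1])) if peak_i >= j else 0.0
        if rise_max <= slope_criterion:
            continue
        thr_i = j if dvdt[j] >= slope_criterion else c
        ev = APEvent(
            peak_time_ms=peak_i * dt_ms,
            threshold_time_ms=thr_i * dt_ms,
            threshold_v_mv=float(v[thr_i]),
            peak_v_mv=float(v[peak_i]),
            half_width_ms=np.nan,
            max_rise_slope_mv_per_ms=rise_max,
        )
        try:
            ev.half_width_ms = ap_half_width(v, ev, dt_ms)
        except ValueError:
            ev.half_width_ms = np.nan
        events.append(ev)
    return events


def ap_half_width(trace: np.ndarray, event: APEvent, dt_ms: float) -> float:
    """Full width at half threshold-to-peak amplitude, by linear interpolation."""
    v = np.asarray(trace, dtype=float)
    peak_i = int(round(event.peak_time_ms / dt_ms))
    half = event.threshold_v_mv + 0.5 * (event.peak_v_mv - event.threshold_v_mv)
    if event.peak_v_mv <= half:
        raise ValueError("malformed event: peak does not exceed half level")

    def _cross(i0: int, step: int) -> float:
        i = peak_i
        while 0 < i < v.size - 1 and v[i] > half:
            i += step
        if v[i] > half:
            raise ValueError("half level not reached within the trace")
        a, b = (i, i - step) if step < 0 else (i - step, i)
        # linear interpolation between the samples bracketing the half level
        lo_i, hi_i = (a, b)
        frac = (half - v[lo_i]) / (v[hi_i] - v[lo_i])
        return (lo_i + frac * (hi_i - lo_i)) * dt_ms

    t_rise = _cross(peak_i, -1)
    t_fall = _cross(peak_i, +1)
    return t_fall - t_rise


@dataclass
class FiringCurve:
    """Firing rate per current step, its maximum, and the current threshold."""

    amplitudes_pa: np.ndarray
    rates_hz: np.ndarray
    max_rate_hz: float
    current_threshold_pa: float | None


def firing_curve(sweeps: SweepSet) -> FiringCurve:
    """AP rate per step (count / step duration) and the rheobase.

    Only sweeps with injected current inside the 0–500 pA detection range
    contribute spikes; the current threshold is the lowest amplitude evoking
    at least one AP.
    """
    dur_s = sweeps.protocol.step_duration_ms / 1000.0
    amps = np.array([sweeps.step_amplitude_pa(k) for k in range(sweeps.n_sweeps)])
    counts = np.array(
        [
            len(detect_aps(sweeps.voltages[k], sweeps.dt_ms, injected_current_pa=amps[k]))
            for k in range(sweeps.n_sweeps)
        ]
    )
    rates = counts / dur_s
    thr = None
    firing = np.flatnonzero(counts > 0)
    if firing.size:
        thr = float(amps[firing[0]])
    return FiringCurve(
        amplitudes_pa=amps,
        rates_hz=rates,
        max_rate_hz=float(rates.max()) if rates.size else 0.0,
        current_threshold_pa=thr,
    )


@dataclass
class PassiveProperties:
    input_resistance_mohm: float
    tau_ms: float
    capacitance_pf: float
    resting_potential_mv: float


def _step_window(sweeps: SweepSet) -> tuple[int, int]:
    p = sweeps.protocol
    onset = int(round(p.step_onset_ms / sweeps.dt_ms))
    offset = onset + int(round(p.step_duration_ms / sweeps.dt_ms))
    return onset, offset


def passive_properties(sweeps: SweepSet) -> PassiveProperties:
    """Input resistance, membrane tau and capacitance from the step protocol.

    Per-step R = steady-state ΔV / ΔI with the steady state taken over the
    final 20% of the step; the reported R averages the two most negative
    steps and the first subthreshold positive step.  Tau comes from a
    least-squares single-exponential fit of the relaxation on the largest
    hyperpolarizing step; C = tau / R (ms/MΩ, reported in pF).
    """
    onset, offset = _step_window(sweeps)
    amps = np.array([sweeps.step_amplitude_pa(k) for k in range(sweeps.n_sweeps)])
    neg = np.flatnonzero(amps < 0)
    if neg.size < 2:
        raise ValueError("need at least two hyperpolarizing steps")
    # two most negative steps
    neg = neg[np.argsort(amps[neg])][:2]
    pos = None
    for k in np.flatnonzero(amps > 0):
        if not detect_aps(sweeps.voltages[k], sweeps.dt_ms, injected_current_pa=amps[k]):
            pos = k
            break
    if pos is None:
        raise ValueError("need one subthreshold depolarizing step")
    use = list(neg) + [pos]

    ss_start = offset - max(1, int(round(0.2 * (offset - onset))))
    r_per_step = []
    for k in use:
        v = sweeps.voltages[k]
        baseline = float(np.mean(v[:onset]))
        dv = float(np.mean(v[ss_start:offset])) - baseline
        r_per_step.append(1e3 * dv / amps[k])  # mV/pA -> GΩ -> MΩ via 1e3
    r_in = float(np.mean(r_per_step))

    # tau: largest hyperpolarizing step
    k = neg[0]
    v = sweeps.voltages[k]
    baseline = float(np.mean(v[:onset]))
    seg = v[onset:offset] - baseline
    t = np.arange(seg.size) * sweeps.dt_ms
    dv_ss = float(np.mean(seg[-max(1, seg.size // 5):]))
    # initial tau guess: time to 63% of the plateau deflection, taken on a
    # lightly smoothed copy so a single noise excursion cannot trigger it
    win = max(1, int(round(1.0 / sweeps.dt_ms)))
    smooth = np.convolve(seg, np.ones(win) / win, mode="same")
    frac = np.flatnonzero(np.abs(smooth) >= 0.632 * abs(dv_ss))
    tau0 = t[frac[0]] if frac.size else sweeps.protocol.step_duration_ms / 10
    fit_n = min(seg.size, max(64, int(round(8 * tau0 / sweeps.dt_ms))))

    # fit the boxcar-smoothed relaxation: smoothing leaves the exponential's
    # time constant untouched away from the onset (a filtered exponential is
    # a rescaled exponential), so the first window is excluded and the model
    # carries a free onset offset to absorb the rescaling
    fit_t = t[win:fit_n]
    fit_v = smooth[win:fit_n]

    def relax(tt, dv, tau, t0):
        return dv * (1.0 - np.exp(-(tt - t0) / tau))

    try:
        popt, _ = curve_fit(
            relax, fit_t, fit_v, p0=(dv_ss, max(tau0, sweeps.dt_ms), 0.0),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"exponential relaxation fit failed to converge: {err}"
        ) from err
    tau = float(abs(popt[1]))
    resid = float(np.sqrt(np.mean((relax(fit_t, *popt) - fit_v) ** 2)))
    if not np.isfinite(tau) or resid > 0.5 * abs(dv_ss):
        raise RuntimeError(
            f"exponential relaxation fit unreliable: residual RMS {resid:.3g} mV "
            f"against a {dv_ss:.3g} mV deflection"
        )
    resting = float(
        np.mean([np.mean(sweeps.voltages[k][:onset]) for k in range(sweeps.n_sweeps)])
    )
    return PassiveProperties(
        input_resistance_mohm=r_in,
        tau_ms=tau,
        capacitance_pf=tau / r_in * 1e3,  # ms/MΩ = nF -> pF
        resting_potential_mv=resting,
    )


# ---------------------------------------------------------------------------
# I/O


def write_sweeps(sweeps: SweepSet, path: str | Path) -> None:
    """Write a sweep set to HDF5 (voltage, current, dt, protocol attrs)."""
    p = sweeps.protocol
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage_mv", data=sweeps.voltages)
        f.create_dataset("current_pa", data=sweeps.currents)
        f.attrs["dt_ms"] = sweeps.dt_ms
        for name in (
            "step_duration_ms", "start_amplitude_pa", "increment_pa",
            "n_steps", "step_onset_ms", "tail_ms", "holding_potential_mv",
        ):
            f.attrs[name] = getattr(p, name)


def read_sweeps(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        proto = StepProtocol(
            step_duration_ms=float(f.attrs["step_duration_ms"]),
            start_amplitude_pa=float(f.attrs["start_amplitude_pa"]),
            increment_pa=float(f.attrs["increment_pa"]),
            n_steps=int(f.attrs["n_steps"]),
            step_onset_ms=float(f.attrs["step_onset_ms"]),
            tail_ms=float(f.attrs["tail_ms"]),
            holding_potential_mv=float(f.attrs["holding_potential_mv"]),
        )
        return SweepSet(
            voltages=f["voltage_mv"][()],
            currents=f["current_pa"][()],
            dt_ms=float(f.attrs["dt_ms"]),
            protocol=proto,
        )


def sweep_csv(sweeps: SweepSet, k: int) -> pd.DataFrame:
    """Two-column frame (t_ms, v_mv) for one sweep, for CSV export."""
    t = np.arange(sweeps.voltages.shape[1]) * sweeps.dt_ms
    return pd.DataFrame({"t_ms": t, "v_mv": sweeps.voltages[k]})
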