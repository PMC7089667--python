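"""Activity clamp: conductance-template injection against a model neuron.

The dynamic-clamp current is ``I = g_exc (E_exc_eff - V) + g_inh (E_inh_eff -
V)`` with conductances in nS, potentials in mV and current in pA.  Reversal
potentials are set to 0 mV (excitatory) and −75 mV (inhibitory) and corrected
for a 14.9 mV liquid junction potential, ``E_eff = E_set - 14.9`` (recorded
potentials read more depolarized than true; the sign convention is
configurable).  The closed loop runs at the clamp iteration frequency of
15 kHz (forward Euler), spikes are the model cell's threshold events, and
spike counts are assigned to the template's burst intervals.

``conductance_threshold`` scales both templates by a common factor and
searches (geometric bracketing then bisection, 1% relative tolerance) for the
smallest scale that evokes at least one action potential.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import ModelCellParams, integrate_eif

__all__ = [
    "ConductanceTemplate",
    "ActivityClampResult",
    "clamp_current",
    "simulate_activity_clamp",
    "conductance_threshold",
    "write_template",
    "read_template",
]

JUNCTION_POTENTIAL_MV = 14.9


@dataclass
class ConductanceTemplate:
    """Paired excitatory/inhibitory conductance series for dynamic clamp."""

    g_exc: np.ndarray  # nS
    g_inh: np.ndarray  # nS
    dt_ms: float = 1000.0 / 15000.0
    burst_bounds_s: list[tuple[float, float]] = field(default_factory=list)
    e_exc_set_mv: float = 0.0
    e_inh_set_mv: float = -75.0
    junction_potential_mv: float = JUNCTION_POTENTIAL_MV

    def __post_init__(self) -> None:
        self.g_exc = np.asarray(self.g_exc, dtype=float)
        self.g_inh = np.asarray(self.g_inh, dtype=float)
        if self.g_exc.shape != self.g_inh.shape:
            raise ValueError("g_exc and g_inh must have equal length")
        if (self.g_exc < 0).any() or (self.g_inh < 0).any():
            raise ValueError("conductances must be non-negative")
        for (s0, e0), (s1, e1) in zip(self.burst_bounds_s, self.burst_bounds_s[1:]):
            if s1 < e0:
                raise ValueError("burst intervals must be disjoint")

    @property
    def n_bursts(self) -> int:
        return len(self.burst_bounds_s)

    @property
    def e_exc_eff_mv(self) -> float:
        return self.e_exc_set_mv - self.junction_potential_mv

    @property
    def e_inh_eff_mv(self) -> float:
        return self.e_inh_set_mv - self.junction_potential_mv

    @property
    def duration_s(self) -> float:
        return self.g_exc.size * self.dt_ms / 1000.0


def clamp_current(g_exc, g_inh, v, tmpl: ConductanceTemplate):
    """Injected dynamic-clamp current (pA); positive current depolarizes."""
    return g_exc * (tmpl.e_exc_eff_mv - v) + g_inh * (tmpl.e_inh_eff_mv - v)


@dataclass
class ActivityClampResult:
    """Spike counts per epileptiform burst at one conductance scale."""

    spikes_per_burst: np.ndarray
    spike_times_ms: np.ndarray
    conductance_scale: float

    @property
    def total_spikes(self) -> int:
        return int(self.spikes_per_burst.sum())

    @property
    def mean_spikes_per_burst(self) -> float:
        return float(self.spikes_per_burst.mean()) if self.spikes_per_burst.size else 0.0


def _resample(g: np.ndarray, refine: int) -> np.ndarray:
    if refine == 1:
        return g
    n = g.size
    x = np.arange(n)
    xf = np.arange(n * refine) / refine
    return np.interp(xf, x, g)


def simulate_activity_clamp(
    tmpl: ConductanceTemplate,
    cell: ModelCellParams,
    scale: float = 1.0,
    extra_g_ns: float = 0.0,
    extra_reversal_mv: float = -90.0,
    refine: int = 1,
) -> ActivityClampResult:
    """Closed-loop activity clamp on the model cell.

    At each step the clamp current is computed from the present membrane
    potential with both conductance templates scaled by ``scale``, the cell
    is advanced one Euler step, and spikes are assigned to bursts.
    ``extra_g_ns`` adds a static leak-like conductance (e.g. a potassium
    conductance with ``extra_reversal_mv = -90``) to the cell.  ``refine``
    integrates at a multiple of the clamp rate (template linearly
    interpolated) for step-size validation.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    dt = tmpl.dt_ms / refine
    v, spikes_ms = integrate_eif(
        cell,
        dt,
        g_exc=_resample(tmpl.g_exc, refine) * scale,
        g_inh=_resample(tmpl.g_inh, refine) * scale,
        e_exc_mv=tmpl.e_exc_eff_mv,
        e_inh_mv=tmpl.e_inh_eff_mv,
        extra_g_ns=extra_g_ns,
        e_extra_mv=extra_reversal_mv,
    )
    spikes_s = spikes_ms / 1000.0
    counts = np.array(
        [
            int(np.sum((spikes_s >= s) & (spikes_s < e)))
            for s, e in tmpl.burst_bounds_s
        ],
        dtype=int,
    )
    return ActivityClampResult(
        spikes_per_burst=counts,
        spike_times_ms=spikes_ms,
        conductance_scale=scale,
    )


def conductance_threshold(
    tmpl: ConductanceTemplate,
    cell: ModelCellParams,
    scale_max: float = 100.0,
    rel_tol: float = 0.01,
    **sim_kwargs,
) -> float | None:
    """Smallest template scale that evokes at least one action potential.

    Geometric bracketing from a small scale doubles until spiking, then
    bisection narrows the bracket to ``rel_tol`` relative width.  Returns
    None (with a warning) if the cell never spikes up to ``scale_max``.
    """

    def spikes_at(s: float) -> int:
        return simulate_activity_clamp(tmpl, cell, scale=s, **sim_kwargs).total_spikes

    lo, hi = 0.0, None
    s = 0.01 * scale_max
    while s <= scale_max:
        if spikes_at(s) >= 1:
            hi = s
            break
        lo = s
        s *= 2.0
    if hi is None:
        if s / 2.0 < scale_max and spikes_at(scale_max) >= 1:
            lo, hi = s / 2.0, scale_max
        else:
            warnings.warn(
                f"no spiking up to scale_max = {scale_max}", stacklevel=2
            )
            return None
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid) >= 1:
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# I/O: 3-column CSV + JSON sidecar


def write_template(tmpl: ConductanceTemplate, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    t = np.arange(tmpl.g_exc.size) * tmpl.dt_ms
    pd.DataFrame(
        {"t_ms": t, "g_exc_nS": tmpl.g_exc, "g_inh_nS": tmpl.g_inh}
    ).to_csv(csv_path, index=False)
    sidecar = {
        "dt_ms": tmpl.dt_ms,
        "e_exc_set_mv": tmpl.e_exc_set_mv,
        "e_inh_set_mv": tmpl.e_inh_set_mv,
        "junction_potential_mv": tmpl.junction_potential_mv,
        "burst_bounds_s": tmpl.burst_bounds_s,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_template(csv_path: str | Path) -> ConductanceTemplate:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return ConductanceTemplate(
        g_exc=df["g_exc_nS"].to_numpy(),
        g_inh=df["g_inh_nS"].to_numpy(),
        dt_ms=float(meta["dt_ms"]),
        burst_bounds_s=[tuple(b) for b in meta["burst_bounds_s"]],
        e_exc_set_mv=float(meta["e_exc_set_mv"]),
        e_inh_set_mv=float(meta["e_inh_set_mv"]),
        junction_potential_mv=float(meta["junction_potential_mv"]),
    )
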