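"""In-silico downstream experiments on fitted calmodulin schemes.

Three protocols probe what a parameter set implies physiologically:

* equilibrium titration curves (mean Ca2+ per CaM vs clamped free Ca2+),
* integration of a 1-s spike train of Ca2+ impulses against a minimal
  single-exponential extrusion model, summarised as the area under the
  partially and fully bound calmodulin curves, and
* fractional site occupancy over a flash relaxation, which exposes where
  the quasi-steady-state reduction of singly bound lobe states is and is
  not valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import (
    EquilibriumPoint,
    ODESettings,
    Recording,
    apply_flash,
    pre_flash_equilibrium,
    uncaging_fraction_sigmoid,
)
from .schemes import (
    BufferParams,
    RateSet,
    SchemeSpec,
    equilibrium_cam_state,
    equilibrium_occupancy,
    get_system,
)


@dataclass(frozen=True)
class SpikeTrainProtocol:
    """A 1-s train of instantaneous Ca2+ injections with extrusion.

    Defaults follow hippocampal-spine physiology: 0.7 uM Ca2+ influx per
    synaptic stimulus, decay to a 100 nM baseline with tau = 12 ms, and
    20 uM total calmodulin."""

    frequency: float  # Hz
    duration: float = 1000.0  # ms
    amplitude_per_spike: float = 0.7e-6  # M
    tau_extrusion: float = 12.0  # ms
    baseline_ca: float = 100e-9  # M
    total_cam: float = 20e-6  # M

    def __post_init__(self):
        if min(self.frequency, self.duration, self.amplitude_per_spike + 1,
               self.tau_extrusion, self.baseline_ca, self.total_cam) <= 0:
            raise ValueError("protocol parameters must be positive")
        if self.amplitude_per_spike < 0:
            raise ValueError("amplitude must be >= 0")
        if self.frequency * self.duration < 1000.0:
            raise ValueError("protocol must contain at least one spike")

    def spike_times(self) -> np.ndarray:
        period = 1000.0 / self.frequency
        return np.arange(0.0, self.duration, period)


@dataclass(frozen=True)
class IntegrationResult:
    auc_partial: float  # M * ms
    auc_full: float  # M * ms
    frequency: float


def titration_curve(spec: SchemeSpec, rates: RateSet, ca_grid,
                    ) -> list[EquilibriumPoint]:
    """Equilibrium occupancy along an increasing free-Ca grid."""
    ca_grid = np.asarray(ca_grid, float)
    if np.any(ca_grid <= 0) or np.any(np.diff(ca_grid) <= 0):
        raise ValueError("ca_grid must be positive and increasing")
    return [EquilibriumPoint(float(c), equilibrium_occupancy(spec, rates, c))
            for c in ca_grid]


def partial_and_full(spec: SchemeSpec, traj: np.ndarray, sys) -> tuple[np.ndarray, np.ndarray]:
    """Concentrations of partially (1-3 ions) and fully (4 ions) bound
    calmodulin molecules along a trajectory.

    Whole-molecule schemes read species directly.  For independent-lobe
    schemes the molecule-level states follow from lobe independence: the
    fully bound fraction is the product of the two lobes' fully bound
    fractions, the unbound fraction the product of the unbound ones, and
    partial is the remainder."""
    if len(spec.components) == 1:
        partial = np.zeros(traj.shape[0])
        full = np.zeros(traj.shape[0])
        for s in spec.species:
            n = spec.n_bound[s]
            col = traj[:, sys.index[s]]
            if n == spec.max_bound():
                full += col
            elif n > 0:
                partial += col
        return partial, full
    fracs = []
    totals = []
    for comp in spec.components:
        tot = np.sum([traj[:, sys.index[s]] for s in comp], axis=0)
        n_max = max(spec.n_bound[s] for s in comp)
        f_full = sum(traj[:, sys.index[s]] for s in comp
                     if spec.n_bound[s] == n_max) / tot
        f_zero = sum(traj[:, sys.index[s]] for s in comp
                     if spec.n_bound[s] == 0) / tot
        fracs.append((f_zero, f_full))
        totals.append(tot)
    total_cam = totals[0]
    full = total_cam * fracs[0][1] * fracs[1][1]
    unbound = total_cam * fracs[0][0] * fracs[1][0]
    partial = total_cam - full - unbound
    return partial, full


def run_spike_train(spec: SchemeSpec, rates: RateSet,
                    protocol: SpikeTrainProtocol,
                    settings: ODESettings = ODESettings(),
                    grid_dt: float = 0.1,
                    baseline_subtract: bool = False,
                    ) -> tuple[IntegrationResult, dict]:
    """Integrate a spike train: start at the baseline-Ca equilibrium, add
    ``amplitude_per_spike`` to free Ca at each spike instant, relax with
    extrusion between spikes (no exogenous buffers present), and report
    trapezoid AUCs of partially and fully bound CaM over the duration.

    ``baseline_subtract`` removes the resting-equilibrium partial/full
    levels (times duration) from the AUCs, reporting stimulus-evoked area
    only; off by default."""
    buffers = BufferParams()  # buffer species present but at zero concentration
    sys = get_system(spec, rates, buffers)
    extr = (protocol.tau_extrusion, protocol.baseline_ca)

    state = {n: 0.0 for n in sys.names}
    state["Ca"] = protocol.baseline_ca
    state.update(equilibrium_cam_state(spec, rates, protocol.baseline_ca,
                                       protocol.total_cam))
    y = sys.state_from_dict(state)

    spikes = protocol.spike_times()
    edges = np.append(spikes, protocol.duration)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for k in range(len(spikes)):
        y[0] += protocol.amplitude_per_spike
        t0, t1 = edges[k], edges[k + 1]
        n_pts = max(int(round((t1 - t0) / grid_dt)), 2)
        t_local = np.linspace(0.0, t1 - t0, n_pts + 1)
        seg = sys.integrate(y, t_local, extrusion=extr, rtol=settings.rtol,
                            atol=settings.atol)
        ts.append(t0 + t_local[:-1] if k < len(spikes) - 1 else t0 + t_local)
        ys.append(seg[:-1] if k < len(spikes) - 1 else seg)
        y = seg[-1].copy()
    t_all = np.concatenate(ts)
    traj = np.vstack(ys)
    partial, full = partial_and_full(spec, traj, sys)
    auc_partial = float(np.trapezoid(partial, t_all))
    auc_full = float(np.trapezoid(full, t_all))
    if baseline_subtract:
        rest_p, rest_f = partial_and_full(
            spec, sys.state_from_dict(state)[None, :], sys)
        auc_partial -= float(rest_p[0]) * protocol.duration
        auc_full -= float(rest_f[0]) * protocol.duration
    result = IntegrationResult(
        auc_partial=auc_partial,
        auc_full=auc_full,
        frequency=protocol.frequency,
    )
    return result, {"t": t_all, "traj": traj, "partial": partial, "full": full,
                    "system": sys}


def frequency_sweep(spec: SchemeSpec, rates: RateSet, frequencies,
                    **protocol_kwargs) -> list[IntegrationResult]:
    out = []
    for f in frequencies:
        proto = SpikeTrainProtocol(frequency=float(f), **protocol_kwargs)
        res, _ = run_spike_train(spec, rates, proto)
        out.append(res)
    return out


def fractional_occupancy_run(rates: RateSet, composition, eta: float = 1.0,
                             buffers: BufferParams | None = None,
                             t_end: float = 35.0, n_times: int = 120,
                             settings: ODESettings = ODESettings()) -> dict:
    """Per-lobe fractional state occupancy of the distinct-sites scheme
    over a flash relaxation (the QSS-validity diagnostic).

    Returns times plus, per lobe, an array of state fractions (unbound,
    site-a, site-b, both) normalized to total calmodulin."""
    from .schemes import build_scheme

    spec = build_scheme("S6")
    if rates.scheme_id != "S6":
        raise ValueError("fractional occupancy requires a Scheme-6 rate set")
    buffers = buffers or BufferParams()
    sys = get_system(spec, rates, buffers)
    state0 = apply_flash(pre_flash_equilibrium(composition, spec, rates, buffers),
                         uncaging_fraction_sigmoid(eta))
    times = np.concatenate(([0.0], np.geomspace(1e-3, t_end, n_times - 1)))
    traj = sys.integrate(sys.state_from_dict(state0), times,
                         rtol=settings.rtol, atol=settings.atol)
    out = {"times": times}
    for comp in spec.components:
        tot = np.sum([traj[:, sys.index[s]] for s in comp], axis=0)
        lobe = comp[0][-1]  # 'C' or 'N'
        out[lobe] = {s: traj[:, sys.index[s]] / tot for s in comp}
    return out
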