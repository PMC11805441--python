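"""From solution composition + laser flash to observables.

A flash-photolysis recording is modelled in three stages:

1. the solution (CaM + DMn + OGB-5N + total Ca) is equilibrated,
2. a fraction U of DMn (free and Ca-bound alike) is instantaneously
   converted to its low-affinity photoproduct, releasing Ca2+,
3. the stiff mass-action system relaxes, observed through the indicator as
   a relative-fluorescence time series.

The second observable, mean Ca2+ ions bound per calmodulin at equilibrium,
comes directly from the clamped-Ca equilibrium of the scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .schemes import (
    BufferParams,
    RateSet,
    SchemeSpec,
    System,
    equilibrium_cam_state,
    equilibrium_occupancy,
    get_system,
)


@dataclass(frozen=True)
class SolutionComposition:
    """Total concentrations (M) of one experimental solution."""

    total_cam: float
    total_dmn: float
    total_ogb5n: float
    total_ca: float
    group_label: str = ""
    temperature_note: str = ""

    def __post_init__(self):
        for name in ("total_cam", "total_dmn", "total_ogb5n", "total_ca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Recording:
    """One flash experiment: composition covariates, time stamps and the
    observed relative-fluorescence values."""

    recording_id: str
    composition: SolutionComposition
    pcd: float
    times: np.ndarray
    observed: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.times.shape != self.observed.shape:
            raise ValueError("times and observed must be aligned")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must start at >= 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class EquilibriumPoint:
    free_ca: float
    ca_per_cam: float


@dataclass(frozen=True)
class ODESettings:
    """Stiff-solver settings (LSODA).  The absolute tolerance default of
    1e-13 M guards the nanomolar-scale species; it is the tightest setting
    that double precision supports robustly here."""

    rtol: float = 1e-8
    atol: float = 1e-13


# ---------------------------------------------------------------------------
# Uncaging models
# ---------------------------------------------------------------------------

def uncaging_fraction_linear(pcd: float, x: float) -> float:
    """Linear uncaged-fraction model, 0.0011 * PCD - 0.39 + x.

    Kept for comparison only: the output is not bounded to [0, 1], which is
    the defect that motivates the sigmoid model actually used in fitting.
    """
    return 0.0011 * pcd - 0.39 + x


def uncaging_fraction_sigmoid(x: float) -> float:
    """Logistic uncaged fraction U(x) = 1 / (1 + exp(-x)), in (0, 1)."""
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-x)),
                   np.exp(np.clip(x, -745, 0)) / (1.0 + np.exp(np.clip(x, -745, 0))))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Initial conditions and the flash
# ---------------------------------------------------------------------------

def pre_flash_equilibrium(composition: SolutionComposition, spec: SchemeSpec,
                          rates: RateSet, buffers: BufferParams) -> dict[str, float]:
    """Partition total Ca among free Ca, DMn, OGB-5N and the CaM states.

    Free Ca is the root of the scalar total-Ca balance (every buffer and the
    scheme's equilibrium occupancy are monotone in free Ca); species
    concentrations then follow in closed form, so the returned state is an
    exact fixed point of the mass-action system up to root-finder tolerance.
    No photoproduct exists before the flash.
    """
    kd_dmn = buffers.dmn_koff / buffers.dmn_kon
    kd_ogb = buffers.ogb5n_koff / buffers.ogb5n_kon

    def bound(free):
        b = composition.total_dmn * free / (free + kd_dmn)
        b += composition.total_ogb5n * free / (free + kd_ogb)
        if composition.total_cam > 0 and free > 0:
            b += composition.total_cam * equilibrium_occupancy(spec, rates, free)
        return b

    total = composition.total_ca
    if total <= 0:
        free = 0.0
    else:
        f = lambda c: c + bound(c) - total
        free = brentq(f, 0.0, total, xtol=1e-18, rtol=1e-14, maxiter=200)

    state = {
        "Ca": free,
        "DMn": composition.total_dmn * kd_dmn / (free + kd_dmn),
        "CaDMn": composition.total_dmn * free / (free + kd_dmn),
        "PP": 0.0,
        "CaPP": 0.0,
        "OGB5N": composition.total_ogb5n * kd_ogb / (free + kd_ogb),
        "CaOGB5N": composition.total_ogb5n * free / (free + kd_ogb),
    }
    if free > 0:
        state.update(equilibrium_cam_state(spec, rates, free, composition.total_cam))
    else:
        for comp in spec.components:
            for s in comp:
                state[s] = 0.0
            state[comp[0]] = composition.total_cam
    return state


def apply_flash(state: dict[str, float], u: float) -> dict[str, float]:
    """Instantaneously convert fraction ``u`` of DMn and CaDMn to the
    photoproduct species (PP / CaPP); total Ca is conserved."""
    if not 0.0 <= u <= 1.0:
        raise ValueError("uncaging fraction must lie in [0, 1]")
    out = dict(state)
    out["PP"] = state.get("PP", 0.0) + u * state["DMn"]
    out["CaPP"] = state.get("CaPP", 0.0) + u * state["CaDMn"]
    out["DMn"] = (1.0 - u) * state["DMn"]
    out["CaDMn"] = (1.0 - u) * state["CaDMn"]
    return out


# ---------------------------------------------------------------------------
# Simulation and observables
# ---------------------------------------------------------------------------

def simulate_recording(recording: Recording, spec: SchemeSpec, rates: RateSet,
                       buffers: BufferParams, eta: float,
                       settings: ODESettings = ODESettings(),
                       ) -> tuple[np.ndarray, System]:
    """Simulate one recording: flash at t=0 with U = sigmoid(eta), then
    stiff relaxation.  Returns (states at recording.times, system)."""
    if not np.isfinite(eta):
        raise ValueError("eta must be finite")
    sys = get_system(spec, rates, buffers)
    u = uncaging_fraction_sigmoid(eta)
    state0 = apply_flash(
        pre_flash_equilibrium(recording.composition, spec, rates, buffers), u)
    y0 = sys.state_from_dict(state0)
    try:
        traj = sys.integrate(y0, recording.times, rtol=settings.rtol,
                             atol=settings.atol)
    except RuntimeError as exc:
        raise RuntimeError(f"solver failure in recording "
                           f"{recording.recording_id!r}: {exc}") from exc
    return traj, sys


def delta_f_f0(ogb5n: np.ndarray, ca_ogb5n: np.ndarray, ogb5n_0: float,
               ca_ogb5n_0: float, fmax_over_fmin: float = 39.364) -> np.ndarray:
    """Relative fluorescence ([OGB5N] + R [CaOGB5N]) / (t=0 values).

    Evaluates to exactly 1 at t=0; despite the conventional name the
    quantity is a fluorescence *ratio*, not a background-subtracted change.
    """
    denom = ogb5n_0 + fmax_over_fmin * ca_ogb5n_0
    if denom == 0:
        raise ZeroDivisionError("no indicator present at t=0")
    return (np.asarray(ogb5n) + fmax_over_fmin * np.asarray(ca_ogb5n)) / denom


def predict_dff(recording: Recording, spec: SchemeSpec, rates: RateSet,
                buffers: BufferParams, eta: float,
                settings: ODESettings = ODESettings()) -> np.ndarray:
    """Model relative-fluorescence series at the recording's time stamps."""
    traj, sys = simulate_recording(recording, spec, rates, buffers, eta, settings)
    i_free, i_bound = sys.index["OGB5N"], sys.index["CaOGB5N"]
    u = uncaging_fraction_sigmoid(eta)
    state0 = apply_flash(
        pre_flash_equilibrium(recording.composition, spec, rates, buffers), u)
    return delta_f_f0(traj[:, i_free], traj[:, i_bound], state0["OGB5N"],
                      state0["CaOGB5N"], buffers.fmax_over_fmin)


def ca_per_cam(state: dict[str, float], spec: SchemeSpec) -> float:
    """Mean Ca2+ ions bound per calmodulin molecule in ``state`` (0..4)."""
    bound = sum(spec.n_bound[s] * state[s] for c in spec.components for s in c)
    totals = [sum(state[s] for s in comp) for comp in spec.components]
    total_cam = float(np.mean(totals))
    if total_cam <= 0:
        raise ValueError("total CaM must be positive")
    return float(bound / total_cam)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_COMPOSITION_COLS = ["recording_id", "group_label", "pcd", "total_cam_M",
                     "total_dmn_M", "total_ogb5n_M", "total_ca_M"]


def recordings_to_frames(recordings: list[Recording]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format (recording_id, time_ms, dff) plus a composition table."""
    rows = []
    comps = []
    for rec in recordings:
        for t, v in zip(rec.times, rec.observed):
            rows.append((rec.recording_id, t, v))
        c = rec.composition
        comps.append((rec.recording_id, c.group_label, rec.pcd, c.total_cam,
                      c.total_dmn, c.total_ogb5n, c.total_ca))
    traces = pd.DataFrame(rows, columns=["recording_id", "time_ms", "dff"])
    compositions = pd.DataFrame(comps, columns=_COMPOSITION_COLS)
    return traces, compositions


def recordings_from_frames(traces: pd.DataFrame, compositions: pd.DataFrame,
                           ) -> list[Recording]:
    out = []
    comp_by_id = compositions.set_index("recording_id")
    for rid, grp in traces.groupby("recording_id", sort=False):
        row = comp_by_id.loc[rid]
        comp = SolutionComposition(
            total_cam=float(row["total_cam_M"]),
            total_dmn=float(row["total_dmn_M"]),
            total_ogb5n=float(row["total_ogb5n_M"]),
            total_ca=float(row["total_ca_M"]),
            group_label=str(row["group_label"]),
        )
        grp = grp.sort_values("time_ms")
        out.append(Recording(str(rid), comp, float(row["pcd"]),
                             grp["time_ms"].to_numpy(), grp["dff"].to_numpy()))
    return out


def equilibrium_points_to_frame(points: list[EquilibriumPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.free_ca, p.ca_per_cam) for p in points],
        columns=["free_ca_M", "ca_per_cam"],
    )


def equilibrium_points_from_frame(df: pd.DataFrame) -> list[EquilibriumPoint]:
    return [EquilibriumPoint(float(r.free_ca_M), float(r.ca_per_cam))
            for r in df.itertuples()]


def load_config(path) -> tuple[BufferParams, ODESettings]:
    """Read buffer rate constants and solver tolerances from YAML/JSON."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    buffers = BufferParams(**cfg.get("buffers", {}))
    settings = ODESettings(**cfg.get("solver", {}))
    return buffers, settings


def save_config(path, buffers: BufferParams, settings: ODESettings) -> None:
    import dataclasses

    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({"buffers": dataclasses.asdict(buffers),
                        "solver": dataclasses.asdict(settings)}, fh)
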