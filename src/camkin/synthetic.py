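"""Synthetic flash-uncaging and equilibrium data with known ground truth.

The generator reproduces the statistical structure the NLME analysis
assumes: seven solution groups spanning a realistic composition range, a
sequence of flashes of increasing strength per group realised as ordered
draws of the per-recording random effect, stiff multi-buffer relaxation
after each flash, i.i.d. Gaussian observation noise on the fluorescence
ratio, and a 107-point equilibrium titration of 5 uM calmodulin with its
own (smaller) Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward_model import (
    EquilibriumPoint,
    ODESettings,
    Recording,
    SolutionComposition,
    predict_dff,
)
from .schemes import BufferParams, RateSet, SchemeSpec, build_scheme, equilibrium_occupancy, load_rate_set

#: Ground truth for Scheme 1 synthetic studies: a fast, strongly
#: co-operative, high-affinity parameter set chosen (within the U(2,9) /
#: U(-9,-4) prior supports) so that *both* two-ion binding steps relax
#: within the uncaging observation window and every parameter leaves a
#: kinetic fingerprint in the data.  The best published-style S1 fit rails
#: against the prior boundary with a second on-rate too slow to matter
#: dynamically, which would make recovery studies vacuous.
S1_SYNTHETIC_TRUTH = RateSet(
    scheme_id="S1",
    log10_forward={"k1": 8.0, "k3": 7.7},
    log10_kd={"KD1": -8.6, "KD2": -8.8},
    source_label="synthetic ground truth",
)

#: Solution-group composition grid (CaM, DMn, OGB-5N in M).  Total Ca loads
#: DMn at a fixed sub-saturating fraction so that even strong flashes leave
#: enough intact chelator to re-buffer the released Ca2+.
GROUP_TABLE = (
    ("A", 100e-6, 1.5e-3, 20e-6),
    ("B", 70e-6, 2.0e-3, 80e-6),
    ("C", 40e-6, 2.5e-3, 50e-6),
    ("D", 20e-6, 3.0e-3, 100e-6),
    ("E", 10e-6, 3.5e-3, 30e-6),
    ("F", 5e-6, 4.0e-3, 60e-6),
    ("G", 2e-6, 4.5e-3, 40e-6),
)

#: fraction of DMn pre-loaded with Ca2+.  High enough that strong flashes
#: exhaust part of the chelator capacity and leave a sustained elevated
#: free-Ca plateau (as in the real recordings, where strong-flash traces
#: equilibrate at high fluorescence), low enough that weak flashes are
#: fully re-buffered.
CA_LOAD_FRACTION = 0.25

#: default sampling grid: log-spaced to resolve the sub-ms free-Ca spike
#: and the tens-of-ms calmodulin-governed tail alike
DEFAULT_TIME_GRID = np.concatenate(([0.0], np.geomspace(0.02, 40.0, 47)))


def default_truth_rates(scheme_id: str) -> RateSet:
    if scheme_id == "S1":
        return S1_SYNTHETIC_TRUTH
    return load_rate_set(scheme_id, "our_fits")


@dataclass
class GroundTruth:
    """Everything needed to regenerate a dataset bit-for-bit."""

    scheme_id: str
    rates: RateSet
    mu: float = 0.0
    omega: float = 1.0
    sigma_dyn: float = 0.02
    sigma_eq: float = 0.1
    buffers: BufferParams = field(default_factory=BufferParams)
    seed: int = 0
    eta: dict[str, float] = field(default_factory=dict)

    @classmethod
    def default(cls, scheme_id: str, seed: int = 0, **overrides) -> "GroundTruth":
        return cls(scheme_id=scheme_id, rates=default_truth_rates(scheme_id),
                   seed=seed, **overrides)

    @property
    def spec(self) -> SchemeSpec:
        return build_scheme(self.scheme_id)


def generate_uncaging_dataset(truth: GroundTruth, n_groups: int = 7,
                              flashes_per_group: int = 4,
                              time_grid: np.ndarray | None = None,
                              settings: ODESettings = ODESettings(),
                              max_retries: int = 5,
                              ) -> tuple[list[Recording], GroundTruth]:
    """Simulate flash recordings for ``n_groups`` solution groups.

    Per group, ``flashes_per_group`` random effects are drawn from
    N(mu, omega^2) and sorted ascending so that later recordings in a group
    mimic stronger laser pulses; each is simulated through the forward
    model and observed with additive Gaussian noise sigma_dyn.  The eta
    used for every recording is recorded in the returned ground truth.
    """
    if n_groups < 1:
        raise ValueError("need at least one group")
    t = DEFAULT_TIME_GRID if time_grid is None else np.asarray(time_grid, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be increasing")
    # independent child streams so that the flash-strength draws are
    # identical whether or not observation noise is generated
    eta_rng = np.random.default_rng([truth.seed, 11])
    noise_rng = np.random.default_rng([truth.seed, 12])
    spec = truth.spec
    recordings: list[Recording] = []
    truth.eta = {}
    for g in range(n_groups):
        label, cam, dmn, ogb = GROUP_TABLE[g % len(GROUP_TABLE)]
        comp = SolutionComposition(
            total_cam=cam, total_dmn=dmn, total_ogb5n=ogb,
            total_ca=CA_LOAD_FRACTION * dmn, group_label=label,
            temperature_note="35C nominal",
        )
        etas = np.sort(eta_rng.normal(truth.mu, truth.omega,
                                      size=flashes_per_group))
        for j, eta in enumerate(etas):
            rid = f"{label}{g // len(GROUP_TABLE)}_{j}" if g >= len(GROUP_TABLE) \
                else f"{label}_{j}"
            rec = Recording(rid, comp, pcd=float(600 + 100 * j), times=t,
                            observed=np.zeros_like(t))
            pred = None
            for attempt in range(max_retries):
                try:
                    pred = predict_dff(rec, spec, truth.rates, truth.buffers,
                                       float(eta), settings)
                    break
                except RuntimeError:
                    eta = float(eta_rng.normal(truth.mu, truth.omega))
            if pred is None:
                raise RuntimeError(f"could not simulate recording {rid}")
            noise = noise_rng.normal(0.0, truth.sigma_dyn, size=pred.shape) \
                if truth.sigma_dyn > 0 else 0.0
            rec.observed = pred + noise
            truth.eta[rid] = float(eta)
            recordings.append(rec)
    return recordings, truth


def generate_equilibrium_dataset(truth: GroundTruth, n_points: int = 107,
                                 ca_range: tuple[float, float] = (1e-7, 5.5e-5),
                                 ) -> list[EquilibriumPoint]:
    """Log-spaced titration of mean Ca per CaM with noise sigma_eq,
    clipped to the physical range [0, 4]."""
    if n_points < 2:
        raise ValueError("need at least two titration points")
    rng = np.random.default_rng(truth.seed + 1)
    grid = np.geomspace(ca_range[0], ca_range[1], n_points)
    spec = truth.spec
    clean = np.array([
        equilibrium_occupancy(spec, truth.rates, c) for c in grid
    ])
    noisy = clean + (rng.normal(0.0, truth.sigma_eq, size=clean.shape)
                     if truth.sigma_eq > 0 else 0.0)
    noisy = np.clip(noisy, 0.0, 4.0)
    return [EquilibriumPoint(float(c), float(v)) for c, v in zip(grid, noisy)]
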