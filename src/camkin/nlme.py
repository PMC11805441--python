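"""Two-level nonlinear mixed-effects model for uncaging + equilibrium data.

Fixed effects are the scheme's rate constants (log10), the random-effect
prior parameters (mu, omega) and the observation-noise SDs; the single
random effect eta_n per recording maps through a sigmoid to that
recording's uncaged DMn fraction.  The fitting objective is the MAP
conditional log-likelihood

    log p(Theta) + sum_n [ log p(y_n | Theta, eta_n) + log p(eta_n | Theta) ]

maximized jointly over Theta and all eta_n; model comparison uses the
marginal likelihood with the eta integral replaced by its Laplace
approximation (scalar eta makes the curvature a cheap second derivative).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .forward_model import (
    EquilibriumPoint,
    ODESettings,
    Recording,
    apply_flash,
    delta_f_f0,
    pre_flash_equilibrium,
    uncaging_fraction_sigmoid,
)
from .schemes import BufferParams, RateSet, SchemeSpec, equilibrium_occupancy, get_system

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class FixedEffects:
    """Population-level parameters Theta = (theta, mu, omega, sigma)."""

    rates: RateSet
    mu: float = 0.0
    omega: float = 1.0
    sigma_dyn: float = 0.1
    sigma_eq: float = 0.1

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")


@dataclass
class RandomEffects:
    eta: dict[str, float]

    def __post_init__(self):
        if not all(np.isfinite(v) for v in self.eta.values()):
            raise ValueError("eta values must be finite")


@dataclass(frozen=True)
class Prior:
    """Prior for one log10 rate parameter: Uniform(lo, hi) or Normal(center, sd)."""

    kind: str  # "uniform" | "normal"
    a: float
    b: float

    def logpdf(self, x: float) -> float:
        if self.kind == "uniform":
            return -math.log(self.b - self.a) if self.a <= x <= self.b else -math.inf
        return -0.5 * ((x - self.a) / self.b) ** 2 - math.log(self.b) - 0.5 * _LOG_2PI

    def sample(self, rng: np.random.Generator) -> float:
        """Draw an initialization value; normal draws are truncated to
        +-2 sd (extreme corners make useless, often unintegrable starts)."""
        if self.kind == "uniform":
            return float(rng.uniform(self.a, self.b))
        return float(self.a + self.b * np.clip(rng.standard_normal(), -2, 2))


@dataclass
class PriorSpec:
    """Per-scheme priors on the log10 rate parameters plus the domain
    restrictions on mu ([-5, 5]) and omega (N(0,1) truncated to [1, inf),
    the minimal restriction preventing random-effect over-fitting under the
    MAP conditional objective)."""

    theta: dict[str, Prior]
    mu_bounds: tuple[float, float] = (-5.0, 5.0)
    omega_min: float = 1.0

    def log_omega_prior(self, omega: float) -> float:
        if omega < self.omega_min:
            return -math.inf
        z = 1.0 - norm.cdf(self.omega_min)  # truncation mass of N(0,1)
        return float(norm.logpdf(omega) - math.log(z))


def priors_to_yaml(priors: PriorSpec, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump({
            "theta": {k: {"kind": p.kind, "a": p.a, "b": p.b}
                      for k, p in priors.theta.items()},
            "mu_bounds": list(priors.mu_bounds),
            "omega_min": priors.omega_min,
        }, fh)


def priors_from_yaml(path) -> PriorSpec:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    return PriorSpec(
        theta={k: Prior(v["kind"], float(v["a"]), float(v["b"]))
               for k, v in d["theta"].items()},
        mu_bounds=tuple(d.get("mu_bounds", (-5.0, 5.0))),
        omega_min=float(d.get("omega_min", 1.0)),
    )


def default_priors(spec: SchemeSpec) -> PriorSpec:
    """The per-scheme priors used throughout the analysis.

    S1/S2: wide uniforms, U(2, 9) on log10 forward rates and U(-9, -4) on
    log10 K_D (in each reaction's own units).  S3: same forward-rate
    uniforms, with N(r, 1) on each K_D centered on the Shifman values.
    S4/S5: N(r, 1) centered on the Faas values for every parameter.
    S6: N(r, 1) centered on the Byrne values.
    """
    from .schemes import load_rate_set

    sid = spec.scheme_id
    theta: dict[str, Prior] = {}
    if sid in ("S1", "S2"):
        for s in spec.forward_slots:
            theta[s] = Prior("uniform", 2.0, 9.0)
        for k in spec.kd_names:
            theta[k] = Prior("uniform", -9.0, -4.0)
    elif sid == "S3":
        centers = load_rate_set("S3", "shifman")
        for s in spec.forward_slots:
            theta[s] = Prior("uniform", 2.0, 9.0)
        for k in spec.kd_names:
            theta[k] = Prior("normal", centers.log10_kd[k], 1.0)
    elif sid in ("S4", "S5"):
        centers = load_rate_set("S5", "faas")
        for s in ("k1", "k3", "k5", "k7"):
            theta[s] = Prior("normal", centers.log10_forward[s], 1.0)
        for k in ("KD1", "KD2", "KD3", "KD4"):
            theta[k] = Prior("normal", centers.log10_kd[k], 1.0)
    elif sid == "S6":
        centers = load_rate_set("S6", "byrne")
        for s, v in centers.log10_forward.items():
            theta[s] = Prior("normal", v, 1.0)
        for k, v in centers.log10_kd.items():
            theta[k] = Prior("normal", v, 1.0)
    else:  # pragma: no cover
        raise ValueError(sid)
    return PriorSpec(theta=theta)


def theta_param_names(spec: SchemeSpec) -> tuple[str, ...]:
    """Canonical ordering of the scheme's free log10 parameters."""
    return spec.forward_slots + spec.kd_names


def theta_vector(fixed: FixedEffects, spec: SchemeSpec) -> np.ndarray:
    vals = []
    for name in theta_param_names(spec):
        if name in fixed.rates.log10_forward:
            vals.append(fixed.rates.log10_forward[name])
        else:
            vals.append(fixed.rates.log10_kd[name])
    return np.array(vals)


def rates_from_vector(spec: SchemeSpec, vec: np.ndarray, template: RateSet) -> RateSet:
    fwd = dict(template.log10_forward)
    kd = dict(template.log10_kd)
    for name, v in zip(theta_param_names(spec), vec):
        if name in fwd:
            fwd[name] = float(v)
        else:
            kd[name] = float(v)
    return replace_rates(template, fwd, kd)


def replace_rates(template: RateSet, fwd: dict, kd: dict) -> RateSet:
    return RateSet(
        scheme_id=template.scheme_id,
        log10_forward=fwd,
        log10_kd=kd,
        source_label=template.source_label,
        double_forward=template.double_forward,
        double_reverse=template.double_reverse,
    )


# ---------------------------------------------------------------------------
# Parameter model (Eq-3-style bundling)
# ---------------------------------------------------------------------------

def parameter_model(fixed: FixedEffects, composition, eta: float,
                    buffers: BufferParams, spec: SchemeSpec) -> dict:
    """Bundle the dynamical parameters of one recording.

    Reaction rates carry no per-recording individualization; the sole use
    of the random effect is the uncaged fraction U = sigmoid(eta)."""
    return {
        "linear_rate_pairs": fixed.rates.linear_pairs(
            spec if not spec.qss_reduced else _s5_for(spec)),
        "buffers": buffers,
        "composition": composition,
        "uncaging_fraction": uncaging_fraction_sigmoid(eta),
    }


def _s5_for(spec):
    from .schemes import build_scheme

    return build_scheme("S5")


# ---------------------------------------------------------------------------
# Likelihood components
# ---------------------------------------------------------------------------

def gaussian_loglik(residuals: np.ndarray, sigma: float) -> float:
    m = residuals.size
    if m == 0:
        return 0.0
    return float(-0.5 * np.sum((residuals / sigma) ** 2)
                 - m * math.log(sigma) - 0.5 * m * _LOG_2PI)


def log_prior(fixed: FixedEffects, priors: PriorSpec, spec: SchemeSpec) -> float:
    lp = 0.0
    for name, v in zip(theta_param_names(spec), theta_vector(fixed, spec)):
        lp += priors.theta[name].logpdf(v)
        if lp == -math.inf:
            return -math.inf
    lo, hi = priors.mu_bounds
    if not lo <= fixed.mu <= hi:
        return -math.inf
    lp += priors.log_omega_prior(fixed.omega)
    return lp


class NLMEProblem:
    """One scheme + data set, with the bookkeeping needed to evaluate the
    conditional likelihood fast.

    Pre-flash equilibria depend only on the rate parameters and on the
    (few, shared) solution compositions, so they are computed once per
    theta; per-recording work is then one flash + one stiff integration.
    """

    def __init__(self, spec: SchemeSpec, buffers: BufferParams,
                 recordings: list[Recording],
                 eq_points: list[EquilibriumPoint],
                 settings: ODESettings = ODESettings()):
        self.spec = spec
        self.buffers = buffers
        self.recordings = list(recordings)
        self.eq_points = list(eq_points)
        self.settings = settings
        self.recording_ids = [r.recording_id for r in self.recordings]
        # group recordings by identical composition
        self._comp_key = [self._key(r.composition) for r in self.recordings]
        self._unique_comps = {}
        for r, k in zip(self.recordings, self._comp_key):
            self._unique_comps.setdefault(k, r.composition)
        self._eq_ca = np.array([p.free_ca for p in eq_points])
        self._eq_y = np.array([p.ca_per_cam for p in eq_points])

    @staticmethod
    def _key(c):
        return (c.total_cam, c.total_dmn, c.total_ogb5n, c.total_ca)

    # -- model predictions ------------------------------------------------
    def preflash_states(self, rates: RateSet) -> dict:
        return {
            k: pre_flash_equilibrium(c, self.spec, rates, self.buffers)
            for k, c in self._unique_comps.items()
        }

    def predict_recording(self, rates: RateSet, eta: float, i: int,
                          preflash: dict) -> np.ndarray:
        rec = self.recordings[i]
        sys = get_system(self.spec, rates, self.buffers)
        state0 = apply_flash(preflash[self._comp_key[i]],
                             uncaging_fraction_sigmoid(eta))
        y0 = sys.state_from_dict(state0)
        traj = sys.integrate(y0, rec.times, rtol=self.settings.rtol,
                             atol=self.settings.atol)
        return delta_f_f0(traj[:, sys.index["OGB5N"]],
                          traj[:, sys.index["CaOGB5N"]],
                          state0["OGB5N"], state0["CaOGB5N"],
                          self.buffers.fmax_over_fmin)

    def dyn_residuals(self, rates: RateSet, etas: np.ndarray,
                      preflash: dict | None = None,
                      ) -> list[np.ndarray | None]:
        """Per-recording observed-minus-model residuals; None marks a solver
        failure (that recording's likelihood contribution becomes -inf)."""
        if preflash is None:
            preflash = self.preflash_states(rates)
        out = []
        for i, rec in enumerate(self.recordings):
            try:
                pred = self.predict_recording(rates, etas[i], i, preflash)
                out.append(rec.observed - pred)
            except RuntimeError as exc:
                logger.warning("solver failure: %s", exc)
                out.append(None)
        return out

    def eq_residuals(self, rates: RateSet) -> np.ndarray:
        if self._eq_ca.size == 0:
            return np.empty(0)
        pred = np.array([
            equilibrium_occupancy(self.spec, rates, c) for c in self._eq_ca
        ])
        return self._eq_y - pred

    # -- likelihoods -------------------------------------------------------
    def conditional_loglik(self, fixed: FixedEffects, etas: np.ndarray,
                           dyn_res=None, eq_res=None) -> float:
        if dyn_res is None:
            dyn_res = self.dyn_residuals(fixed.rates, etas)
        if eq_res is None:
            eq_res = self.eq_residuals(fixed.rates)
        ll = 0.0
        for res in dyn_res:
            if res is None:
                return -math.inf
            ll += gaussian_loglik(res, fixed.sigma_dyn)
        ll += gaussian_loglik(eq_res, fixed.sigma_eq)
        return ll

    def eta_prior_loglik(self, fixed: FixedEffects, etas: np.ndarray) -> float:
        z = (etas - fixed.mu) / fixed.omega
        return float(-0.5 * np.sum(z ** 2) - etas.size * math.log(fixed.omega)
                     - 0.5 * etas.size * _LOG_2PI)

    def map_objective(self, fixed: FixedEffects, etas: np.ndarray,
                      priors: PriorSpec) -> float:
        lp = log_prior(fixed, priors, self.spec)
        if lp == -math.inf:
            return -math.inf
        return lp + self.conditional_loglik(fixed, etas) \
            + self.eta_prior_loglik(fixed, etas)

    # -- Laplace marginal --------------------------------------------------
    def laplace_marginal_loglik(self, fixed: FixedEffects) -> float:
        """Marginal log-likelihood with the per-recording eta integral
        approximated by Laplace; equilibrium data (no random effects) enter
        unchanged."""
        preflash = self.preflash_states(fixed.rates)
        total = 0.0
        for i, rec in enumerate(self.recordings):
            def joint(eta, i=i):
                try:
                    pred = self.predict_recording(fixed.rates, eta, i, preflash)
                except RuntimeError:
                    return -math.inf
                return (gaussian_loglik(rec.observed - pred, fixed.sigma_dyn)
                        + norm.logpdf(eta, fixed.mu, fixed.omega))

            total += laplace_marginal_1d(joint, fixed.mu, fixed.omega,
                                         label=rec.recording_id,
                                         on_flat="prior")
        total += gaussian_loglik(self.eq_residuals(fixed.rates), fixed.sigma_eq)
        return total


def laplace_marginal_1d(log_joint, mu: float, omega: float, h: float = 1e-3,
                        label: str = "", on_flat: str = "raise") -> float:
    """Laplace approximation of log integral exp(log_joint(eta)) d eta for a
    scalar latent: maximize, then add 0.5 log(2 pi / H) with H the negative
    second derivative at the optimum.  Exact for quadratic log densities.

    A non-positive measured curvature (an optimum pinned at the search
    boundary by a badly misspecified model) raises by default;
    ``on_flat='prior'`` substitutes the eta-prior curvature 1/omega^2
    instead — the flat-likelihood limit, used during model comparison so a
    hopeless model gets a (poor) likelihood rather than an exception."""
    res = minimize_scalar(lambda e: -log_joint(e),
                          bounds=(mu - 8 * omega, mu + 8 * omega),
                          method="bounded",
                          options={"xatol": 1e-8})
    eta_star = float(res.x)
    g0 = log_joint(eta_star)
    h2 = (log_joint(eta_star + h) - 2.0 * g0 + log_joint(eta_star - h)) / h ** 2
    curvature = -h2
    if not np.isfinite(curvature) or curvature <= 1e-9:
        if on_flat == "prior":
            logger.warning("flat joint at eta* for recording %r; using the "
                           "prior curvature", label)
            curvature = 1.0 / omega ** 2
        else:
            raise RuntimeError(
                f"non-positive curvature at eta* for recording {label!r}")
    return float(g0 + 0.5 * _LOG_2PI - 0.5 * math.log(curvature))


# -- module-level wrappers matching the operation contracts -----------------

def conditional_loglik(fixed: FixedEffects, etas: RandomEffects | dict,
                       recordings: list[Recording],
                       eq_points: list[EquilibriumPoint],
                       spec: SchemeSpec, buffers: BufferParams,
                       settings: ODESettings = ODESettings()) -> float:
    prob = NLMEProblem(spec, buffers, recordings, eq_points, settings)
    eta_map = etas.eta if isinstance(etas, RandomEffects) else etas
    vec = np.array([eta_map[r.recording_id] for r in recordings])
    return prob.conditional_loglik(fixed, vec)


def map_objective(fixed: FixedEffects, etas: RandomEffects | dict,
                  recordings: list[Recording],
                  eq_points: list[EquilibriumPoint],
                  spec: SchemeSpec, buffers: BufferParams,
                  priors: PriorSpec,
                  settings: ODESettings = ODESettings()) -> float:
    prob = NLMEProblem(spec, buffers, recordings, eq_points, settings)
    eta_map = etas.eta if isinstance(etas, RandomEffects) else etas
    vec = np.array([eta_map[r.recording_id] for r in recordings])
    lp = log_prior(fixed, priors, spec)
    if lp == -math.inf:
        return -math.inf
    # the eta prior runs over every random effect supplied, including ones
    # whose recordings are absent (no-data limit)
    all_eta = np.array(list(eta_map.values()))
    z = (all_eta - fixed.mu) / fixed.omega
    eta_term = float(-0.5 * np.sum(z ** 2)
                     - all_eta.size * math.log(fixed.omega)
                     - 0.5 * all_eta.size * _LOG_2PI)
    return lp + prob.conditional_loglik(fixed, vec) + eta_term


def laplace_marginal_loglik(fixed: FixedEffects, recordings: list[Recording],
                            eq_points: list[EquilibriumPoint],
                            spec: SchemeSpec, buffers: BufferParams,
                            settings: ODESettings = ODESettings()) -> float:
    prob = NLMEProblem(spec, buffers, recordings, eq_points, settings)
    return prob.laplace_marginal_loglik(fixed)
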