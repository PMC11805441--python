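"""Data splitting, MAP optimization and multistart bookkeeping.

The MAP conditional objective is maximized jointly over the fixed effects
and all per-recording random effects with bounded quasi-Newton (L-BFGS-B).
Gradients use the hierarchical structure of the model: perturbing one
eta_n requires re-solving only recording n; the noise SDs, mu and omega
have closed-form partial derivatives given the residuals; only the rate
parameters need full finite-difference passes over the data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .forward_model import EquilibriumPoint, ODESettings, Recording
from .nlme import (
    FixedEffects,
    NLMEProblem,
    Prior,
    PriorSpec,
    RandomEffects,
    gaussian_loglik,
    rates_from_vector,
    theta_param_names,
    theta_vector,
)
from .schemes import BufferParams, RateSet, SchemeSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splitting and preprocessing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    seed: int
    fractions: tuple[float, float, float]
    assignment: dict[str, str]  # recording_id -> train|val|test

    def ids(self, which: str) -> list[str]:
        return [k for k, v in self.assignment.items() if v == which]

    def select(self, recordings: list[Recording], which: str) -> list[Recording]:
        return [r for r in recordings if self.assignment[r.recording_id] == which]


def split_data(recordings: list[Recording], seed: int,
               fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
               ) -> SplitPlan:
    """Deterministic stratified train/val/test split.

    Stratified by solution group so that every group contributes at least
    one training recording; reproducible from the seed alone."""
    if len(recordings) < 3:
        raise ValueError("need at least 3 recordings to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[str]] = {}
    for r in recordings:
        groups.setdefault(r.composition.group_label, []).append(r.recording_id)
    assignment: dict[str, str] = {}
    for label in sorted(groups):
        ids = sorted(groups[label])
        perm = rng.permutation(len(ids))
        n = len(ids)
        n_train = max(1, int(round(fractions[0] * n))) if fractions[0] > 0 else 0
        n_val = int(round(fractions[1] * n))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        for pos, idx in enumerate(perm):
            which = ("train" if pos < n_train
                     else "val" if pos < n_train + n_val else "test")
            assignment[ids[idx]] = which
    return SplitPlan(seed=seed, fractions=tuple(fractions), assignment=assignment)


def downsample_early(recording: Recording, keep_every: int = 2,
                     cutoff_ms: float = 1.0) -> Recording:
    """Thin densely sampled early points: keep every ``keep_every``-th
    sample before ``cutoff_ms`` (plus t=0), everything after unchanged.
    Applied identically to synthetic and real data before fitting."""
    t = recording.times
    early = np.flatnonzero(t < cutoff_ms)
    keep = np.ones(t.size, dtype=bool)
    keep[early] = False
    keep[early[::keep_every]] = True
    keep[0] = True
    return Recording(recording.recording_id, recording.composition,
                     recording.pcd, t[keep], recording.observed[keep])


def preprocess_recordings(recordings: list[Recording], keep_every: int = 2,
                          cutoff_ms: float = 1.0) -> list[Recording]:
    return [downsample_early(r, keep_every, cutoff_ms) for r in recordings]


# ---------------------------------------------------------------------------
# MAP fitting
# ---------------------------------------------------------------------------

@dataclass
class NLMEFit:
    theta_star: FixedEffects
    eta_star: RandomEffects
    objective_trace: list[float]
    converged: bool
    seed: int
    n_function_evals: int
    message: str = ""
    validation_rmse: float = math.nan


_BAD = -1e12


class _MAPObjective:
    """Joint MAP objective with structured gradients.

    Layout of the packed vector: [theta_free..., log sigma_dyn,
    log sigma_eq, mu, omega, eta...].
    """

    FD_STEP = 3e-5

    def __init__(self, problem: NLMEProblem, priors: PriorSpec,
                 template: RateSet, fixed_params: dict[str, float] | None = None):
        self.problem = problem
        self.priors = priors
        self.template = template
        self.fixed_params = dict(fixed_params or {})
        all_names = theta_param_names(problem.spec)
        self.free_names = [n for n in all_names if n not in self.fixed_params]
        self.n_theta = len(self.free_names)
        self.n_eta = len(problem.recordings)
        self.n_evals = 0

    # -- packing ----------------------------------------------------------
    def pack_vector(self, fixed: FixedEffects, etas: np.ndarray) -> np.ndarray:
        tv = dict(zip(theta_param_names(self.problem.spec),
                      theta_vector(fixed, self.problem.spec)))
        head = [tv[n] for n in self.free_names]
        return np.concatenate([
            np.array(head + [math.log(fixed.sigma_dyn), math.log(fixed.sigma_eq),
                             fixed.mu, fixed.omega]),
            etas,
        ])

    def unpack(self, x: np.ndarray) -> tuple[FixedEffects, np.ndarray]:
        nt = self.n_theta
        full = dict(self.fixed_params)
        full.update(dict(zip(self.free_names, x[:nt])))
        vec = np.array([full[n] for n in theta_param_names(self.problem.spec)])
        rates = rates_from_vector(self.problem.spec, vec, self.template)
        fixed = FixedEffects(rates=rates,
                             sigma_dyn=math.exp(x[nt]),
                             sigma_eq=math.exp(x[nt + 1]),
                             mu=x[nt + 2], omega=x[nt + 3])
        return fixed, x[nt + 4:]

    def bounds(self) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = []
        for n in self.free_names:
            p = self.priors.theta[n]
            if p.kind == "uniform":
                b.append((p.a, p.b))
            else:
                b.append((p.a - 5 * p.b, p.b * 5 + p.a))
        b.append((math.log(1e-4), math.log(1e2)))   # log sigma_dyn
        b.append((math.log(1e-4), math.log(1e2)))   # log sigma_eq
        b.append(self.priors.mu_bounds)              # mu
        b.append((self.priors.omega_min, 50.0))      # omega
        b.extend([(-10.0, 10.0)] * self.n_eta)       # eta
        return b

    # -- pieces ------------------------------------------------------------
    def _data_loglik(self, rates: RateSet, etas: np.ndarray, sigma_dyn, sigma_eq,
                     preflash=None):
        dyn = self.problem.dyn_residuals(rates, etas, preflash)
        if any(r is None for r in dyn):
            return None, None, None
        eq = self.problem.eq_residuals(rates)
        ll = sum(gaussian_loglik(r, sigma_dyn) for r in dyn)
        ll += gaussian_loglik(eq, sigma_eq)
        return ll, dyn, eq

    def _theta_prior(self, x_theta: np.ndarray) -> tuple[float, np.ndarray]:
        lp, grad = 0.0, np.zeros_like(x_theta)
        for i, n in enumerate(self.free_names):
            p = self.priors.theta[n]
            lp += p.logpdf(x_theta[i])
            if p.kind == "normal":
                grad[i] = -(x_theta[i] - p.a) / p.b ** 2
        return lp, grad

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        self.n_evals += 1
        fixed, etas = self.unpack(x)
        nt = self.n_theta
        grad = np.zeros_like(x)

        preflash = self.problem.preflash_states(fixed.rates)
        ll, dyn, eq = self._data_loglik(fixed.rates, etas, fixed.sigma_dyn,
                                        fixed.sigma_eq, preflash)
        if ll is None:
            return _BAD, grad

        lp_theta, g_theta_prior = self._theta_prior(x[:nt])
        omega_lp = self.priors.log_omega_prior(fixed.omega)
        z = (etas - fixed.mu) / fixed.omega
        eta_lp = (-0.5 * np.sum(z ** 2) - self.n_eta * math.log(fixed.omega)
                  - 0.5 * self.n_eta * math.log(2 * math.pi))
        value = ll + lp_theta + omega_lp + eta_lp

        # --- gradient ---
        h = self.FD_STEP
        # rate parameters: forward differences, full data pass each
        for i in range(nt):
            xp = x.copy()
            xp[i] += h
            fp, _ = self.unpack(xp)
            llp, _, _ = self._data_loglik(fp.rates, etas, fixed.sigma_dyn,
                                          fixed.sigma_eq)
            if llp is None:
                grad[i] = 0.0
            else:
                grad[i] = (llp - ll) / h
        grad[:nt] += g_theta_prior
        # noise SDs: closed form in log-sigma
        ss_dyn = sum(float(np.sum(r ** 2)) for r in dyn)
        m_dyn = sum(r.size for r in dyn)
        grad[nt] = ss_dyn / fixed.sigma_dyn ** 2 - m_dyn
        ss_eq = float(np.sum(eq ** 2))
        grad[nt + 1] = ss_eq / fixed.sigma_eq ** 2 - eq.size
        # mu, omega: closed form (incl. omega prior d/dw log phi(w) = -w)
        grad[nt + 2] = np.sum(etas - fixed.mu) / fixed.omega ** 2
        grad[nt + 3] = (-self.n_eta / fixed.omega
                        + np.sum((etas - fixed.mu) ** 2) / fixed.omega ** 3
                        - fixed.omega)
        # etas: forward difference, one recording each
        for i in range(self.n_eta):
            rec = self.problem.recordings[i]
            base = dyn[i]
            try:
                pred = self.problem.predict_recording(fixed.rates, etas[i] + h,
                                                      i, preflash)
                res = rec.observed - pred
                d_ll = (gaussian_loglik(res, fixed.sigma_dyn)
                        - gaussian_loglik(base, fixed.sigma_dyn)) / h
            except RuntimeError:
                d_ll = 0.0
            grad[nt + 4 + i] = d_ll - (etas[i] - fixed.mu) / fixed.omega ** 2
        return value, grad


def equilibrium_prefit(problem: NLMEProblem, priors: PriorSpec,
                       init: FixedEffects,
                       fixed_params: dict[str, float] | None = None,
                       maxiter: int = 300) -> FixedEffects:
    """Cheap initialization stage: fit the dissociation constants to the
    equilibrium titration alone (closed-form occupancy, no ODE solves),
    profiling out the equilibrium noise SD.  The on-rates are untouched --
    equilibrium data only constrains K_D ratios."""
    from .nlme import rates_from_vector, theta_param_names

    spec = problem.spec
    fixed_params = dict(fixed_params or {})
    kd_names = [n for n in spec.kd_names if n not in fixed_params]
    if not kd_names or not problem.eq_points:
        return init
    names = theta_param_names(spec)
    base = dict(zip(names, theta_vector(init, spec)))
    base.update(fixed_params)

    def unpack(x):
        full = dict(base)
        full.update(dict(zip(kd_names, x)))
        vec = np.array([full[n] for n in names])
        return rates_from_vector(spec, vec, init.rates)

    def neg(x):
        rates = unpack(x)
        res = problem.eq_residuals(rates)
        sigma = max(math.sqrt(float(np.mean(res ** 2))), 1e-3)
        ll = gaussian_loglik(res, sigma)
        lp = sum(priors.theta[n].logpdf(v) for n, v in zip(kd_names, x))
        return -(ll + lp)

    x0 = np.array([base[n] for n in kd_names])
    bounds = []
    for n in kd_names:
        p = priors.theta[n]
        bounds.append((p.a, p.b) if p.kind == "uniform"
                      else (p.a - 5 * p.b, p.a + 5 * p.b))
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter})
    rates = unpack(res.x)
    eq_res = problem.eq_residuals(rates)
    sigma_eq = float(np.clip(math.sqrt(float(np.mean(eq_res ** 2))), 2e-2, 1.0))
    return FixedEffects(rates=rates, mu=init.mu, omega=init.omega,
                        sigma_dyn=init.sigma_dyn, sigma_eq=sigma_eq)


def fit(problem: NLMEProblem, priors: PriorSpec, init: FixedEffects,
        seed: int = 0, init_etas: np.ndarray | None = None,
        fixed_params: dict[str, float] | None = None,
        maxiter: int = 150, gtol: float = 1e-6,
        warmup_iters: int = 40, prefit_equilibrium: bool = True) -> NLMEFit:
    """Maximize the MAP conditional objective from one starting point.

    Optimization runs in two phases: a warm-up with the noise SDs frozen
    at their initial values (which prevents the optimizer from inflating a
    noise term instead of fitting the corresponding observable), then a
    full joint polish over all parameters.  Returns a local maximizer of
    the joint (Theta, eta) objective; the convergence flag reflects the
    optimizer's own stopping status."""
    if prefit_equilibrium:
        init = equilibrium_prefit(problem, priors, init, fixed_params)
    obj = _MAPObjective(problem, priors, init.rates, fixed_params)
    if init_etas is None:
        # per-recording scalar MAP of eta given the initial rates, so the
        # joint optimizer starts with consistent flash strengths
        try:
            eta_map = estimate_etas(problem.spec, problem.buffers,
                                    problem.recordings, init,
                                    settings=problem.settings)
            etas0 = np.array([eta_map[r] for r in problem.recording_ids])
        except Exception:  # noqa: BLE001 - fall back to the prior mean
            etas0 = np.full(obj.n_eta, init.mu)
    else:
        etas0 = np.asarray(init_etas, float)
    x0 = obj.pack_vector(init, etas0)
    bounds = obj.bounds()
    x0 = np.clip(x0, [lo if lo is not None else -np.inf for lo, _ in bounds],
                 [hi if hi is not None else np.inf for _, hi in bounds])
    trace: list[float] = []
    last: dict = {"v": math.nan}

    def neg_tracked(x):
        v, g = obj.value_and_grad(x)
        last["v"] = v
        return -v, -g

    def cb(xk):
        trace.append(last["v"])

    opts = {"gtol": gtol, "ftol": 1e-8, "maxls": 20}
    if warmup_iters > 0:
        nt = obj.n_theta
        frozen = list(bounds)
        frozen[nt] = (x0[nt], x0[nt])
        frozen[nt + 1] = (x0[nt + 1], x0[nt + 1])
        warm = minimize(neg_tracked, x0, jac=True, method="L-BFGS-B",
                        bounds=frozen, callback=cb,
                        options={**opts, "maxiter": warmup_iters})
        x0 = warm.x
    res = minimize(neg_tracked, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                   callback=cb, options={**opts, "maxiter": maxiter})
    fixed, etas = obj.unpack(res.x)
    eta_map = dict(zip(problem.recording_ids, etas))
    # keep only accepted (monotone) prefix of the trace; always end with
    # the final objective so even a 0-iteration run reports its value
    trace.append(-float(res.fun))
    mono = []
    best = -math.inf
    for v in trace:
        if not math.isnan(v) and v >= best - 1e-9:
            best = max(best, v)
            mono.append(best)
    if not mono:
        mono = [-float(res.fun)]
    return NLMEFit(theta_star=fixed, eta_star=RandomEffects(eta_map),
                   objective_trace=mono, converged=bool(res.success),
                   seed=seed, n_function_evals=obj.n_evals,
                   message=str(res.message))


def estimate_etas(spec: SchemeSpec, buffers: BufferParams,
                  recordings: list[Recording], fixed: FixedEffects,
                  settings: ODESettings = ODESettings()) -> dict[str, float]:
    """MAP estimate of eta for recordings not seen in training (needed to
    evaluate held-out predictive error)."""
    prob = NLMEProblem(spec, buffers, recordings, [], settings)
    preflash = prob.preflash_states(fixed.rates)
    out = {}
    for i, rec in enumerate(recordings):
        def neg(eta, i=i):
            try:
                pred = prob.predict_recording(fixed.rates, float(eta), i, preflash)
            except RuntimeError:
                return 1e12
            return -(gaussian_loglik(rec.observed - pred, fixed.sigma_dyn)
                     - 0.5 * ((eta - fixed.mu) / fixed.omega) ** 2)

        res = minimize_scalar(neg, bounds=(fixed.mu - 8 * fixed.omega,
                                           fixed.mu + 8 * fixed.omega),
                              method="bounded", options={"xatol": 1e-6})
        out[rec.recording_id] = float(res.x)
    return out


def prediction_rmse(spec: SchemeSpec, buffers: BufferParams,
                    recordings: list[Recording], fixed: FixedEffects,
                    etas: dict[str, float] | None = None,
                    settings: ODESettings = ODESettings()) -> float:
    """Mean per-recording RMSE of the fluorescence observable."""
    from .compare import rmse

    if etas is None:
        etas = estimate_etas(spec, buffers, recordings, fixed, settings)
    prob = NLMEProblem(spec, buffers, recordings, [], settings)
    preflash = prob.preflash_states(fixed.rates)
    vals = []
    for i, rec in enumerate(recordings):
        try:
            pred = prob.predict_recording(fixed.rates, etas[rec.recording_id],
                                          i, preflash)
            vals.append(rmse(rec.observed, pred))
        except RuntimeError:
            vals.append(math.inf)
    return float(np.mean(vals))


def stratified_inits(priors: PriorSpec, template: RateSet, spec: SchemeSpec,
                     n_starts: int, rng: np.random.Generator,
                     ) -> list[FixedEffects]:
    """Stratified initial conditions for the widely nonconvex directions.

    Uniform-prior *forward rates* share one stratum index per start (the
    starts sweep the slow ... fast axis together), because the on-rates set
    a common kinetic timescale and wrong-timescale local optima trap
    independent draws; uniform-prior K_Ds and normal-prior parameters are
    sampled from their priors (the K_Ds are re-placed by the equilibrium
    pre-fit anyway)."""
    from .nlme import theta_param_names

    names = theta_param_names(spec)
    speed_strata = rng.permutation(n_starts)
    inits = []
    for s in range(n_starts):
        fwd = dict(template.log10_forward)
        kd = dict(template.log10_kd)
        for name in names:
            p = priors.theta[name]
            if p.kind == "uniform" and name in fwd:
                width = (p.b - p.a) / n_starts
                v = p.a + (speed_strata[s] + rng.uniform()) * width
            else:
                v = p.sample(rng)
            (fwd if name in fwd else kd)[name] = float(v)
        rates = RateSet(spec.scheme_id, fwd, kd, source_label="init",
                        double_forward=template.double_forward,
                        double_reverse=template.double_reverse)
        inits.append(FixedEffects(rates=rates, mu=0.0, omega=1.2,
                                  sigma_dyn=0.2, sigma_eq=0.2))
    return inits


def multistart_fit(problem: NLMEProblem, priors: PriorSpec,
                   template: RateSet, n_starts: int = 20, seed: int = 0,
                   val_recordings: list[Recording] | None = None,
                   fixed_params: dict[str, float] | None = None,
                   maxiter: int = 150, warmup_iters: int = 40) -> list[NLMEFit]:
    """Run ``n_starts`` MAP fits from stratified prior-drawn initial
    conditions and return them sorted by validation RMSE (training
    objective as the tie-break when no validation set is supplied)."""
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    inits = stratified_inits(priors, template, problem.spec, n_starts, rng)
    fits: list[NLMEFit] = []
    failures: list[str] = []
    for s in range(n_starts):
        init = inits[s]
        try:
            f = fit(problem, priors, init, seed=seed + s,
                    fixed_params=fixed_params, maxiter=maxiter,
                    warmup_iters=warmup_iters)
        except Exception as exc:  # noqa: BLE001 - reported collectively below
            failures.append(f"start {s}: {exc}")
            continue
        if val_recordings:
            f.validation_rmse = prediction_rmse(
                problem.spec, problem.buffers, val_recordings, f.theta_star,
                settings=problem.settings)
        else:
            f.validation_rmse = (-f.objective_trace[-1]
                                 if f.objective_trace else math.inf)
        fits.append(f)
    if not fits:
        raise RuntimeError("all starts diverged: " + "; ".join(failures))
    fits.sort(key=lambda f: f.validation_rmse)
    return fits
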