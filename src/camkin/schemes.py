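"""Kinetic schemes for calcium-calmodulin binding.

Six published scheme topologies are supported, spanning the range of
calmodulin models used in the literature:

* ``S1`` -- three whole-molecule states (CaM0, CaM2Ca, CaM4Ca); each step
  binds two Ca2+ ions at once (strong structural co-operativity).
* ``S2`` -- four states; the first step binds two ions, the remaining two
  bind singly.
* ``S3`` -- fully expanded sequential chain of five states; every binding
  event is explicit but lobes are not distinguished.
* ``S4`` -- lobe-structured lumped scheme (CaM0, CaM2C, CaM2N, CaM4Ca)
  obtained from S5 by a quasi-steady-state (QSS) elimination of the singly
  bound lobe species; its four effective rate "slots" are functions of the
  eight underlying rates and of free Ca2+.
* ``S5`` -- independent C and N lobes, each a three-state chain with
  identical sites; simulated as six independent lobe species.
* ``S6`` -- independent lobes with *distinct* sites: each lobe is a
  four-state diamond (two paths to the doubly bound lobe), eight lobe
  species and sixteen rate constants in total.

Conventions: concentrations in M, time in ms, bimolecular rates in
M^-1 ms^-1 and termolecular (two-ion) rates in M^-2 ms^-1.  Rate constants
are carried in log10 space and exponentiated only when a concrete ODE
right-hand side is compiled.  Reverse rates are always derived from the
dissociation constants via K_D = k_off / k_on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.integrate import odeint
from scipy.linalg import null_space

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is pre-installed everywhere we run
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


SCHEME_IDS = ("S1", "S2", "S3", "S4", "S5", "S6")

#: auxiliary (non-calmodulin) species appended after the scheme's CaM species
BUFFER_SPECIES = ("DMn", "CaDMn", "PP", "CaPP", "OGB5N", "CaOGB5N")


@dataclass(frozen=True)
class Reaction:
    """One reversible Ca-binding step: reactant + n_ca * Ca <-> product."""

    reactant: str
    product: str
    n_ca: int
    forward_slot: str
    reverse_slot: str


@dataclass(frozen=True)
class SchemeSpec:
    """Declarative description of one calmodulin scheme."""

    scheme_id: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    kd_definitions: dict[str, tuple[str, str]]  # KD name -> (reverse_slot, forward_slot)
    n_bound: dict[str, int]
    components: tuple[tuple[str, ...], ...]
    qss_reduced: bool = False

    def to_json_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "species": list(self.species),
            "reactions": [
                {"reactant": r.reactant, "product": r.product,
                 "n_ca_bound": r.n_ca, "forward_slot": r.forward_slot,
                 "reverse_slot": r.reverse_slot} for r in self.reactions
            ],
            "kd_definitions": {k: list(v) for k, v in self.kd_definitions.items()},
            "n_bound": dict(self.n_bound),
            "components": [list(c) for c in self.components],
            "qss_reduced": self.qss_reduced,
        }

    @property
    def forward_slots(self) -> tuple[str, ...]:
        return tuple(r.forward_slot for r in self.reactions)

    @property
    def kd_names(self) -> tuple[str, ...]:
        return tuple(self.kd_definitions)

    def kd_for_forward_slot(self, slot: str) -> str:
        for name, (_, fwd) in self.kd_definitions.items():
            if fwd == slot:
                return name
        raise KeyError(slot)

    def reaction_order(self, reaction: Reaction) -> int:
        return 1 + reaction.n_ca

    def cam_weight(self, species: str) -> float:
        """Fraction of one calmodulin molecule this species accounts for.

        Whole-molecule schemes count each species once; lobe schemes count
        each lobe species as half a molecule (every CaM contributes one C
        and one N lobe)."""
        return 1.0 if len(self.components) == 1 else 0.5

    def max_bound(self) -> int:
        return sum(max(self.n_bound[s] for s in comp) for comp in self.components)


@dataclass
class RateSet:
    """log10 rate constants for one scheme.

    ``log10_forward`` maps forward slots (``k1``, ``k3``, ...) to log10 on-
    rates; ``log10_kd`` maps dissociation-constant names to log10 K_D (units
    M for single-ion steps, M^2 for two-ion steps).  Reverse rates are
    derived, never stored.  ``double_forward`` / ``double_reverse`` flag
    slots whose published values follow an intrinsic-site convention and
    must be doubled (statistical factor for identical sites) to obtain the
    macroscopic constants used in the ODEs.
    """

    scheme_id: str
    log10_forward: dict[str, float]
    log10_kd: dict[str, float]
    source_label: str = ""
    double_forward: tuple[str, ...] = ()
    double_reverse: tuple[str, ...] = ()

    def log10_reverse(self, spec: SchemeSpec, kd_name: str) -> float:
        rev, fwd = spec.kd_definitions[kd_name]
        return self.log10_kd[kd_name] + self.log10_forward[fwd]

    def linear_pairs(self, spec: SchemeSpec) -> list[tuple[float, float]]:
        """(k_on, k_off) per reaction, in spec.reactions order, with the
        statistical-factor convention applied.

        For the QSS-reduced scheme the stored slots are the *underlying*
        chain rates; the pairs returned are those of the unreduced per-lobe
        chains (the effective lumped rates are Ca-dependent and built by
        qss_effective_rates / the compiled system)."""
        if spec.qss_reduced:
            spec = build_scheme("S5")
        pairs = []
        for r in spec.reactions:
            kd_name = spec.kd_for_forward_slot(r.forward_slot)
            kf = 10.0 ** self.log10_forward[r.forward_slot]
            kr = 10.0 ** (self.log10_kd[kd_name] + self.log10_forward[r.forward_slot])
            if r.forward_slot in self.double_forward:
                kf *= 2.0
            if r.reverse_slot in self.double_reverse:
                kr *= 2.0
            if not (np.isfinite(kf) and np.isfinite(kr)):
                raise ValueError(f"non-finite rate for reaction {r}")
            pairs.append((kf, kr))
        return pairs

    def linear_kd(self, kd_name: str) -> float:
        return 10.0 ** self.log10_kd[kd_name]

    def to_json_dict(self) -> dict:
        return {
            "scheme_id": self.scheme_id,
            "log10_forward": dict(self.log10_forward),
            "log10_kd": dict(self.log10_kd),
            "source_label": self.source_label,
            "double_forward": list(self.double_forward),
            "double_reverse": list(self.double_reverse),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RateSet":
        return cls(
            scheme_id=d["scheme_id"],
            log10_forward=dict(d["log10_forward"]),
            log10_kd=dict(d["log10_kd"]),
            source_label=d.get("source_label", ""),
            double_forward=tuple(d.get("double_forward", ())),
            double_reverse=tuple(d.get("double_reverse", ())),
        )


@dataclass(frozen=True)
class BufferParams:
    """Rate constants of the auxiliary buffers (linear scale, M^-1 ms^-1 /
    ms^-1) and the indicator fluorescence ratio.

    The defaults are Faas-style placeholder values: a high-affinity,
    moderately fast photolabile chelator (DMn), a low-affinity fast
    photoproduct (PP) and a low-affinity fast indicator (OGB-5N).
    """

    dmn_kon: float = 3.0e4
    dmn_koff: float = 1.5e-4  # K_D = 5 nM
    photoproduct_kon: float = 3.0e4
    photoproduct_koff: float = 90.0  # K_D = 3 mM
    ogb5n_kon: float = 4.0e5
    ogb5n_koff: float = 14.0  # K_D = 35 uM
    fmax_over_fmin: float = 39.364

    def __post_init__(self):
        rates = (
            self.dmn_kon,
            self.dmn_koff,
            self.photoproduct_kon,
            self.photoproduct_koff,
            self.ogb5n_kon,
            self.ogb5n_koff,
        )
        if any(r <= 0 for r in rates):
            raise ValueError("all buffer rates must be positive")
        if self.photoproduct_koff / self.photoproduct_kon <= self.dmn_koff / self.dmn_kon:
            raise ValueError("photoproduct must have much lower affinity than DMn")


def _chain(scheme_id, names, n_per_step, slot_start=1, kd_start=1, slot_suffix=""):
    reactions = []
    kds = {}
    slot = slot_start
    kd = kd_start
    for a, b, n in zip(names[:-1], names[1:], n_per_step):
        f = f"k{slot}{slot_suffix}"
        r = f"k{slot + 1}{slot_suffix}"
        reactions.append(Reaction(a, b, n, f, r))
        kds[f"KD{kd}{slot_suffix}"] = (r, f)
        slot += 2
        kd += 1
    return reactions, kds


@lru_cache(maxsize=None)
def build_scheme(scheme_id: str) -> SchemeSpec:
    """Return the declarative spec for one of the six schemes."""
    if scheme_id == "S1":
        sp = ("CaM0", "CaM2Ca", "CaM4Ca")
        reactions, kds = _chain("S1", sp, (2, 2))
        return SchemeSpec("S1", sp, tuple(reactions), kds,
                          {"CaM0": 0, "CaM2Ca": 2, "CaM4Ca": 4}, (sp,))
    if scheme_id == "S2":
        sp = ("CaM0", "CaM2Ca", "CaM3Ca", "CaM4Ca")
        reactions, kds = _chain("S2", sp, (2, 1, 1))
        return SchemeSpec("S2", sp, tuple(reactions), kds,
                          {"CaM0": 0, "CaM2Ca": 2, "CaM3Ca": 3, "CaM4Ca": 4}, (sp,))
    if scheme_id == "S3":
        sp = ("CaM0", "CaM1Ca", "CaM2Ca", "CaM3Ca", "CaM4Ca")
        reactions, kds = _chain("S3", sp, (1, 1, 1, 1))
        return SchemeSpec("S3", sp, tuple(reactions), kds,
                          {s: i for i, s in enumerate(sp)}, (sp,))
    if scheme_id == "S4":
        sp = ("CaM0", "CaM2C", "CaM2N", "CaM4Ca")
        # Effective lumped reactions; their four on/off slots are *derived*
        # from the eight underlying S5-style rates by qss_effective_rates.
        reactions = (
            Reaction("CaM0", "CaM2C", 2, "kss1", "kss2"),
            Reaction("CaM0", "CaM2N", 2, "kss3", "kss4"),
            Reaction("CaM2N", "CaM4Ca", 2, "kss5", "kss6"),
            Reaction("CaM2C", "CaM4Ca", 2, "kss7", "kss8"),
        )
        kds = {
            "KDss1": ("kss2", "kss1"),
            "KDss2": ("kss4", "kss3"),
            "KDss3": ("kss6", "kss5"),
            "KDss4": ("kss8", "kss7"),
        }
        return SchemeSpec("S4", sp, reactions, kds,
                          {"CaM0": 0, "CaM2C": 2, "CaM2N": 2, "CaM4Ca": 4},
                          (sp,), qss_reduced=True)
    if scheme_id == "S5":
        c = ("CaM0C", "CaM1C", "CaM2C")
        n = ("CaM0N", "CaM1N", "CaM2N")
        rc, kc = _chain("S5", c, (1, 1), slot_start=1, kd_start=1)
        rn, kn = _chain("S5", n, (1, 1), slot_start=5, kd_start=3)
        nb = {"CaM0C": 0, "CaM1C": 1, "CaM2C": 2, "CaM0N": 0, "CaM1N": 1, "CaM2N": 2}
        return SchemeSpec("S5", c + n, tuple(rc + rn), {**kc, **kn}, nb, (c, n))
    if scheme_id == "S6":
        species = []
        reactions = []
        kds = {}
        comps = []
        nb = {}
        for lobe in ("c", "n"):
            L = lobe.upper()
            s0, s1, s2, s12 = f"CaM0{L}", f"CaM{L}a", f"CaM{L}b", f"CaM2{L}"
            comp = (s0, s1, s2, s12)
            comps.append(comp)
            species.extend(comp)
            nb.update({s0: 0, s1: 1, s2: 1, s12: 2})
            # diamond: site-a path (k1..k4) and site-b path (k5..k8)
            reactions += [
                Reaction(s0, s1, 1, f"k1{lobe}", f"k2{lobe}"),
                Reaction(s1, s12, 1, f"k3{lobe}", f"k4{lobe}"),
                Reaction(s0, s2, 1, f"k5{lobe}", f"k6{lobe}"),
                Reaction(s2, s12, 1, f"k7{lobe}", f"k8{lobe}"),
            ]
            for i in range(1, 5):
                kds[f"KD{i}{lobe}"] = (f"k{2 * i}{lobe}", f"k{2 * i - 1}{lobe}")
        return SchemeSpec("S6", tuple(species), tuple(reactions), kds, nb,
                          tuple(comps))
    raise ValueError(f"unknown scheme_id {scheme_id!r}; expected one of {SCHEME_IDS}")


def qss_effective_rates(rates: RateSet, free_ca: float) -> dict[str, float]:
    """Effective lumped rates for Scheme 4 from a Scheme-5-style rate set.

    For one lobe chain A <-k1,k2-> B <-k3,k4-> C, setting dB/dt = 0 gives
    B = (k1 Ca A + k4 C) / (k2 + k3 Ca) and hence the lumped two-ion step
    A + 2 Ca <-> C with

        k_on_eff  = k1 k3 / (k2 + k3 Ca)      [M^-2 ms^-1]
        k_off_eff = k2 k4 / (k2 + k3 Ca)      [ms^-1]

    so the effective K_D equals K_D1 * K_D2 (in M^2) at every free Ca.
    Returned keys are the S4 effective slots ``kss1..kss8`` (C-lobe binding
    on-/off-, N-lobe binding on-/off-rates, repeated for the second lobe's
    binding on the already half-occupied molecule).
    """
    if free_ca <= 0:
        raise ValueError("free_ca must be positive")
    if set(rates.log10_forward) != {"k1", "k3", "k5", "k7"}:
        raise ValueError("expected a Scheme-4/5 rate set with slots k1,k3,k5,k7")
    spec5 = build_scheme("S5")
    (k1, k2), (k3, k4), (k5, k6), (k7, k8) = rates.linear_pairs(spec5)
    den_c = k2 + k3 * free_ca
    den_n = k6 + k7 * free_ca
    kon_c, koff_c = k1 * k3 / den_c, k2 * k4 / den_c
    kon_n, koff_n = k5 * k7 / den_n, k6 * k8 / den_n
    return {
        "kss1": kon_c, "kss2": koff_c,   # CaM0 -> CaM2C
        "kss3": kon_n, "kss4": koff_n,   # CaM0 -> CaM2N
        "kss5": kon_c, "kss6": koff_c,   # CaM2N -> CaM4Ca (C lobe binds)
        "kss7": kon_n, "kss8": koff_n,   # CaM2C -> CaM4Ca (N lobe binds)
    }


# ---------------------------------------------------------------------------
# Compiled ODE system
# ---------------------------------------------------------------------------

@njit(cache=True)
def _rhs_core(y, t, ri, rj, rn, kf, kr, d0, d1, tau, baseline):  # pragma: no cover
    ca = y[0] if y[0] > 0.0 else 0.0
    dy = np.zeros_like(y)
    for r in range(ri.shape[0]):
        yi = y[ri[r]]
        yj = y[rj[r]]
        if yi < 0.0:
            yi = 0.0
        if yj < 0.0:
            yj = 0.0
        den = d0[r] + d1[r] * ca
        can = ca if rn[r] == 1 else ca * ca
        flux = (kf[r] / den) * can * yi - (kr[r] / den) * yj
        dy[ri[r]] -= flux
        dy[rj[r]] += flux
        dy[0] -= rn[r] * flux
    if tau > 0.0:
        dy[0] -= (ca - baseline) / tau
    return dy


class System:
    """A scheme + rate set + buffers compiled to flat arrays for fast
    mass-action RHS evaluation.

    Species order: Ca, <CaM species in spec order>, DMn, CaDMn, PP, CaPP,
    OGB5N, CaOGB5N.
    """

    def __init__(self, spec: SchemeSpec, rates: RateSet, buffers: BufferParams):
        self.spec = spec
        self.rates = rates
        self.buffers = buffers
        self.names: tuple[str, ...] = ("Ca",) + spec.species + BUFFER_SPECIES
        self.index = {n: i for i, n in enumerate(self.names)}
        n_reac = len(spec.reactions) + 3
        ri = np.empty(n_reac, dtype=np.int64)
        rj = np.empty(n_reac, dtype=np.int64)
        rn = np.empty(n_reac, dtype=np.int64)
        kf = np.empty(n_reac)
        kr = np.empty(n_reac)
        d0 = np.ones(n_reac)
        d1 = np.zeros(n_reac)
        if spec.qss_reduced:
            # S4: flux numerators/denominators carry the full QSS algebra,
            #   k_eff = k1 k3 / (k2 + k3 Ca), exactly (no fixed-Ca freeze).
            spec5 = build_scheme("S5")
            (k1, k2), (k3, k4), (k5, k6), (k7, k8) = rates.linear_pairs(spec5)
            lobe = {
                "C": (k1 * k3, k2 * k4, k2, k3),
                "N": (k5 * k7, k6 * k8, k6, k7),
            }
            which = ("C", "N", "C", "N")
            for r, (reac, lb) in enumerate(zip(spec.reactions, which)):
                ri[r] = self.index[reac.reactant]
                rj[r] = self.index[reac.product]
                rn[r] = reac.n_ca
                kf[r], kr[r], d0[r], d1[r] = lobe[lb]
        else:
            for r, (reac, (f, rev)) in enumerate(zip(spec.reactions, rates.linear_pairs(spec))):
                ri[r] = self.index[reac.reactant]
                rj[r] = self.index[reac.product]
                rn[r] = reac.n_ca
                kf[r], kr[r] = f, rev
        b = len(spec.reactions)
        for off, (free, bound, kon, koff) in enumerate([
            ("DMn", "CaDMn", buffers.dmn_kon, buffers.dmn_koff),
            ("PP", "CaPP", buffers.photoproduct_kon, buffers.photoproduct_koff),
            ("OGB5N", "CaOGB5N", buffers.ogb5n_kon, buffers.ogb5n_koff),
        ]):
            ri[b + off] = self.index[free]
            rj[b + off] = self.index[bound]
            rn[b + off] = 1
            kf[b + off], kr[b + off] = kon, koff
        self._arrays = (ri, rj, rn, kf, kr, d0, d1)

    def rhs(self, y: np.ndarray, extrusion: tuple[float, float] | None = None) -> np.ndarray:
        tau, baseline = extrusion if extrusion is not None else (0.0, 0.0)
        return _rhs_core(np.asarray(y, dtype=float), 0.0, *self._arrays, tau, baseline)

    def integrate(self, y0, t_eval, extrusion=None, rtol=1e-8, atol=1e-13):
        """Integrate with LSODA (stiff-capable) and return states at t_eval.

        ``t_eval`` must be increasing; a leading t=0 is handled naturally.
        """
        tau, baseline = extrusion if extrusion is not None else (0.0, 0.0)
        args = self._arrays + (tau, baseline)
        t = np.asarray(t_eval, dtype=float)
        single = False
        if t[0] > 0.0:
            t = np.concatenate(([0.0], t))
            single = True
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # failures handled via info below
            sol, info = odeint(
                _rhs_core, np.asarray(y0, dtype=float), t, args=args,
                rtol=rtol, atol=atol, tfirst=False, full_output=True,
                mxstep=12000,
            )
        if info["message"] != "Integration successful.":
            raise RuntimeError(f"ODE integration failed: {info['message']}")
        return sol[1:] if single else sol

    def state_from_dict(self, conc: dict[str, float]) -> np.ndarray:
        y = np.zeros(len(self.names))
        for k, v in conc.items():
            y[self.index[k]] = v
        return y

    def state_to_dict(self, y: np.ndarray) -> dict[str, float]:
        return {n: float(y[i]) for n, i in self.index.items()}

    # -- conserved quantities -------------------------------------------
    def cam_totals(self, y: np.ndarray) -> np.ndarray:
        """Total calmodulin per connected component (per lobe for S5/S6)."""
        return np.array([
            sum(y[self.index[s]] for s in comp) for comp in self.spec.components
        ])

    def total_ca(self, y: np.ndarray) -> float:
        tot = y[0]
        for s in self.spec.species:
            tot += self.spec.n_bound[s] * y[self.index[s]]
        for bound in ("CaDMn", "CaPP", "CaOGB5N"):
            tot += y[self.index[bound]]
        return float(tot)


@lru_cache(maxsize=64)
def _cached_system(spec_id: str, rates_key: tuple, buffers: BufferParams) -> System:
    scheme = build_scheme(spec_id)
    rates = RateSet(
        scheme_id=spec_id,
        log10_forward=dict(rates_key[0]),
        log10_kd=dict(rates_key[1]),
        source_label=rates_key[2],
        double_forward=rates_key[3],
        double_reverse=rates_key[4],
    )
    return System(scheme, rates, buffers)


def get_system(spec: SchemeSpec, rates: RateSet, buffers: BufferParams) -> System:
    key = (
        tuple(sorted(rates.log10_forward.items())),
        tuple(sorted(rates.log10_kd.items())),
        rates.source_label,
        tuple(rates.double_forward),
        tuple(rates.double_reverse),
    )
    return _cached_system(spec.scheme_id, key, buffers)


def ode_rhs(spec: SchemeSpec, rates: RateSet, buffers: BufferParams,
            state: dict[str, float], extrusion: tuple[float, float] | None = None,
            ) -> dict[str, float]:
    """Mass-action time derivative (M/ms) of every species in ``state``.

    ``extrusion``, if given, is (tau_ms, baseline_M): free Ca gains an extra
    -(Ca - baseline)/tau leak term (single-exponential extrusion model).
    """
    sys = get_system(spec, rates, buffers)
    missing = set(spec.species) - set(state)
    if missing:
        raise KeyError(f"missing species in state: {sorted(missing)}")
    if any(v < 0 for v in state.values()):
        raise ValueError("negative concentration in state")
    dy = sys.rhs(sys.state_from_dict(state), extrusion)
    return sys.state_to_dict(dy)


# ---------------------------------------------------------------------------
# Equilibrium
# ---------------------------------------------------------------------------

def _component_weights(spec: SchemeSpec, rates: RateSet, free_ca: float,
                       component: tuple[str, ...]) -> np.ndarray:
    """Relative equilibrium abundances of one connected component at clamped
    free Ca, normalized to sum 1.

    Chains (and the consistent S4 cycle) use the detailed-balance path
    product [Ca]^n / K_D along reactions; the S6 diamond is not constrained
    to close thermodynamically, so its steady state is the null space of the
    clamped linear rate matrix.
    """
    idx = {s: i for i, s in enumerate(component)}
    reactions = [r for r in spec.reactions if r.reactant in idx]
    if spec.scheme_id == "S6":
        m = np.zeros((len(component), len(component)))
        pairs = dict(zip([r for r in spec.reactions], rates.linear_pairs(spec)))
        for r in reactions:
            kf, kr = pairs[r]
            i, j = idx[r.reactant], idx[r.product]
            fwd = kf * free_ca ** r.n_ca
            m[i, i] -= fwd
            m[j, i] += fwd
            m[j, j] -= kr
            m[i, j] += kr
        # steady state: solve M w = 0 with the normalization sum(w) = 1
        # (better conditioned than an explicit null space for extreme rates)
        a = m.copy()
        scale = np.max(np.abs(a), axis=1)
        scale[scale == 0] = 1.0
        a /= scale[:, None]
        a[-1, :] = 1.0
        b = np.zeros(len(component))
        b[-1] = 1.0
        try:
            w = np.linalg.solve(a, b)
        except np.linalg.LinAlgError:
            ns = null_space(m)
            if ns.shape[1] != 1:
                raise RuntimeError(
                    f"degenerate steady state for component {component}")
            w = np.abs(ns[:, 0])
        w = np.clip(w, 0.0, None)
        return w / w.sum()
    # tree / consistent cycle: walk from the component's first species
    w = np.full(len(component), np.nan)
    w[0] = 1.0
    pending = list(reactions)
    while pending:
        progressed = False
        for r in list(pending):
            i, j = idx[r.reactant], idx[r.product]
            if spec.qss_reduced:
                # S4 lumped steps: effective K_D = K_D1 K_D2 per lobe (M^2)
                kd = _s4_effective_kd(rates, r)
            else:
                kd = rates.linear_kd(spec.kd_for_forward_slot(r.forward_slot))
            if not np.isnan(w[i]):
                w[j] = w[i] * free_ca ** r.n_ca / kd
                pending.remove(r)
                progressed = True
            elif not np.isnan(w[j]):
                w[i] = w[j] * kd / free_ca ** r.n_ca
                pending.remove(r)
                progressed = True
        if not progressed:
            raise RuntimeError("disconnected component")
    return w / w.sum()


def _s4_effective_kd(rates: RateSet, reaction: Reaction) -> float:
    kd1, kd2 = rates.linear_kd("KD1"), rates.linear_kd("KD2")
    kd3, kd4 = rates.linear_kd("KD3"), rates.linear_kd("KD4")
    lobe = {"kss1": kd1 * kd2, "kss3": kd3 * kd4, "kss5": kd1 * kd2, "kss7": kd3 * kd4}
    return lobe[reaction.forward_slot]


def equilibrium_weights(spec: SchemeSpec, rates: RateSet, free_ca: float,
                        ) -> list[np.ndarray]:
    """Per-component normalized equilibrium abundances at clamped free Ca."""
    if free_ca <= 0:
        raise ValueError("free_ca must be positive")
    return [
        _component_weights(spec, rates, free_ca, comp) for comp in spec.components
    ]


def equilibrium_occupancy(spec: SchemeSpec, rates: RateSet, free_ca: float) -> float:
    """Mean number of Ca2+ ions bound per calmodulin at clamped free Ca.

    Free Ca is treated as held fixed (titration conditions).  For lobe
    schemes the per-lobe occupancies add, giving a value in [0, 4].
    """
    occ = 0.0
    for comp, w in zip(spec.components, equilibrium_weights(spec, rates, free_ca)):
        occ += float(sum(spec.n_bound[s] * wi for s, wi in zip(comp, w)))
    return occ


def equilibrium_cam_state(spec: SchemeSpec, rates: RateSet, free_ca: float,
                          total_cam: float) -> dict[str, float]:
    """Concentrations of every CaM species at clamped free Ca.

    For lobe schemes each component carries ``total_cam`` of lobes."""
    out = {}
    for comp, w in zip(spec.components, equilibrium_weights(spec, rates, free_ca)):
        for s, wi in zip(comp, w):
            out[s] = float(total_cam * wi)
    return out


# ---------------------------------------------------------------------------
# Packaged rate fixtures
# ---------------------------------------------------------------------------

@lru_cache(maxsize=1)
def _fixture_data() -> dict:
    with resources.files("camkin.fixtures").joinpath("rate_sets.json").open() as fh:
        return json.load(fh)


def load_rate_set(scheme_id: str, source: str) -> RateSet:
    """Load one of the packaged published / fitted rate sets.

    Sources include ``our_fits`` for every scheme plus the literature values
    (``kim``, ``hayer_bhalla``, ``shifman``, ``pepke``, ``faas``, ``byrne``).
    The Shifman set carries only dissociation constants; its forward slots
    are filled with a nominal fast on-rate and flagged in ``source_label``.
    """
    data = _fixture_data()
    try:
        entry = data[scheme_id][source]
    except KeyError:
        raise KeyError(f"no packaged rate set {scheme_id}/{source}") from None
    return RateSet(
        scheme_id=scheme_id,
        log10_forward={k: float(v) for k, v in entry["log10_forward"].items()},
        log10_kd={k: float(v) for k, v in entry["log10_kd"].items()},
        source_label=entry.get("source_label", source),
        double_forward=tuple(entry.get("double_forward", ())),
        double_reverse=tuple(entry.get("double_reverse", ())),
    )


def available_rate_sets() -> dict[str, list[str]]:
    return {sch: sorted(srcs) for sch, srcs in _fixture_data().items()}
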