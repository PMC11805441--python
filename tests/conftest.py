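import numpy as np
import pytest
from scipy.integrate import solve_ivp

from camkin.schemes import BufferParams, build_scheme


@pytest.fixture(scope="session")
def buffers():
    return BufferParams()


ALL_SCHEME_SOURCES = [
    ("S1", "our_fits"), ("S1", "kim"),
    ("S2", "our_fits"), ("S2", "hayer_bhalla"),
    ("S3", "our_fits"), ("S3", "shifman"),
    ("S4", "our_fits"), ("S4", "pepke"),
    ("S5", "our_fits"), ("S5", "faas"),
    ("S6", "our_fits"), ("S6", "byrne"),
]


def clamped_relaxation_occupancy(spec, rates, free_ca, rtol=1e-10):
    """Independent steady-state oracle: integrate the calmodulin subsystem
    with free Ca held fixed until relaxation, then average bound ions.

    Built directly from the declarative reaction list (not the compiled
    mass-action system) so it exercises a separate code path.
    """
    species = list(spec.species)
    idx = {s: i for i, s in enumerate(species)}
    if spec.qss_reduced:
        from camkin.schemes import qss_effective_rates

        eff = qss_effective_rates(rates, free_ca)
        pairs = [(eff[r.forward_slot], eff[r.reverse_slot])
                 for r in spec.reactions]
    else:
        pairs = []
        for r in spec.reactions:
            kd_name = spec.kd_for_forward_slot(r.forward_slot)
            kf = 10.0 ** rates.log10_forward[r.forward_slot]
            kr = 10.0 ** (rates.log10_kd[kd_name]
                          + rates.log10_forward[r.forward_slot])
            if r.forward_slot in rates.double_forward:
                kf *= 2.0
            if r.reverse_slot in rates.double_reverse:
                kr *= 2.0
            pairs.append((kf, kr))

    def rhs(t, y):
        dy = np.zeros_like(y)
        for r, (kf, kr) in zip(spec.reactions, pairs):
            flux = kf * free_ca ** r.n_ca * y[idx[r.reactant]] \
                - kr * y[idx[r.product]]
            dy[idx[r.reactant]] -= flux
            dy[idx[r.product]] += flux
        return dy

    y0 = np.zeros(len(species))
    for comp in spec.components:
        y0[idx[comp[0]]] = 1.0
    # relax over many decades; LSODA takes large steps once settled
    sol = solve_ivp(rhs, (0.0, 1e9), y0, method="LSODA", rtol=rtol,
                    atol=1e-14, t_eval=[1e9])
    y = sol.y[:, -1]
    occ = 0.0
    for comp in spec.components:
        tot = sum(y[idx[s]] for s in comp)
        occ += sum(spec.n_bound[s] * y[idx[s]] for s in comp) / tot
    return occ
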