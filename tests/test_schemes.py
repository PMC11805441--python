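"""Structure, mass-action kinetics and equilibrium of the six schemes."""

import numpy as np
import pytest

from camkin.schemes import (
    SCHEME_IDS,
    BufferParams,
    RateSet,
    build_scheme,
    equilibrium_occupancy,
    get_system,
    load_rate_set,
    ode_rhs,
    qss_effective_rates,
)

from conftest import ALL_SCHEME_SOURCES, clamped_relaxation_occupancy


EXPECTED_SHAPE = {  # species count, reaction count, connected components
    "S1": (3, 2, 1), "S2": (4, 3, 1), "S3": (5, 4, 1),
    "S4": (4, 4, 1), "S5": (6, 4, 2), "S6": (8, 8, 2),
}


@pytest.mark.parametrize("sid", SCHEME_IDS)
def test_scheme_structure(sid):
    spec = build_scheme(sid)
    n_sp, n_re, n_comp = EXPECTED_SHAPE[sid]
    assert len(spec.species) == n_sp
    assert len(spec.reactions) == n_re
    assert len(spec.components) == n_comp
    # every forward/reverse slot appears in exactly one reaction
    fwd = [r.forward_slot for r in spec.reactions]
    rev = [r.reverse_slot for r in spec.reactions]
    assert len(set(fwd)) == len(fwd)
    assert len(set(rev)) == len(rev)
    # reaction order 1 + n_ca, n_ca in {1, 2}
    for r in spec.reactions:
        assert r.n_ca in (1, 2)
        assert spec.reaction_order(r) == 1 + r.n_ca
    # every K_D maps onto exactly one reaction's slot pair
    assert len(spec.kd_definitions) == n_re
    for name, (rslot, fslot) in spec.kd_definitions.items():
        matching = [r for r in spec.reactions
                    if r.forward_slot == fslot and r.reverse_slot == rslot]
        assert len(matching) == 1


def test_scheme1_binds_two_ions_per_step():
    spec = build_scheme("S1")
    assert spec.species == ("CaM0", "CaM2Ca", "CaM4Ca")
    assert all(r.n_ca == 2 for r in spec.reactions)


def test_scheme6_has_sixteen_rate_slots():
    spec = build_scheme("S6")
    slots = {r.forward_slot for r in spec.reactions} | \
            {r.reverse_slot for r in spec.reactions}
    assert len(slots) == 16
    # two 4-state components
    assert [len(c) for c in spec.components] == [4, 4]


def test_unknown_scheme_rejected():
    with pytest.raises(ValueError):
        build_scheme("S7")


def test_reverse_rates_are_derived():
    spec = build_scheme("S5")
    rates = load_rate_set("S5", "faas")
    for name, (rev, fwd) in spec.kd_definitions.items():
        assert rates.log10_reverse(spec, name) == pytest.approx(
            rates.log10_kd[name] + rates.log10_forward[fwd])


def test_statistical_factor_convention_doubles_flagged_slots():
    plain = load_rate_set("S4", "pepke")
    doubled = load_rate_set("S5", "pepke")
    spec = build_scheme("S5")
    pairs_plain = RateSet("S5", plain.log10_forward, plain.log10_kd).linear_pairs(spec)
    pairs_doubled = doubled.linear_pairs(spec)
    # first on-rates (reactions 0, 2) and second off-rates (reactions 1, 3)
    assert pairs_doubled[0][0] == pytest.approx(2 * pairs_plain[0][0])
    assert pairs_doubled[2][0] == pytest.approx(2 * pairs_plain[2][0])
    assert pairs_doubled[1][1] == pytest.approx(2 * pairs_plain[1][1])
    assert pairs_doubled[3][1] == pytest.approx(2 * pairs_plain[3][1])
    assert pairs_doubled[0][1] == pytest.approx(pairs_plain[0][1])


@pytest.mark.parametrize("sid,source", ALL_SCHEME_SOURCES)
def test_fixture_rate_sets_load(sid, source):
    rates = load_rate_set(sid, source)
    spec = build_scheme(sid)
    pairs = rates.linear_pairs(spec)
    assert len(pairs) == len(spec.reactions)
    assert all(np.isfinite(p).all() and min(p) > 0 for p in pairs)


def test_rate_set_json_roundtrip():
    rates = load_rate_set("S5", "pepke")
    again = RateSet.from_json_dict(rates.to_json_dict())
    assert again == rates


def test_zero_ca_limit_scheme1(buffers):
    spec = build_scheme("S1")
    rates = load_rate_set("S1", "our_fits")
    state = {"Ca": 0.0, "CaM0": 0.0, "CaM2Ca": 1e-6, "CaM4Ca": 0.0,
             "DMn": 0.0, "CaDMn": 0.0, "PP": 0.0, "CaPP": 0.0,
             "OGB5N": 0.0, "CaOGB5N": 0.0}
    dy = ode_rhs(spec, rates, buffers, state)
    k2 = 10.0 ** (rates.log10_kd["KD1"] + rates.log10_forward["k1"])
    assert dy["CaM0"] == pytest.approx(k2 * 1e-6, rel=1e-12)
    assert dy["CaM0"] > 0
    assert dy["CaM4Ca"] == 0.0


def test_scheme1_rhs_matches_hand_expansion(buffers):
    """Independent term-by-term expansion of the S1 mass-action equations."""
    spec = build_scheme("S1")
    rates = load_rate_set("S1", "our_fits")
    k1 = 10.0 ** 8.10
    k2 = 10.0 ** (-9.00 + 8.10)
    k3 = 10.0 ** 4.00
    k4 = 10.0 ** (-9.00 + 4.00)
    ca, c0, c2, c4 = 2e-6, 3e-6, 1e-6, 0.5e-6
    state = {"Ca": ca, "CaM0": c0, "CaM2Ca": c2, "CaM4Ca": c4,
             "DMn": 0.0, "CaDMn": 0.0, "PP": 0.0, "CaPP": 0.0,
             "OGB5N": 0.0, "CaOGB5N": 0.0}
    dy = ode_rhs(spec, rates, buffers, state)
    assert dy["CaM0"] == pytest.approx(-k1 * ca ** 2 * c0 + k2 * c2, rel=1e-12)
    assert dy["CaM2Ca"] == pytest.approx(
        k1 * ca ** 2 * c0 - k2 * c2 - k3 * ca ** 2 * c2 + k4 * c4, rel=1e-12)
    assert dy["CaM4Ca"] == pytest.approx(k3 * ca ** 2 * c2 - k4 * c4, rel=1e-12)
    flux1 = k1 * ca ** 2 * c0 - k2 * c2
    flux2 = k3 * ca ** 2 * c2 - k4 * c4
    assert dy["Ca"] == pytest.approx(-2 * flux1 - 2 * flux2, rel=1e-12)


@pytest.mark.parametrize("sid,source", ALL_SCHEME_SOURCES)
def test_cam_derivatives_conserve_cam(sid, source, buffers):
    spec = build_scheme(sid)
    rates = load_rate_set(sid, source)
    rng = np.random.default_rng(42)
    sys = get_system(spec, rates, buffers)
    for _ in range(3):
        y = rng.uniform(0, 1e-5, size=len(sys.names))
        dy = sys.rhs(y)
        for comp in spec.components:
            d_tot = sum(dy[sys.index[s]] for s in comp)
            scale = max(abs(dy).max(), 1e-30)
            assert abs(d_tot) <= 1e-12 * scale


def test_extrusion_term(buffers):
    spec = build_scheme("S1")
    rates = load_rate_set("S1", "our_fits")
    state = {"Ca": 5e-7, "CaM0": 0.0, "CaM2Ca": 0.0, "CaM4Ca": 0.0,
             "DMn": 0.0, "CaDMn": 0.0, "PP": 0.0, "CaPP": 0.0,
             "OGB5N": 0.0, "CaOGB5N": 0.0}
    base = ode_rhs(spec, rates, buffers, state)
    with_ext = ode_rhs(spec, rates, buffers, state, extrusion=(12.0, 100e-9))
    assert with_ext["Ca"] - base["Ca"] == pytest.approx(
        -(5e-7 - 100e-9) / 12.0, rel=1e-12)


def test_negative_concentration_rejected(buffers):
    spec = build_scheme("S1")
    rates = load_rate_set("S1", "our_fits")
    state = {"Ca": -1e-9, "CaM0": 0.0, "CaM2Ca": 0.0, "CaM4Ca": 0.0,
             "DMn": 0.0, "CaDMn": 0.0, "PP": 0.0, "CaPP": 0.0,
             "OGB5N": 0.0, "CaOGB5N": 0.0}
    with pytest.raises(ValueError):
        ode_rhs(spec, rates, buffers, state)


# ---------------------------------------------------------------------------
# Equilibrium
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("sid,source", ALL_SCHEME_SOURCES)
def test_occupancy_limits(sid, source):
    spec = build_scheme(sid)
    rates = load_rate_set(sid, source)
    assert equilibrium_occupancy(spec, rates, 1e-12) < 1e-3
    assert equilibrium_occupancy(spec, rates, 10.0) == pytest.approx(4.0, abs=1e-3)
    with pytest.raises(ValueError):
        equilibrium_occupancy(spec, rates, 0.0)


def test_occupancy_matches_shifman_relaxation_oracle():
    """Titration of the sequential scheme with the published K_Ds agrees
    with long-time clamped-Ca ODE relaxation."""
    spec = build_scheme("S3")
    rates = load_rate_set("S3", "shifman")
    for ca in np.geomspace(3e-7, 5e-5, 6):
        closed = equilibrium_occupancy(spec, rates, ca)
        relaxed = clamped_relaxation_occupancy(spec, rates, ca)
        assert closed == pytest.approx(relaxed, rel=1e-6, abs=1e-9)


def test_detailed_balance_equal_kds_gives_equal_abundance():
    # all K_D equal and [Ca] = K_D^(1/n): adjacent chain states equi-abundant
    from camkin.schemes import equilibrium_weights

    rates = RateSet("S3", {"k1": 5, "k3": 5, "k5": 5, "k7": 5},
                    {"KD1": -6, "KD2": -6, "KD3": -6, "KD4": -6})
    spec = build_scheme("S3")
    w = equilibrium_weights(spec, rates, 1e-6)[0]
    assert np.allclose(w, w[0])


# ---------------------------------------------------------------------------
# QSS reduction
# ---------------------------------------------------------------------------

def test_qss_effective_kd_is_product_of_chain_kds():
    rates = load_rate_set("S5", "faas")
    for ca in (1e-7, 1e-6, 1e-5):
        eff = qss_effective_rates(rates, ca)
        kd_c = eff["kss2"] / eff["kss1"]
        kd_n = eff["kss4"] / eff["kss3"]
        assert kd_c == pytest.approx(
            rates.linear_kd("KD1") * rates.linear_kd("KD2"), rel=1e-12)
        assert kd_n == pytest.approx(
            rates.linear_kd("KD3") * rates.linear_kd("KD4"), rel=1e-12)


def test_qss_on_rate_vanishes_with_fast_intermediate_unbinding():
    base = load_rate_set("S5", "faas")
    fast_off = RateSet("S5", dict(base.log10_forward),
                       {**base.log10_kd, "KD1": 3.0})  # k2 = KD1 * k1 huge
    slow = qss_effective_rates(fast_off, 1e-6)
    ref = qss_effective_rates(base, 1e-6)
    assert slow["kss1"] < 1e-6 * ref["kss1"]


def test_qss_rejects_bad_inputs():
    rates = load_rate_set("S5", "faas")
    with pytest.raises(ValueError):
        qss_effective_rates(rates, 0.0)
    with pytest.raises(ValueError):
        qss_effective_rates(load_rate_set("S6", "byrne"), 1e-6)
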