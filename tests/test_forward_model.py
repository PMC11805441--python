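"""Uncaging models, initial conditions, observables and simulation."""

import numpy as np
import pytest

from camkin.forward_model import (
    ODESettings,
    Recording,
    SolutionComposition,
    apply_flash,
    ca_per_cam,
    delta_f_f0,
    pre_flash_equilibrium,
    predict_dff,
    simulate_recording,
    uncaging_fraction_linear,
    uncaging_fraction_sigmoid,
)
from camkin.schemes import build_scheme, equilibrium_occupancy, load_rate_set, ode_rhs


@pytest.fixture(scope="module")
def s5():
    return build_scheme("S5"), load_rate_set("S5", "our_fits")


@pytest.fixture(scope="module")
def comp():
    return SolutionComposition(total_cam=20e-6, total_dmn=2e-3,
                               total_ogb5n=50e-6, total_ca=0.24e-3,
                               group_label="A")


class TestUncagingModels:
    def test_linear_printed_coefficients(self):
        assert uncaging_fraction_linear(0, 0.39) == pytest.approx(0.0)
        assert uncaging_fraction_linear(1000, 0) == pytest.approx(0.71)
        # the defect motivating the sigmoid: output escapes [0, 1]
        assert uncaging_fraction_linear(0, 0) == pytest.approx(-0.39)

    def test_sigmoid_properties(self):
        assert uncaging_fraction_sigmoid(0.0) == 0.5
        assert uncaging_fraction_sigmoid(40.0) == pytest.approx(1.0)
        assert uncaging_fraction_sigmoid(-40.0) == pytest.approx(0.0, abs=1e-15)
        for x in (-3.2, -0.5, 0.0, 1.7, 6.0):
            u = uncaging_fraction_sigmoid(x)
            assert 0.0 < u < 1.0
            assert u + uncaging_fraction_sigmoid(-x) == pytest.approx(1.0)
        xs = np.linspace(-5, 5, 50)
        assert np.all(np.diff(uncaging_fraction_sigmoid(xs)) > 0)


class TestPreFlashEquilibrium:
    def test_zero_ca_all_unbound(self, s5, buffers):
        spec, rates = s5
        c = SolutionComposition(10e-6, 1e-3, 50e-6, 0.0)
        st = pre_flash_equilibrium(c, spec, rates, buffers)
        assert st["Ca"] == 0.0
        assert st["CaDMn"] == 0.0
        assert st["CaOGB5N"] == 0.0
        assert st["CaM0C"] == pytest.approx(10e-6)

    def test_dominant_buffer_takes_nearly_all_ca(self, s5, buffers):
        spec, rates = s5
        c = SolutionComposition(0.0, 5e-3, 1e-9, 0.5e-3)
        st = pre_flash_equilibrium(c, spec, rates, buffers)
        # single-buffer isotherm: free Ca from total balance with K_D(DMn)
        kd = buffers.dmn_koff / buffers.dmn_kon
        assert st["CaDMn"] / c.total_ca > 0.999
        assert st["CaDMn"] == pytest.approx(
            c.total_dmn * st["Ca"] / (st["Ca"] + kd), rel=1e-9)

    def test_is_fixed_point_of_rhs(self, s5, comp, buffers):
        spec, rates = s5
        st = pre_flash_equilibrium(comp, spec, rates, buffers)
        dy = ode_rhs(spec, rates, buffers, st)
        gross = max(abs(v) for v in dy.values())
        assert gross < 1e-15  # M/ms; solved in closed form, roundoff only

    def test_totals_conserved(self, s5, comp, buffers):
        spec, rates = s5
        st = pre_flash_equilibrium(comp, spec, rates, buffers)
        assert st["DMn"] + st["CaDMn"] == pytest.approx(comp.total_dmn)
        assert st["OGB5N"] + st["CaOGB5N"] == pytest.approx(comp.total_ogb5n)
        ca_total = st["Ca"] + st["CaDMn"] + st["CaOGB5N"] + sum(
            spec.n_bound[s] * st[s] for s in spec.species)
        assert ca_total == pytest.approx(comp.total_ca, rel=1e-9)


class TestFlash:
    def test_identity_and_full_conversion(self, s5, comp, buffers):
        spec, rates = s5
        st = pre_flash_equilibrium(comp, spec, rates, buffers)
        assert apply_flash(st, 0.0) == st
        full = apply_flash(st, 1.0)
        assert full["DMn"] == 0.0 and full["CaDMn"] == 0.0
        assert full["PP"] == pytest.approx(st["DMn"])
        assert full["CaPP"] == pytest.approx(st["CaDMn"])

    def test_total_ca_conserved_for_any_fraction(self, s5, comp, buffers):
        spec, rates = s5
        st = pre_flash_equilibrium(comp, spec, rates, buffers)
        for u in (0.1, 0.5, 0.93):
            st2 = apply_flash(st, u)
            before = st["CaDMn"] + st["CaPP"]
            after = st2["CaDMn"] + st2["CaPP"]
            assert after == pytest.approx(before, rel=1e-12)

    def test_fraction_out_of_range_rejected(self, s5, comp, buffers):
        spec, rates = s5
        st = pre_flash_equilibrium(comp, spec, rates, buffers)
        for u in (-0.1, 1.1):
            with pytest.raises(ValueError):
                apply_flash(st, u)


class TestDeltaFF0:
    def test_unity_at_t0(self):
        out = delta_f_f0(np.array([3e-5]), np.array([1e-5]), 3e-5, 1e-5)
        assert out[0] == 1.0

    def test_extremes_give_fluorescence_ratio(self):
        # nothing bound at t=0, everything bound later -> value = R
        out = delta_f_f0(np.array([0.0]), np.array([5e-5]), 5e-5, 0.0)
        assert out[0] == pytest.approx(39.364)

    def test_homogeneity(self):
        a = delta_f_f0(np.array([2e-5]), np.array([3e-5]), 4e-5, 1e-5)
        b = delta_f_f0(np.array([2e-2]), np.array([3e-2]), 4e-2, 1e-2)
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            delta_f_f0(np.array([1.0]), np.array([1.0]), 0.0, 0.0)

    def test_increases_with_bound_fraction(self):
        total = 5e-5
        bound = np.linspace(0, total, 10)
        out = delta_f_f0(total - bound, bound, total - 1e-6, 1e-6)
        assert np.all(np.diff(out) > 0)


class TestCaPerCam:
    def test_extremes_and_average(self):
        spec = build_scheme("S1")
        assert ca_per_cam({"CaM0": 1e-6, "CaM2Ca": 0, "CaM4Ca": 0}, spec) == 0
        assert ca_per_cam({"CaM0": 0, "CaM2Ca": 0, "CaM4Ca": 1e-6}, spec) == 4
        assert ca_per_cam({"CaM0": 1e-6, "CaM2Ca": 0, "CaM4Ca": 1e-6}, spec) == 2

    def test_lobe_scheme_counts_both_lobes(self):
        spec = build_scheme("S5")
        st = {"CaM0C": 0, "CaM1C": 0, "CaM2C": 1e-6,
              "CaM0N": 1e-6, "CaM1N": 0, "CaM2N": 0}
        assert ca_per_cam(st, spec) == pytest.approx(2.0)

    def test_no_cam_rejected(self):
        spec = build_scheme("S1")
        with pytest.raises(ValueError):
            ca_per_cam({"CaM0": 0, "CaM2Ca": 0, "CaM4Ca": 0}, spec)


class TestSimulateRecording:
    def test_no_flash_stays_at_equilibrium(self, s5, comp, buffers):
        spec, rates = s5
        rec = Recording("r", comp, 0.0, np.linspace(0, 10, 11), np.zeros(11))
        dff = predict_dff(rec, spec, rates, buffers, eta=-40.0)
        assert np.allclose(dff, 1.0, atol=1e-6)

    def test_long_time_reaches_postflash_equilibrium(self, s5, comp, buffers):
        """After the flash the system must relax to the equilibrium of the
        post-flash totals (checked through the independent closed-form
        occupancy at the relaxed free Ca)."""
        spec, rates = s5
        rec = Recording("r", comp, 0.0, np.array([0.0, 5e4]), np.zeros(2))
        traj, sys = simulate_recording(rec, spec, rates, buffers, eta=0.5)
        end = sys.state_to_dict(traj[-1])
        occ_sim = ca_per_cam({s: end[s] for s in spec.species}, spec)
        occ_eq = equilibrium_occupancy(spec, rates, end["Ca"])
        assert occ_sim == pytest.approx(occ_eq, rel=1e-5)

    def test_grid_refinement_invariance(self, s5, comp, buffers):
        spec, rates = s5
        coarse_t = np.linspace(0, 20, 21)
        fine_t = np.linspace(0, 20, 201)
        rc = Recording("c", comp, 0.0, coarse_t, np.zeros_like(coarse_t))
        rf = Recording("f", comp, 0.0, fine_t, np.zeros_like(fine_t))
        dc = predict_dff(rc, spec, rates, buffers, eta=0.3)
        df = predict_dff(rf, spec, rates, buffers, eta=0.3)
        assert np.allclose(dc, df[::10], rtol=1e-4, atol=1e-6)

    def test_nonfinite_eta_rejected(self, s5, comp, buffers):
        spec, rates = s5
        rec = Recording("r", comp, 0.0, np.linspace(0, 1, 5), np.zeros(5))
        with pytest.raises(ValueError):
            simulate_recording(rec, spec, rates, buffers, eta=np.nan)


class TestRecordingValidation:
    def test_misaligned_rejected(self, comp):
        with pytest.raises(ValueError):
            Recording("r", comp, 0.0, np.array([0.0, 1.0]), np.array([1.0]))

    def test_nonincreasing_times_rejected(self, comp):
        with pytest.raises(ValueError):
            Recording("r", comp, 0.0, np.array([0.0, 1.0, 1.0]), np.zeros(3))
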