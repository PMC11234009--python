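"""Finite-volume bioheat solver: limits, conservation, coupling."""

import numpy as np
import pytest

from coldwater import (
    BioheatModel,
    BloodPool,
    BodyModel,
    BodySegment,
    EnvironmentBC,
    boundary_flux,
)
from coldwater.control import PASSIVE
from coldwater.grid import build_grid
from coldwater.tissues import tissue_properties

MUSCLE = tissue_properties("muscle")


def uniform_muscle_body(radius=0.05, length=1.0):
    """Single uniform muscle cylinder (verification geometry)."""
    seg = BodySegment(
        "abdomen", "cylinder", outer_radius=radius, length=length,
        skin_thickness=0.004, layers=(("muscle", radius),), skin_weight=1.0,
    )
    return BodyModel(segments=(seg,))


def layered_cylinder_body(radius=0.05, length=1.0):
    """Muscle core with the standard 4 mm skin shell."""
    seg = BodySegment(
        "abdomen", "cylinder", outer_radius=radius, length=length,
        skin_thickness=0.004,
        layers=(("muscle", radius - 0.004), ("skin", radius)), skin_weight=1.0,
    )
    return BodyModel(segments=(seg,))


class TestBoundaryFlux:
    def test_direct_substitution(self):
        # 220 * (5 - 34.5): an outward loss of 6490 W/m²
        assert boundary_flux(220.0, 5.0, 34.5) == pytest.approx(-6490.0)

    def test_zero_gradient(self):
        assert boundary_flux(220.0, 20.0, 20.0) == 0.0

    def test_insulated_limit(self):
        assert boundary_flux(0.0, -2.0, 37.0) == 0.0

    def test_negative_h_rejected(self):
        with pytest.raises(ValueError):
            boundary_flux(-1.0, 5.0, 34.5)
        with pytest.raises(ValueError):
            EnvironmentBC(T_ext=5.0, h=-10.0)


class TestGrid:
    @pytest.mark.parametrize("name", ["abdomen", "head", "arm"])
    def test_cell_volumes_telescope_to_segment_volume(self, body, name):
        seg = body.segment(name)
        g = build_grid(seg, nr=40)
        assert g.vol.sum() == pytest.approx(seg.volume, rel=1e-12)
        assert g.vol_by_layer.sum() == pytest.approx(seg.volume, rel=1e-12)

    def test_nodes_span_axis_to_surface(self, body):
        g = build_grid(body.segment("thigh"), nr=40)
        assert g.r[0] == 0.0
        assert g.r[-1] == pytest.approx(body.segment("thigh").outer_radius)
        assert np.all(np.diff(g.r) > 0)

    def test_skin_resolved_by_at_least_four_nodes(self, body):
        for seg in body.segments:
            g = build_grid(seg, nr=40)
            assert int(g.nodes_in("skin").sum()) >= 4

    def test_per_layer_volumes_match_shell_formulas(self, body):
        import math

        seg = body.segment("abdomen")
        g = build_grid(seg, nr=40)
        bounds = [0.0] + [r for _, r in seg.layers]
        for j, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
            shell = math.pi * (b**2 - a**2) * seg.length * seg.count
            assert g.vol_by_layer[:, j].sum() == pytest.approx(shell, rel=1e-12)


class TestStepLimits:
    def test_equilibrium_state_is_stationary(self):
        """Uniform T = Tb with sources cancelled stays put."""
        body = layered_cylinder_body()
        model = BioheatModel(body, controls=PASSIVE, nr=40)
        state = model.initial_state()
        state.T["abdomen"][:] = 37.0
        for w in model.work.values():
            w.qcal_W = -w.qmV_W  # perfusion already vanishes at T = Tb
        out, _ = model.step(state, EnvironmentBC(T_ext=37.0, h=0.0))
        np.testing.assert_allclose(out.T["abdomen"], 37.0, atol=1e-10)
        assert out.Tb == pytest.approx(37.0, abs=1e-10)

    def test_source_only_heating_rate(self):
        """With ωb = 0, h = 0 every node rises by q_m/(ρ cp) per unit time."""
        body = uniform_muscle_body()
        model = BioheatModel(body, controls=PASSIVE, basal_offset=False,
                             nr=40, dt=1.0)
        w = model.work["abdomen"]
        w.P_muscle[:] = 0.0
        state = model.initial_state()
        out, _ = model.step(state, EnvironmentBC(T_ext=0.0, h=0.0))
        expected = 37.0 + MUSCLE.q_m / MUSCLE.rho_cp * 1.0
        np.testing.assert_allclose(out.T["abdomen"], expected, rtol=1e-12)

    def test_lumped_capacitance_decay(self):
        """Small-Biot cylinder cools on the ρ cp V/(h A) time constant."""
        body = uniform_muscle_body(radius=0.05, length=1.0)
        model = BioheatModel(body, controls=PASSIVE, basal_offset=False,
                             nr=40, dt=0.5)
        w = model.work["abdomen"]
        w.P_muscle[:] = 0.0
        w.qmV_W[:] = 0.0
        # make conduction effectively infinite (uniform internal T)
        g = w.grid
        object.__setattr__(g, "cond", g.cond * 1e4)
        state = model.initial_state()
        state.T["abdomen"][:] = 30.0
        h, T_inf, t_end = 50.0, 0.0, 600.0
        res = model.integrate(EnvironmentBC(T_inf, h), t_end, record_every=t_end,
                              initial_state=state, freeze_blood=True)
        C = float(w.M.sum())
        tau = C / (h * g.surface_area)
        expected = T_inf + 30.0 * np.exp(-t_end / tau)
        assert res.rectal[-1] == pytest.approx(expected, abs=0.15)


class TestBloodCoupling:
    def test_blood_unchanged_at_equilibrium(self):
        body = uniform_muscle_body()
        model = BioheatModel(body, controls=PASSIVE, basal_offset=False, nr=40)
        for w in model.work.values():
            w.qmV_W[:] = 0.0
        state = model.initial_state()
        out, _ = model.step(state, EnvironmentBC(T_ext=37.0, h=0.0))
        assert out.Tb == pytest.approx(37.0, abs=1e-12)

    def test_two_compartment_equilibration_rate(self):
        """Uniform tissue and blood relax at the closed-form two-pool rate."""
        body = uniform_muscle_body(radius=0.05, length=0.5)
        blood = BloodPool()
        model = BioheatModel(body, controls=PASSIVE, basal_offset=False,
                             nr=40, dt=0.2, blood=blood)
        w = model.work["abdomen"]
        w.qmV_W[:] = 0.0
        state = model.initial_state()
        state.T["abdomen"][:] = 30.0
        P = float(w.perf_conductance(1.0, 1.0).sum())
        C_t = float(w.M.sum())
        lam = P * (1 / C_t + 1 / blood.heat_capacity)
        t_end = 200.0
        res = model.integrate(EnvironmentBC(30.0, 0.0), t_end, record_every=t_end,
                              initial_state=state)
        expected_diff = 7.0 * np.exp(-lam * t_end)
        assert res.blood[-1] - res.rectal[-1] == pytest.approx(
            expected_diff, rel=0.02
        )

    def test_perfusion_heat_antisymmetry(self, passive_model):
        """Pool enthalpy change mirrors tissue perfusion heat exactly."""
        res = passive_model.integrate(EnvironmentBC(5.0, 220.0), t_end=120.0)
        led = res.ledger
        assert led.blood_enthalpy == pytest.approx(-led.perfusion, rel=1e-9)


class TestEnergyConservation:
    @pytest.mark.parametrize(
        "bc",
        [EnvironmentBC(5.0, 220.0), EnvironmentBC(-2.0, 680.0), EnvironmentBC(41.0, 220.0)],
        ids=["cold-still", "cold-salt-moving", "warm-bath"],
    )
    def test_closed_budget(self, body, bc):
        """Enthalpy change equals boundary + source heat to 0.1 %."""
        model = BioheatModel(body, nr=40)
        res = model.integrate(bc, t_end=900.0)
        assert res.ledger.relative_residual < 1e-3

    def test_budget_with_active_controls(self, body):
        model = BioheatModel(body, nr=40)
        res = model.integrate(EnvironmentBC(0.0, 220.0), t_end=1200.0)
        assert res.ledger.relative_residual < 1e-3


class TestRobinLimits:
    def test_infinite_h_pins_surface_to_ambient(self, body):
        # backward Euler: L-stable for the stiff Robin term
        model = BioheatModel(body, controls=PASSIVE, nr=40, theta=1.0)
        res = model.integrate(EnvironmentBC(5.0, 1e5), t_end=300.0)
        for region, trace in res.skin.items():
            assert trace[-1] == pytest.approx(5.0, abs=0.2)

    def test_zero_h_drifts_at_metabolic_rate(self):
        """Insulated raw-Pennes body warms at the metabolic heating rate."""
        body = uniform_muscle_body()
        model = BioheatModel(body, controls=PASSIVE, basal_offset=False,
                             nr=40, dt=1.0)
        w = model.work["abdomen"]
        w.P_muscle[:] = 0.0
        res = model.integrate(EnvironmentBC(20.0, 0.0), t_end=600.0,
                              freeze_blood=True)
        expected = 37.0 + MUSCLE.q_m / MUSCLE.rho_cp * 600.0
        assert res.rectal[-1] == pytest.approx(expected, rel=1e-6)


class TestThermoneutralEquilibrium:
    def test_core_and_blood_hold_37C_in_thermoneutral_bath(self, body):
        """In a 37 °C bath the calibrated basal state keeps the core put.

        The skin trace relaxes from 34.5 °C toward the bath (a cooler
        surface cannot be stationary against a warmer environment), but
        core and blood stay at 37 °C to within ~0.1 °C for an hour.
        """
        model = BioheatModel(body, nr=40)
        res = model.integrate(EnvironmentBC(37.0, 220.0), t_end=3600.0,
                              record_every=300.0)
        assert np.all(np.abs(res.rectal - 37.0) < 0.15)
        assert np.all(np.abs(res.blood - 37.0) < 0.15)
        assert np.all(res.mean_skin >= 34.4) and np.all(res.mean_skin <= 37.3)


class TestMonotonicity:
    def test_colder_or_stronger_exchange_never_slows_cooling(self, body):
        """Time for the core to reach 35 °C is monotone in T_ext and h."""
        from coldwater.scenarios import survival_time_from_series

        def time_to_35(T_ext, h):
            model = BioheatModel(body, controls=PASSIVE, nr=24, dt=4.0)
            res = model.integrate(
                EnvironmentBC(T_ext, h), t_end=4800.0, record_every=60.0
            )
            return survival_time_from_series(res.t_min, res.rectal, threshold=35.0)

        t_cold = time_to_35(0.0, 220.0)
        t_warm = time_to_35(10.0, 220.0)
        t_hi_h = time_to_35(0.0, 680.0)
        assert t_cold is not None and t_hi_h is not None
        assert t_hi_h <= t_cold
        assert t_warm is None or t_cold <= t_warm


class TestDivergenceGuard:
    def test_unstable_state_raises(self, body):
        model = BioheatModel(body, controls=PASSIVE, nr=40)
        state = model.initial_state()
        state.T["abdomen"][:] = np.nan
        with pytest.raises(FloatingPointError):
            model.step(state, EnvironmentBC(5.0, 220.0))
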