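"""Transient Pennes bioheat solver on the multi-segment body.

Physics
-------
Each segment solves the 1-D radial Pennes equation

    ρ cp ∂T/∂t = ∇·(k ∇T) + ρ_b c_b ω_b (T_b − T) + q_m + q_shiv + q_cal

with a Robin (convective) surface condition q₀ = h (T_ext − T).  There is
no tissue-scale advection and no external volumetric source; every exchange
with the environment enters through the surface coefficient h, which lumps
convection and radiation.  Segments do not conduct into each other; they
are coupled exclusively through a lumped arterial blood pool whose energy
balance collects every perfusion exchange:

    m_b c_b dT_b/dt = − Σ ρ_b c_b ω_b (T_b − T) V_cell .

``q_cal`` is a constant basal-offset source fixed at assembly so that the
normothermic initial state (interior 37 °C, skin 34.5 °C) is a metabolic/
perfusion equilibrium: it cancels the basal perfusion exchange and basal
metabolic heat node-by-node, representing the basal losses (respiration,
evaporation, basal vasomotor tone) that the immersion boundary condition
does not model.  Deviations from the basal state then drive the dynamics.

Numerics
--------
Crank–Nicolson in time (θ = ½) with the perfusion sink treated implicitly;
tridiagonal solve per segment per step; operator splitting tissue-step →
blood-step with the perfusion heat computed at the θ-averaged tissue
temperature so that pool and tissue enthalpy changes cancel exactly.
A discrete energy ledger (boundary, source, perfusion, enthalpy) is
accumulated for conservation checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .body import BodyModel, mean_skin_temperature
from .control import ControlParams, control_state
from .grid import RadialGrid, build_grid
from .tissues import (
    BLOOD_DENSITY,
    BLOOD_SPECIFIC_HEAT,
    BLOOD_VOLUME_L,
    tissue_properties,
)

__all__ = [
    "EnvironmentBC",
    "BloodPool",
    "TemperatureState",
    "SimulationResult",
    "BioheatModel",
    "boundary_flux",
]

MEDIA = ("fresh_still", "fresh_moving", "salt_still", "salt_moving", "air_forced", "custom")

CORE_T0 = 37.0  # °C, initial interior (muscle/organ/head/blood) temperature
SKIN_T0 = 34.5  # °C, initial skin temperature

SANITY_BAND = (-10.0, 60.0)  # °C, divergence guard


@dataclass(frozen=True)
class EnvironmentBC:
    """Convective environment: temperature, coefficient, and medium tag."""

    T_ext: float  # °C
    h: float  # W/(m²·°C), lumped convective+radiative coefficient
    medium: str = "custom"

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError(f"heat transfer coefficient must be >= 0, got {self.h}")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}; one of {MEDIA}")


@dataclass(frozen=True)
class BloodPool:
    """Lumped arterial blood compartment."""

    rho_b: float = BLOOD_DENSITY  # kg/m³
    c_b: float = BLOOD_SPECIFIC_HEAT  # J/(kg·°C)
    mass_b: float = BLOOD_VOLUME_L * 1e-3 * BLOOD_DENSITY  # kg (5 L)
    Tb0: float = CORE_T0  # °C

    def __post_init__(self) -> None:
        if min(self.rho_b, self.c_b, self.mass_b) <= 0:
            raise ValueError("blood pool parameters must all be positive")

    @property
    def heat_capacity(self) -> float:
        """m_b·c_b, J/°C."""
        return self.mass_b * self.c_b


def boundary_flux(h: float, T_ext: float, T_surf: float) -> float:
    """Robin surface flux into the body, W/m²: ``q0 = h (T_ext − T_surf)``.

    Negative values are outward heat loss.  ``h`` must be non-negative.
    """
    if h < 0:
        raise ValueError(f"heat transfer coefficient must be >= 0, got {h}")
    return h * (T_ext - T_surf)


@dataclass
class TemperatureState:
    """Full thermal state: per-segment nodal fields, blood, and clock."""

    T: dict[str, np.ndarray]  # segment name → nodal temperatures, °C
    Tb: float  # blood temperature, °C
    t: float  # time, s

    def copy(self) -> "TemperatureState":
        return TemperatureState(
            T={k: v.copy() for k, v in self.T.items()}, Tb=self.Tb, t=self.t
        )

    def shifted(self, delta: float) -> "TemperatureState":
        """Uniformly shift every temperature by ``delta`` °C."""
        return TemperatureState(
            T={k: v + delta for k, v in self.T.items()}, Tb=self.Tb + delta, t=self.t
        )


@dataclass
class EnergyLedger:
    """Cumulative discrete energy bookkeeping, J."""

    boundary: float = 0.0  # heat through the skin surface (into body +)
    source: float = 0.0  # metabolic + shivering + basal offset
    perfusion: float = 0.0  # heat into tissue from the blood pool
    tissue_enthalpy: float = 0.0
    blood_enthalpy: float = 0.0

    @property
    def residual(self) -> float:
        """(ΔH_tissue + ΔH_blood) − (boundary + source); ~0 by construction."""
        return (self.tissue_enthalpy + self.blood_enthalpy) - (
            self.boundary + self.source
        )

    @property
    def relative_residual(self) -> float:
        scale = max(
            abs(self.boundary), abs(self.source), abs(self.tissue_enthalpy), 1.0
        )
        return abs(self.residual) / scale


@dataclass
class SimulationResult:
    """Recorded traces of one transient run.

    Times in seconds; temperatures in °C.  ``skin`` holds the surface-node
    temperature of each weighted region; ``mean_skin`` is their weighted
    sum.  ``final_state`` is the full thermal state at the last step.
    """

    t: np.ndarray
    rectal: np.ndarray
    blood: np.ndarray
    mean_skin: np.ndarray
    skin: dict[str, np.ndarray]
    shivering_W: np.ndarray
    ledger: EnergyLedger
    final_state: TemperatureState
    bc: EnvironmentBC

    @property
    def t_min(self) -> np.ndarray:
        """Sample times in minutes."""
        return self.t / 60.0

    def to_frame(self):
        """Long-format DataFrame: time_s, variable, segment, value (°C/W)."""
        import pandas as pd

        rows = [
            pd.DataFrame({"time_s": self.t, "variable": "rectal", "segment": "abdomen", "value": self.rectal}),
            pd.DataFrame({"time_s": self.t, "variable": "blood", "segment": "pool", "value": self.blood}),
            pd.DataFrame({"time_s": self.t, "variable": "mean_skin", "segment": "body", "value": self.mean_skin}),
            pd.DataFrame({"time_s": self.t, "variable": "shivering_W", "segment": "body", "value": self.shivering_W}),
        ]
        rows += [
            pd.DataFrame({"time_s": self.t, "variable": "skin", "segment": region, "value": trace})
            for region, trace in self.skin.items()
        ]
        return pd.concat(rows, ignore_index=True)


class _SegmentWork:
    """Precomputed per-segment arrays used by the stepper.

    Volumetric properties are built from the exact per-tissue volume split
    of each control volume, so cells straddling a layer interface carry
    volume-weighted heat capacity, perfusion and metabolism.
    """

    __slots__ = (
        "grid", "M", "P_skin", "P_muscle", "P_other", "qmV_W", "vol_muscle",
        "skin_mask", "muscle_mask", "qcal_W",
    )

    def __init__(self, grid: RadialGrid, blood: BloodPool):
        self.grid = grid
        props = [tissue_properties(name) for name in grid.tissue_names]
        vbl = grid.vol_by_layer  # (n, n_layers)
        rho_cp = np.array([p.rho_cp for p in props])
        wb = np.array([p.w_b for p in props])
        qm = np.array([p.q_m for p in props])
        self.M = vbl @ rho_cp  # J/°C per cell
        self.qmV_W = vbl @ qm  # W per cell (basal metabolism)
        # perfusion exchange conductance per cell, W/°C at factor 1, split
        # by the vasomotor group the tissue belongs to
        rbcb = blood.rho_b * blood.c_b
        skin_l = np.array([n == "skin" for n in grid.tissue_names])
        musc_l = np.array([n == "muscle" for n in grid.tissue_names])
        other_l = ~(skin_l | musc_l)
        self.P_skin = rbcb * (vbl[:, skin_l] @ wb[skin_l])
        self.P_muscle = rbcb * (vbl[:, musc_l] @ wb[musc_l])
        self.P_other = rbcb * (vbl[:, other_l] @ wb[other_l])
        self.vol_muscle = vbl[:, musc_l].sum(axis=1)
        self.skin_mask = grid.nodes_in("skin")
        self.muscle_mask = grid.nodes_in("muscle")
        self.qcal_W = np.zeros(grid.n)

    def perf_conductance(self, f_skin: float, f_muscle: float) -> np.ndarray:
        """Per-cell blood-tissue conductance, W/°C, at the given factors."""
        return self.P_other + f_skin * self.P_skin + f_muscle * self.P_muscle


class BioheatModel:
    """Assembled solver over a :class:`BodyModel`.

    Parameters
    ----------
    body : BodyModel
        Segment geometry and tissue layering.
    controls : ControlParams, optional
        Thermoregulatory parameters; defaults to the calibrated active set.
        Use :data:`coldwater.control.PASSIVE` for a passive body.
    nr : int
        Approximate radial nodes per segment.
    dt : float
        Time step, s.
    theta : float
        Time-weighting (0.5 = Crank–Nicolson, 1.0 = backward Euler).
    basal_offset : bool
        Apply the constant basal-offset source q_cal (default).  Disable
        for raw-Pennes verification runs against closed-form solutions.
    blood : BloodPool, optional
        Override blood-pool parameters.
    shiver_to_blood : float
        Fraction of shivering power delivered to the blood pool (default
        0.5).  Shivering muscle is strongly perfused (exercise
        hyperaemia), so most of its heat is picked up by the circulation
        and defends the core directly; the remainder is deposited locally
        in trunk/proximal muscle tissue.
    shiver_segments : tuple of str, optional
        Segments whose muscle receives the locally-deposited share of
        shivering heat.  Defaults to the trunk and proximal muscles
        (chest, back, abdomen, neck, thigh), where shivering
        thermogenesis is concentrated; distal limb muscle shivers little.
    """

    def __init__(
        self,
        body: BodyModel,
        controls: ControlParams | None = None,
        *,
        nr: int = 160,
        dt: float = 1.0,
        theta: float = 0.5,
        basal_offset: bool = True,
        blood: BloodPool | None = None,
        shiver_to_blood: float = 0.5,
        shiver_segments: tuple[str, ...] | None = None,
    ):
        if not 0.0 <= shiver_to_blood <= 1.0:
            raise ValueError("shiver_to_blood must lie in [0, 1]")
        self.shiver_to_blood = shiver_to_blood
        if dt <= 0:
            raise ValueError("dt must be positive")
        if not 0.0 <= theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        self.body = body
        self.controls = controls if controls is not None else ControlParams()
        self.dt = dt
        self.theta = theta
        self.blood = blood if blood is not None else BloodPool()
        self.basal_offset = basal_offset
        self.work: dict[str, _SegmentWork] = {
            s.name: _SegmentWork(build_grid(s, nr=nr), self.blood) for s in body.segments
        }
        if shiver_segments is None:
            shiver_segments = ("chest", "back", "abdomen", "neck", "thigh")
        present = tuple(n for n in shiver_segments if n in self.work)
        self.shiver_segments = present or tuple(self.work)
        self.shiver_volume = sum(
            float(self.work[n].vol_muscle.sum()) for n in self.shiver_segments
        )
        self.muscle_volume = sum(
            float(w.vol_muscle.sum()) for w in self.work.values()
        )
        self._rectal_segment = "abdomen" if any(
            s.name == "abdomen" for s in body.segments
        ) else body.segments[0].name
        if basal_offset:
            self._compute_basal_offset()

    # ------------------------------------------------------------------ setup

    def initial_state(self) -> TemperatureState:
        """Normothermic start: interior 37 °C, skin nodes 34.5 °C."""
        T = {}
        for name, w in self.work.items():
            field = np.full(w.grid.n, CORE_T0)
            field[w.skin_mask] = SKIN_T0
            T[name] = field
        return TemperatureState(T=T, Tb=self.blood.Tb0, t=0.0)

    def _compute_basal_offset(self) -> None:
        """Fix q_cal so the initial profile is a source equilibrium.

        Cancels, node by node, the basal perfusion exchange at the initial
        temperatures plus the basal metabolic heat.  Stored in watts per
        cell.
        """
        state = self.initial_state()
        for name, w in self.work.items():
            T0 = state.T[name]
            P0 = w.perf_conductance(1.0, 1.0)
            w.qcal_W = -(P0 * (self.blood.Tb0 - T0) + w.qmV_W)

    # ------------------------------------------------------------- observables

    def rectal(self, state: TemperatureState) -> float:
        """Core proxy: innermost node of the abdominal segment."""
        return float(state.T[self._rectal_segment][0])

    def skin_temps(self, state: TemperatureState) -> dict[str, float]:
        """Surface-node temperature of each weighted skin region."""
        return {
            s.name: float(state.T[s.name][-1])
            for s in self.body.segments
            if s.skin_weight > 0
        }

    def mean_skin(self, state: TemperatureState) -> float:
        """Weighted mean skin temperature.

        Uses the nine-region weighting when the body provides all nine
        regions; reduced bodies (e.g. single-segment verification cases)
        fall back to an area-weighted mean over their skin surfaces.
        """
        temps = self.skin_temps(state)
        try:
            return mean_skin_temperature(temps)
        except KeyError:
            areas = {s.name: s.surface_area for s in self.body.segments}
            total = sum(areas[n] for n in temps)
            return sum(temps[n] * areas[n] for n in temps) / total

    # ------------------------------------------------------------------ stepping

    def step(
        self,
        state: TemperatureState,
        bc: EnvironmentBC,
        ledger: EnergyLedger | None = None,
        *,
        freeze_blood: bool = False,
    ) -> tuple[TemperatureState, float]:
        """Advance one time step (tissue update, then blood update).

        Returns the new state and the whole-body shivering power applied
        during the step.  Raises ``FloatingPointError`` if the state leaves
        the sanity band (divergence guard).
        """
        dt, th = self.dt, self.theta
        for name, arr in state.T.items():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(
                    f"non-finite temperatures in segment {name!r} at t={state.t:.1f}s"
                )
        tc = self.rectal(state)
        ts = self.mean_skin(state)
        ctrl = control_state(tc, ts, self.controls)
        # muscle follows the cold-side factor with a higher floor; the
        # warm-side dilator response is cutaneous only (never above basal)
        f_muscle = min(1.0, max(ctrl.perfusion_factor, self.controls.f_min_muscle))
        shiv_local_W = (1.0 - self.shiver_to_blood) * ctrl.shivering_W
        shiv_blood_W = self.shiver_to_blood * ctrl.shivering_W
        q_shiv_vol = shiv_local_W / self.shiver_volume  # W/m³ on shivering muscle

        Tb = state.Tb
        newT: dict[str, np.ndarray] = {}
        perf_heat = 0.0  # J into tissue from blood this step

        for name, w in self.work.items():
            g = w.grid
            T_old = state.T[name]
            n = g.n

            P = w.perf_conductance(ctrl.perfusion_factor, f_muscle)
            shiv_here = q_shiv_vol if name in self.shiver_segments else 0.0
            S = w.qmV_W + shiv_here * w.vol_muscle
            if self.basal_offset:
                S = S + w.qcal_W
            Gb = bc.h * g.surface_area

            # L T + b with L tridiagonal (conduction + perfusion + Robin)
            lower = np.zeros(n)
            upper = np.zeros(n)
            diag = -P.astype(float)
            diag[-1] -= Gb
            lower[1:] = g.cond
            upper[:-1] = g.cond
            diag[:-1] -= g.cond
            diag[1:] -= g.cond
            b = P * Tb + S
            b[-1] += Gb * bc.T_ext

            # (M/dt − θL) T_new = (M/dt + (1−θ)L) T_old + b
            Mdt = w.M / dt
            ab = np.zeros((3, n))
            ab[0, 1:] = -th * upper[:-1]
            ab[1] = Mdt - th * diag
            ab[2, :-1] = -th * lower[1:]
            rhs = Mdt * T_old + (1.0 - th) * (
                diag * T_old
                + np.concatenate(([0.0], lower[1:] * T_old[:-1]))
                + np.concatenate((upper[:-1] * T_old[1:], [0.0]))
            ) + b
            T_new = solve_banded((1, 1), ab, rhs)
            newT[name] = T_new

            T_half = th * T_new + (1.0 - th) * T_old
            perf_heat += float(np.sum(P * (Tb - T_half))) * dt
            if ledger is not None:
                ledger.boundary += Gb * (bc.T_ext - T_half[-1]) * dt
                ledger.source += float(S.sum()) * dt
                ledger.tissue_enthalpy += float(np.sum(w.M * (T_new - T_old)))

        if ledger is not None:
            ledger.perfusion += perf_heat

        if freeze_blood:
            Tb_new = Tb
        else:
            Tb_new = Tb + (shiv_blood_W * dt - perf_heat) / self.blood.heat_capacity
        if ledger is not None and not freeze_blood:
            ledger.source += shiv_blood_W * dt
            ledger.blood_enthalpy += self.blood.heat_capacity * (Tb_new - Tb)

        new_state = TemperatureState(T=newT, Tb=Tb_new, t=state.t + dt)
        lo, hi = SANITY_BAND
        for name, arr in newT.items():
            if not np.all(np.isfinite(arr)) or arr.min() < lo or arr.max() > hi:
                raise FloatingPointError(
                    f"solver diverged in segment {name!r} at t={new_state.t:.1f}s "
                    f"(min={arr.min():.2f}, max={arr.max():.2f} °C)"
                )
        return new_state, ctrl.shivering_W

    # ----------------------------------------------------------------- integrate

    def integrate(
        self,
        bc: EnvironmentBC,
        t_end: float,
        *,
        record_every: float = 15.0,
        initial_state: TemperatureState | None = None,
        stop_rectal_below: float | None = None,
        stop_rectal_above: float | None = None,
        freeze_blood: bool = False,
    ) -> SimulationResult:
        """Run a transient simulation for ``t_end`` seconds.

        Recording happens every ``record_every`` seconds (plus the initial
        and final instants).  Early-stop thresholds act on the rectal trace
        and leave a short margin past the crossing so that interpolation
        brackets it.
        """
        state = initial_state.copy() if initial_state is not None else self.initial_state()
        ledger = EnergyLedger()
        n_steps = int(round(t_end / self.dt))
        rec_stride = max(1, int(round(record_every / self.dt)))

        times, rectals, bloods, mean_skins, shivs = [], [], [], [], []
        skins: dict[str, list[float]] = {r: [] for r in self.skin_temps(state)}

        def record(shiver_W: float) -> None:
            times.append(state.t)
            rectals.append(self.rectal(state))
            bloods.append(state.Tb)
            st = self.skin_temps(state)
            for r, v in st.items():
                skins[r].append(v)
            mean_skins.append(self.mean_skin(state))
            shivs.append(shiver_W)

        record(0.0)
        stop_countdown = None
        for i in range(1, n_steps + 1):
            state, shiver_W = self.step(state, bc, ledger, freeze_blood=freeze_blood)
            if i % rec_stride == 0 or i == n_steps:
                record(shiver_W)
            if stop_countdown is None:
                r = self.rectal(state)
                if stop_rectal_below is not None and r < stop_rectal_below:
                    stop_countdown = rec_stride  # overshoot one record interval
                elif stop_rectal_above is not None and r > stop_rectal_above:
                    stop_countdown = rec_stride
            else:
                stop_countdown -= 1
                if stop_countdown <= 0:
                    if (i % rec_stride) != 0 and i != n_steps:
                        record(shiver_W)
                    break

        return SimulationResult(
            t=np.array(times),
            rectal=np.array(rectals),
            blood=np.array(bloods),
            mean_skin=np.array(mean_skins),
            skin={r: np.array(v) for r, v in skins.items()},
            shivering_W=np.array(shivs),
            ledger=ledger,
            final_state=state,
            bc=bc,
        )

    # -------------------------------------------------------------- steady state

    def steady_state(
        self,
        bc: EnvironmentBC,
        *,
        Tb: float | None = None,
        perfusion_factor: float = 1.0,
        shivering_W: float = 0.0,
    ) -> dict[str, np.ndarray]:
        """Direct steady solve per segment at a fixed blood temperature.

        Solves ``L T + b = 0`` with frozen controls; used for verification
        against the closed-form perfused-cylinder solution.
        """
        Tb = self.blood.Tb0 if Tb is None else Tb
        q_shiv_vol = shivering_W / self.shiver_volume if shivering_W else 0.0
        out = {}
        for name, w in self.work.items():
            g = w.grid
            n = g.n
            f_musc = min(1.0, max(perfusion_factor, self.controls.f_min_muscle))
            P = w.perf_conductance(perfusion_factor, f_musc)
            shiv_here = q_shiv_vol if name in self.shiver_segments else 0.0
            S = w.qmV_W + shiv_here * w.vol_muscle
            if self.basal_offset:
                S = S + w.qcal_W
            Gb = bc.h * g.surface_area
            diag = -P.astype(float)
            diag[-1] -= Gb
            diag[:-1] -= g.cond
            diag[1:] -= g.cond
            ab = np.zeros((3, n))
            ab[0, 1:] = -g.cond
            ab[1] = -diag
            ab[2, :-1] = -g.cond
            b = P * Tb + S
            b[-1] += Gb * bc.T_ext
            out[name] = solve_banded((1, 1), ab, b)
        return out
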