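"""Analytic oracles and randomized scenario suites for solver verification.

The steady constant-coefficient perfused cylinder admits a closed-form
solution in modified Bessel functions; it is evaluated here through
``scipy.special`` routines entirely independent of the finite-volume path,
and serves as the reference for nodal-accuracy checks.  A seeded scenario
generator produces randomized environments for property tests
(monotonicity of cooling in h and T_ext) without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import i0, i1

from .tissues import BLOOD_DENSITY, BLOOD_SPECIFIC_HEAT, TissueProperties

__all__ = ["AnalyticCase", "analytic_steady_radial", "generate_scenario_suite"]


@dataclass(frozen=True)
class AnalyticCase:
    """Uniform infinite cylinder with Robin surface exchange.

    Single tissue, constant coefficients, fixed arterial temperature.
    """

    radius: float  # m
    tissue: TissueProperties
    h: float  # W/(m²·°C)
    T_ext: float  # °C
    Tb: float  # °C

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.h < 0:
            raise ValueError("h must be non-negative")


def analytic_steady_radial(case: AnalyticCase, r: np.ndarray) -> np.ndarray:
    """Closed-form steady radial temperature profile, °C.

    Solves ``k (T'' + T'/r) + P (Tb − T) + q_m = 0`` with
    ``−k T'(R) = h (T(R) − T_ext)`` and ``P = ρ_b c_b ω_b``:

        T(r) = T∞ + A·I0(m r),   m = √(P/k),   T∞ = Tb + q_m / P,
        A = −h (T∞ − T_ext) / (k m I1(mR) + h I0(mR)).

    For vanishing perfusion the pure-conduction parabola with volumetric
    source is returned instead.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > case.radius * (1 + 1e-12)):
        raise ValueError("evaluation radii must lie within [0, R]")
    k, qm = case.tissue.k, case.tissue.q_m
    P = BLOOD_DENSITY * BLOOD_SPECIFIC_HEAT * case.tissue.w_b
    R, h = case.radius, case.h

    if P < 1e-12:
        # conduction only: T = T_ext + qm R/(2h) + qm (R² − r²)/(4k)
        surf = case.T_ext + (qm * R / (2.0 * h) if h > 0 else 0.0)
        return surf + qm * (R**2 - r**2) / (4.0 * k)

    m = math.sqrt(P / k)
    T_inf = case.Tb + qm / P
    denom = k * m * i1(m * R) + h * i0(m * R)
    A = -h * (T_inf - case.T_ext) / denom
    return T_inf + A * i0(m * r)


def generate_scenario_suite(seed: int, n: int):
    """Draw ``n`` randomized immersion scenarios, reproducibly.

    Environments span T_ext ∈ [−2, 30] °C and h ∈ [5, 1000] W/(m²·°C)
    across the supported media, with mode sampled between cooling and
    rewarming.  Returns a list of :class:`coldwater.scenarios.Scenario`.
    """
    from .scenarios import Scenario

    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    media = ["fresh_still", "fresh_moving", "salt_still", "salt_moving", "custom"]
    out = []
    for i in range(n):
        medium = media[rng.integers(len(media))]
        t_lo = -2.0 if medium.startswith("salt") or medium == "custom" else 0.0
        T_ext = float(rng.uniform(t_lo, 30.0))
        h = float(rng.uniform(5.0, 1000.0))
        mode = "cooling" if rng.random() < 0.8 else "rewarming"
        if mode == "rewarming":
            T_ext = float(rng.uniform(38.0, 43.0))
        out.append(
            Scenario(
                label=f"random_{seed}_{i}",
                medium=medium,
                T_ext=T_ext,
                h=h,
                mode=mode,
                t_max_min=float(rng.uniform(30.0, 240.0)),
            )
        )
    return out
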