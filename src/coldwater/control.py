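"""Thermoregulatory control laws: vasoconstriction and shivering.

Both effectors are linear-gain laws around the thermoneutral set-points
(core 37 °C, mean skin 34.5 °C), the simplest forms consistent with
whole-body thermal models of the Wissler lineage:

* **Vasomotor control** scales the skin blood perfusion rate by a factor
  ``f``: on the cold side ``f = clamp(1 − a_s·(Ts_set − Ts), f_min, 1)``
  (cutaneous vasoconstriction down to a deep-cold floor ``f_min``), and on
  the warm side ``f = clamp(1 + a_d·(Ts − Ts_set), 1, f_max)`` (active
  cutaneous vasodilation during warm immersion, up to several times basal
  flow).  Muscle perfusion follows the cold-side factor with a much higher
  floor (``f_min_muscle``) and never exceeds basal: both the constrictor
  and dilator responses are predominantly cutaneous.
* **Shivering** adds volumetric heat to muscle,
  ``q = clamp(g_c·(Tc_set − Tc) + g_s·(Ts_set − Ts), 0, q_max)`` expressed
  here as whole-body watts and distributed uniformly over muscle volume.
  Shivering ceases entirely once the core drops below 32 °C.

The shivering gains and cap carry a single calibration multiplier
(``shiver_scale``) fixed once against the 5 °C still-fresh-water anchor
scenario; every other scenario is then a prediction.  The calibration
driver ships in ``scripts/calibrate.py``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["ControlParams", "ControlState", "perfusion_factor", "shivering_heat", "PASSIVE"]

#: core temperature below which shivering stops, °C
SHIVER_CUTOFF_TC = 32.0


@dataclass(frozen=True)
class ControlParams:
    """Set-points, gains and caps of the two control laws.

    Gains are expressed as whole-body shivering power per °C of deviation;
    the solver divides by total muscle volume to get W/m³.

    ``shiver_scale`` is the single calibrated multiplier applied to
    ``g_core_W``, ``g_skin_W`` and ``q_shiv_max_W`` together (anchor:
    5 °C still fresh water → 136 min survival).
    """

    tc_set: float = 37.0  # °C
    ts_set: float = 34.5  # °C
    g_core_W: float = 70.0  # W per °C core deviation
    g_skin_W: float = 10.0  # W per °C skin deviation
    q_shiv_max_W: float = 350.0  # pre-scale cap (basal-multiple units)
    shiver_scale: float = 2.3271  # calibrated once (scripts/calibrate.py)
    a_s: float = 0.2  # vasoconstriction gain, 1/°C
    f_min: float = 0.1  # skin perfusion-factor floor
    f_min_muscle: float = 0.7  # muscle floor: vasoconstriction is mostly cutaneous
    a_d: float = 1.5  # warm-side vasodilation gain, 1/°C
    f_max: float = 12.0  # skin perfusion ceiling under heat strain
    enabled: bool = True

    def scaled(self, scale: float) -> "ControlParams":
        return replace(self, shiver_scale=scale)


#: controls switched off (passive body)
PASSIVE = ControlParams(enabled=False)


@dataclass(frozen=True)
class ControlState:
    """Instantaneous effector output applied during one solver step."""

    perfusion_factor: float  # dimensionless, [f_min, f_max], on skin ωb
    shivering_W: float  # whole-body shivering power, W

    def __post_init__(self) -> None:
        if not 0.0 < self.perfusion_factor:
            raise ValueError("perfusion_factor must be positive")
        if self.shivering_W < 0.0:
            raise ValueError("shivering power cannot be negative")


def perfusion_factor(tc: float, ts: float, params: ControlParams) -> float:
    """Skin perfusion scaling under thermal strain.

    Returns 1 at the thermoneutral set-points, decreases linearly with
    skin cooling down to ``f_min``, and rises linearly with skin warming
    up to ``f_max`` (active vasodilation); non-decreasing in skin
    temperature.
    """
    if not params.enabled:
        return 1.0
    if ts >= params.ts_set:
        f = 1.0 + params.a_d * (ts - params.ts_set)
        return min(params.f_max, f)
    f = 1.0 - params.a_s * (params.ts_set - ts)
    return min(1.0, max(params.f_min, f))


def shivering_heat(tc: float, ts: float, params: ControlParams) -> float:
    """Whole-body shivering thermogenesis, W.

    Zero at thermoneutrality, rises with cold strain up to the cap, and is
    forced to zero when the core temperature drops below 32 °C (shivering
    cessation in deep hypothermia).
    """
    if not params.enabled or tc < SHIVER_CUTOFF_TC:
        return 0.0
    s = params.shiver_scale
    q = s * params.g_core_W * (params.tc_set - tc) + s * params.g_skin_W * (
        params.ts_set - ts
    )
    return min(s * params.q_shiv_max_W, max(0.0, q))


def control_state(tc: float, ts: float, params: ControlParams) -> ControlState:
    """Evaluate both effectors at the current core/skin temperatures."""
    return ControlState(
        perfusion_factor=perfusion_factor(tc, ts, params),
        shivering_W=shivering_heat(tc, ts, params),
    )
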