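"""Closed-form empirical cold-water immersion relations (Hayward).

Regression relations from immersion experiments linking water temperature
Tw (°C, valid for Tw ≤ 23), immersion time ts (min), rectal temperature
TR (°C) and rectal cooling rate C (°C/min):

    C(Tw)       = 0.0785 − 0.0034·Tw
    TR(ts, Tw)  = 37.2 − (ts − 15)·C(Tw)          (ts ≥ 15 min)
    ts(Tw)      = 15 + 7.2 / C(Tw)

with "incipient death" at a rectal temperature of 30.0 °C.  The survival
time is the ts at which TR reaches 30.0 exactly: the 7.2 °C traverse
(37.2 → 30.0) divided by the cooling rate, plus the 15 min lag before the
linear decline begins.  These closed forms are the independent empirical
check on the transient simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "cooling_rate",
    "rectal_temperature",
    "survival_time",
    "HaywardPrediction",
    "predict",
]

# The regressions are quoted for Tw <= 23 °C; the linear cooling rate stays
# non-negative up to its root at 0.0785/0.0034 ~ 23.09 °C, which is accepted
# as the closed-form domain boundary.
TW_MAX = 0.0785 / 0.0034  # °C
T_START = 37.2  # °C, effective empirical starting rectal temperature
T_DEATH = 30.0  # °C, incipient-death rectal temperature
LAG_MIN = 15.0  # min, pre-decline lag


def cooling_rate(tw: float) -> float:
    """Rectal cooling rate C = 0.0785 − 0.0034·Tw, °C/min (Tw ≤ 23)."""
    if tw > TW_MAX:
        raise ValueError(
            f"water temperature {tw} °C outside domain (Tw ≤ 23 °C)"
        )
    return 0.0785 - 0.0034 * tw


def rectal_temperature(ts: float, tw: float) -> float:
    """Rectal temperature after ``ts`` minutes in water at ``tw`` °C.

    ``TR = 37.2 − (ts − 15)·C(Tw)``, valid for ts ≥ 15 min.
    """
    if ts < LAG_MIN:
        raise ValueError(f"immersion time {ts} min outside domain (ts ≥ 15 min)")
    return T_START - (ts - LAG_MIN) * cooling_rate(tw)


def survival_time(tw: float) -> float:
    """Survival time ``ts = 15 + 7.2 / C(Tw)``, min.

    The domain requires a positive cooling rate (Tw < 0.0785/0.0034
    ≈ 23.09 °C).
    """
    c = cooling_rate(tw)
    if c <= 0:
        raise ValueError(
            f"cooling rate non-positive at Tw={tw} °C; survival time undefined"
        )
    return LAG_MIN + (T_START - T_DEATH) / c


@dataclass(frozen=True)
class HaywardPrediction:
    """Bundle of the three closed-form outputs at one water temperature."""

    Tw: float  # °C
    ts: float  # min (survival time, or the supplied immersion time)
    TR: float  # °C
    C: float  # °C/min


def predict(tw: float, ts: float | None = None) -> HaywardPrediction:
    """Evaluate all three relations at ``tw``.

    If ``ts`` is omitted, the survival time is used (so TR = 30.0).
    """
    c = cooling_rate(tw)
    t = survival_time(tw) if ts is None else float(ts)
    return HaywardPrediction(Tw=tw, ts=t, TR=rectal_temperature(t, tw), C=c)
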