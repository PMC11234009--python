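"""One-shot calibration of the shivering scale against the anchor scenario.

The thermoregulation gains and cap carry a single multiplier
(``shiver_scale``) that is fixed once against the anchor condition —
still fresh water at 5 °C, h = 220 W/(m²·°C), survival time 136 min —
by bisection.  Every other scenario in the package is then a prediction.
The resulting value is frozen as the ``ControlParams.shiver_scale``
default; rerun this script after any structural model change.

Usage:  python scripts/calibrate.py [--target 136] [--nr 160] [--dt 1.0]
"""

from __future__ import annotations

import argparse

from coldwater import BioheatModel, build_default_body
from coldwater.control import ControlParams
from coldwater.scenarios import Scenario, run_scenario, survival_time_from_series

ANCHOR = Scenario("fresh_still_5C", "fresh_still", 5.0, t_max_min=400.0)


def survival_at(scale: float, body, nr: int, dt: float) -> float | None:
    model = BioheatModel(body, controls=ControlParams(shiver_scale=scale), nr=nr, dt=dt)
    res = run_scenario(ANCHOR, model=model)
    return survival_time_from_series(res.t_min, res.rectal)


def calibrate(target: float = 136.0, nr: int = 160, dt: float = 1.0,
              tol_min: float = 0.25, verbose: bool = True) -> float:
    body = build_default_body()
    lo, hi = 0.5, 6.0
    mid = 0.5 * (lo + hi)
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        ts = survival_at(mid, body, nr, dt)
        if verbose:
            print(f"  shiver_scale={mid:.4f} -> survival {ts and round(ts, 2)} min")
        if ts is None or ts > target:
            hi = mid
        else:
            lo = mid
        if ts is not None and abs(ts - target) < tol_min:
            break
    return mid


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--target", type=float, default=136.0, help="anchor survival, min")
    ap.add_argument("--nr", type=int, default=160)
    ap.add_argument("--dt", type=float, default=1.0)
    args = ap.parse_args()
    scale = calibrate(args.target, args.nr, args.dt)
    print(f"calibrated shiver_scale = {scale:.4f}")
    print("freeze this value as ControlParams.shiver_scale")
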