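"""Closed-form empirical immersion relations.

Evaluates the linear cooling-rate law and the survival-time and
rectal-temperature relations derived from immersion experiments, across
a few water temperatures.
"""

from coldwater import hayward

print("Tw (°C)   C (°C/min)   survival (min)   TR at survival (°C)")
for tw in (10.0, 5.0, 2.0, 0.0, -2.0):
    p = hayward.predict(tw)
    print(f"{tw:7.1f}   {p.C:10.4f}   {p.ts:14.1f}   {p.TR:19.1f}")

print()
print("After 75 min in 5 °C water the rectal temperature is "
      f"{hayward.rectal_temperature(75, 5.0):.2f} °C.")
print("Survival time is the immersion time at which the rectal trace "
      "reaches the 30.0 °C incipient-death threshold; colder water cools "
      "faster and shortens it.")
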