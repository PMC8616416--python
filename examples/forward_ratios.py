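"""Forward model: how the blue/red excitation ratio encodes PS depth.

Evaluates the closed-form ratio R for the four canonical photosensitizer
depth profiles on the human-dermis preset and prints small depth scans.
R grows from the thin-layer limit R0 toward the thick-layer limit Rinf for
surface profiles, and grows exponentially past Rinf for buried layers --
larger R always means deeper photosensitizer.
"""

import numpy as np

from fluordepth import (
    preset_triple,
    preset_amplitudes,
    ratio_limits,
    ratio_top,
    ratio_exp,
    ratio_bottom,
    ratio_bottom_exp,
)

triple = preset_triple("dermis_table1")
amps = preset_amplitudes("dermis_table1")

r0, rinf = ratio_limits(triple, amps)
print(f"thin-layer limit  R0   = {r0:.4f}")
print(f"thick-layer limit Rinf = {rinf:.4f}")
print(f"buried-layer log-slope = {triple.delta_mu:.3f} /mm\n")

print("uniform surface layer, thickness d (saturates):")
for d in (0.1, 0.25, 0.5, 1.0, 3.0):
    print(f"  d = {d:4.2f} mm -> R = {ratio_top(triple, d, amps):.4f}")

print("\nexponential profile, 1/e depth d_1e (twice the initial slope):")
for d in (0.1, 0.25, 0.5, 1.0, 3.0):
    print(f"  d_1e = {d:4.2f} mm -> R = {ratio_exp(triple, d, amps):.4f}")

print("\nburied uniform layer under a PS-free cover d_b (exponential growth):")
for d in (0.0, 0.15, 0.3, 0.6):
    print(f"  d_b = {d:4.2f} mm -> R = {ratio_bottom(triple, d, amps):.4f}")

print("\nexponential profile (d_1e = 0.3 mm) bleached down by d_b:")
for d in (0.0, 0.1, 0.2):
    print(f"  d_b = {d:4.2f} mm -> R = {ratio_bottom_exp(triple, 0.3, d, amps):.4f}")
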