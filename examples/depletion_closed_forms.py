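"""The prey-depletion model and its closed-form solutions.

The expected prey remaining after a trial solves
dN/dt = -b N / (1 + b h N) P - m N.  With no background mortality the
type II case has the Rogers random-predator closed form via the Lambert W
function; this script shows the agreement between adaptive ODE
integration and the closed form, and the two exponential limits.
"""

import numpy as np

from copefr.fr_fit import FRParameters, predict_remaining, rogers_remaining

b, h, T = 1.0, 0.5, 6.0
print("N0   ODE remaining   Rogers (Lambert-W)   rel. difference")
for N0 in (1, 2, 4, 8, 16, 24, 32):
    ode = predict_remaining(N0, FRParameters(b=b, h=h), 1, T)
    rog = rogers_remaining(N0, b, h, 1, T)
    print(f"{N0:3d}   {ode:12.6f}   {rog:17.6f}   {abs(ode - rog) / rog:.2e}")

print("\nlimits:")
m = 0.05
no_attack = predict_remaining(32, FRParameters(b=0.0, h=h, m=m), 1, T)
print(
    f"  b = 0:  N(T) = {no_attack:.4f}  vs  N0 exp(-mT) = {32 * np.exp(-m * T):.4f}"
)
no_handling = predict_remaining(32, FRParameters(b=0.3, h=0.0), 1, T)
print(
    f"  h = 0:  N(T) = {no_handling:.4f}  vs  N0 exp(-bPT) = {32 * np.exp(-0.3 * T):.4f}"
)
print(
    "\nAt a starting density of 32 larvae the predator eats about a third in\n"
    "6 h because handling time caps the feeding rate at 1/h = 2 larvae/h."
)
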