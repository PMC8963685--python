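"""The treatment confounding bridge in the binary world.

For binary confounder U and binary negative control exposure Z, the bridge
q(a, z) solves a 2x2 linear system in the cell probabilities
P(Z=z, A=a | U=u) and satisfies E[q(a, Z) | A=a, U=u] * P(A=a | U=u) = 1
exactly — it reproduces inverse treatment probabilities without ever
observing U.
"""

import numpy as np

import tndbridge as tb

config = tb.binary_rare()
model = tb.oracle_bridge_binary(config)
table = tb.bridge_table(model)
print("bridge values q[a, z]:")
print(np.round(table, 4))

print("\ndefining identity E[q(a,Z)|A=a,U=u] * P(A=a|U=u):")
for u in (0, 1):
    for a in (0, 1):
        pa = config.p_a_given_u[u] if a else 1 - config.p_a_given_u[u]
        pz1 = config.p_z_given_au[a][u]
        e_q = (1 - pz1) * table[a, 0] + pz1 * table[a, 1]
        print(f"  u={u} a={a}: {e_q * pa:.12f}   (1/P(A={a}|U={u}) = {1/pa:.3f})")

# the same construction applied to *observed* control cell frequencies is
# how the bridge is estimated in practice
pop = tb.simulate_binary_population(config, seed=3)
sample = tb.select_tnd_sample(pop)
cells = tb.CellProbabilities.from_controls(sample)
q0 = tb.closed_form_binary_bridge(cells, 0)
q1 = tb.closed_form_binary_bridge(cells, 1)
print("\ncontrol-estimated bridge (rare-outcome approximation):")
print(np.round([q0, q1], 4))
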