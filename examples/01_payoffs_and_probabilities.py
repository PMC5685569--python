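"""Payoff arithmetic and the Fermi rule on hand-checkable groups.

Builds a few tiny groups, evaluates the homogeneity payoff pi_g and the
formation/breaking probabilities, and prints what each number means.
"""

import numpy as np

from spingroups import (EXAMPLE_VECTOR, breaking_probability,
                        formation_probability, group_payoff)

pair_same = np.tile(EXAMPLE_VECTOR, (2, 1))
pair_mixed = np.array([[1, -1, -1, -1, 1, 1],
                       [1, 1, 1, -1, 1, 1]])
pair_opposed = np.array([[1, 1], [-1, -1]])

print("pi_g, identical pair      :", group_payoff(pair_same))
print("pi_g, 3-of-6 columns agree:", round(group_payoff(pair_mixed), 4))
print("pi_g, perfectly opposed   :", group_payoff(pair_opposed))
print()
print("pi_g = 1 is a perfectly homogeneous group, 0 a perfectly balanced")
print("one; the mixed pair agrees on 4 of 6 features minus the 2 that")
print("cancel, giving 2/3.")
print()

K = 0.5
for pi_i in (-1.0, 0.0, 0.5, 1.0):
    w = formation_probability(pi_i, 1.0, K)
    b = breaking_probability(pi_i, 1.0, K)
    print(f"pi_i={pi_i:+.1f} vs pi_g=1.0:  form {w:.3f}   break {b:.3f}")
print()
print("With K=0.5 agents are nearly rational: a homogeneous group forms")
print("almost surely when acting alone is risky (pi_i=-1) and survives")
print("only half the breaking draws when acting alone pays just as much.")
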