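"""Exhaustive 2^N fixation probabilities, including a non-fixating example.

For hypergraphs with up to 14 nodes the full transition kernel over all
2^N type configurations can be built and solved exactly.  Under the
majority-rule update (model 2) some configurations can never reach
unanimity: on the 6-node, 4-triangle hypergraph below, two mutants placed
on the private pair of one triangle leave two nodes toggling forever.
"""

from hyperfix import Hypergraph, brute_force_fixation, brute_force_vector

# single triangle: whoever reproduces first converts the other two
H3 = Hypergraph(3, ((0, 1, 2),))
for r in (0.5, 1.0, 3.0):
    x = brute_force_fixation(H3, 1, r, mutants={0})
    print(f"triangle, model 1, r={r}: x = {x:.6f}  (expected r/(r+2) = {r/(r+2):.6f})")

print()
H6 = Hypergraph(6, ((0, 1, 2), (2, 3, 4), (3, 4, 5), (0, 1, 5)))
s = (1 << 0) | (1 << 1)  # mutants on nodes 0 and 1
xA = brute_force_vector(H6, 2, 1.5)[s]
xB = brute_force_vector(H6, 2, 1 / 1.5)[((1 << 6) - 1) ^ s]
print("6-node example, model 2, mutants on {0, 1}:")
print(f"  probability of mutant fixation:   {xA}")
print(f"  probability of resident fixation: {xB}")
print("Both are exactly zero: the dynamics is trapped in a cycling class,")
print("so neither type ever occupies all six nodes.")
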