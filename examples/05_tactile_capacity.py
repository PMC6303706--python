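"""Combinatorial tactile capacity of a mechanoreceptor array.

Each sensillum is innervated by one neuron and (in the simplest model) is
either contacted or not, so n sensilla can encode 2^n contact patterns.
One extra sensillum doubles the number of distinguishable patterns.
"""

from platemorph import tactile_pattern_capacity

for n in (25, 26, 28, 49):
    exact, sci = tactile_pattern_capacity(n)
    print(f"n = {n:2d} sensilla -> {exact:>20,d} patterns ({sci})")

print()
print("ratio between consecutive ns is exactly the number of states (2):")
print(tactile_pattern_capacity(26)[0] // tactile_pattern_capacity(25)[0])
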