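"""Decompose 8-bit intensities into their unique Fibonacci term sets.

Builds the 12-element Fibonacci basis for 8-bit images, decomposes a few
intensities, and contrasts the unique non-adjacent representation with
the many other Fibonacci subset sums of the same integer.
"""

from zeckpool import enumerate_representations, fibonacci_basis, zeckendorf

basis = fibonacci_basis(255)
print(f"8-bit Fibonacci basis ({len(basis)} values): {basis.values}")

for n in (255, 183, 106, 42):
    d = zeckendorf(n, basis)
    print(f"  {n:3d} = {' + '.join(map(str, d.terms))}")

reps = enumerate_representations(255, basis)
print(f"\n255 has {len(reps)} Fibonacci subset-sum representations in total,")
print("but exactly one (233, 21, 1) uses no two consecutive Fibonacci numbers")
print("and it is also the shortest — that sparsity is what the image coding exploits.")
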