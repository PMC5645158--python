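"""Exact expansion of the inhibition term in higher-order activity products.

For N=5, theta=3/5 the reference-measure exponent N*G(sbar - theta) equals
the sum of all five 4-tuple products minus three times the 5-tuple product.
"""

from popmaxent import expansion_coefficients, pascal_matrices

P, Pinv = pascal_matrices(5)
print("Pascal matrix row K=1:", P[1].tolist())
print("inverse row S=1:      ", Pinv[1].tolist())

table = expansion_coefficients(5, 3)
print("coefficients f_K for Theta=3:", [int(x) for x in table.f])
print("so N*G = (sum of 4-tuple products) - 3*(5-tuple product)")
print("The coefficients are generalized binomial coefficients with "
      "alternating signs; a hard activity threshold is a very high-order "
      "interaction, not a small correction to the pairwise model.")
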