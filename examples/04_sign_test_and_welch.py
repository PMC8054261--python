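"""Nonparametric and parametric two-group comparisons.

The exact sign test asks only whether paired growth-rate differences
share a direction across ordered oxygen levels — insensitive to
between-experiment scale. The Welch t-test compares two groups without
assuming equal variances.
"""

from ecmscreen import sign_test_two_sided, welch_t_test

# eight independent comparisons, all showing lower growth at lower O2
deltas = [-0.004, -0.007, -0.002, -0.009, -0.001, -0.006, -0.003, -0.005]
res = sign_test_two_sided(deltas)
print(f"sign test: n = {res.n}, k = {res.k} positive, p = {res.p_two_sided:.7f}"
      f" (printed as {res.p_two_sided:.3f})")
print("With all 8 pairs in one direction, p = 2*(1/2)^8 — strong evidence of a")
print("monotone oxygen effect without using the magnitudes at all.\n")

on_disc = [0.031, 0.028, 0.033, 0.030, 0.029]
monolayer = [0.024, 0.022, 0.026, 0.023, 0.025]
w = welch_t_test(on_disc, monolayer)
print(f"Welch t-test: t = {w.t:.3f}, df = {w.df:.2f}, p = {w.p_two_sided:.5f}")
print("A two-sided test of equal means with unequal-variance degrees of freedom.")
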