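"""Plan group sizes from a fold change and a coefficient of variation.

The minimum animals per group for a two-sided two-sample t-test
(alpha = 0.05, power = 0.8) depends only on the fold change k = mu1/mu0 you
want to detect and the control group's CV, through the effect size
Delta = (k - 1) / CV.
"""

from phenovar import PowerQuery, effect_size, generate_sample_size_table, sample_size, t_test_power

# A treatment expected to raise blood glucose by 20% (k = 1.2) in a strain
# whose glucose CV is about 0.15:
q = PowerQuery(k=1.2, cv=0.15)
n = sample_size(q)
print(f"k={q.k}, CV={q.cv}: effect size Delta = {effect_size(q.k, q.cv):.3f}")
print(f"  -> {n} animals per group "
      f"(power at n: {t_test_power(n, effect_size(q.k, q.cv)):.3f}, "
      f"at n-1: {t_test_power(n - 1, effect_size(q.k, q.cv)):.3f})")

# A 20% decrease costs exactly as many animals as a 20% increase:
print(f"k=0.8 gives the same n: {sample_size(PowerQuery(k=0.8, cv=0.15))}")

# A slice of the full planning grid (rows = CV, columns = k):
table = generate_sample_size_table(k_grid=[1.1, 1.2, 1.5, 2.0],
                                   cv_grid=[0.05, 0.15, 0.30, 0.60])
print("\nPer-group sample sizes:")
print(table.to_dataframe().to_string(index=False))
# Reading: a highly variable behavioral endpoint (CV 0.6) needs 567 animals
# per group to certify a 10% difference, but only 7 for a doubling.
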