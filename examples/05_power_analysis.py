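"""Minimal detectable differences for paired t-tests under Bonferroni.

Solves, with the exact noncentral-t distribution, for the smallest true
mean paired difference detectable at 80% power and two-sided family level
0.05, for the muscle (11 pairs) and adipose (5 pairs) designs and for
single-test, candidate-family (136) and genome-wide (26,850) corrections —
assuming a paired-difference SD of 5 percentage points.
"""

import twinmeth as tm

table = tm.power_table(pair_counts=(11, 5), sd=5.0, families=(1, 136, 26_850))
print("n_pairs  m_tests  MDD (points)  rounded")
for row in table.itertuples():
    print(f"{row.n_pairs:7d}  {row.m_tests:7d}  {row.mdd:12.2f}  {row.mdd_rounded:7d}")
# With 11 pairs a 5-point shift is detectable in a single test, but the
# genome-wide correction pushes the detectable effect to 17 points; with
# only 5 adipose pairs the genome-wide design is essentially powerless.

est = tm.simulate_power(n_pairs=11, sd=5.0, delta=5.0, reps=10_000, seed=5)
exact = tm.paired_t_power(5.0, 11, 5.0, 0.05)
print(f"\nMonte-Carlo power at delta=5, n=11, SD=5: {est:.3f} "
      f"(exact noncentral-t: {exact:.3f})")
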