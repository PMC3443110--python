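"""Why tiny microarray designs need enumeration-exact rank tests.

With 3 or 4 arrays per group the exact Mann-Whitney null distribution has
only a handful of achievable p-values. This script prints the extreme end
of that support for the two designs used in a two-age knockout study.
"""

from rankde import exact_rank_sum, kth_smallest_p, min_achievable_p

print("3 vs 3 design (C(6,3) = 20 assignments)")
print(f"  minimum achievable two-tailed p : {min_achievable_p(3, 3):.4f}")
print(f"  second-most-extreme level       : {kth_smallest_p(3, 3, 2):.4f}")

print("4 vs 4 design (C(8,4) = 70 assignments)")
print(f"  minimum achievable two-tailed p : {min_achievable_p(4, 4):.4f}")
print(f"  second-most-extreme level       : {kth_smallest_p(4, 4, 2):.4f}")

res = exact_rank_sum([50, 55, 60], [400, 420, 440])
print(f"completely separated 3v3 data -> U = {res.U}, p = {res.p_two_tailed}")

# The 4v4 second level, 4/70 = 0.0571, is where a printed cutoff of 0.057
# comes from: it admits exactly the two most extreme orderings. A 3v3
# design can never reach it, hence the fallback to its own floor of 0.1.
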