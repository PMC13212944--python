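"""Map a slice of the stability region of distributed-delay model I.

Scans the kernel rate a at alpha1 = 0.97, rho = 4.5 and bisects the
stable/unstable boundary, which the min-|arg| test places just above
a = 4.5 (the delay-kernel must decay faster than this for the growth rate
rho = 4.5 to be contained).
"""

import numpy as np

from fracstab import bisect_boundary_in_a, region_scan

grid = region_scan(
    "I", ("rho", "a"),
    axis1_values=np.array([4.5]),
    axis2_values=np.array([4.2, 4.4, 4.6, 4.8, 5.0, 6.0]),
    fixed={"alpha1": 0.97},
)
for a, verdict, imfos in zip(grid.axis2_values, grid.verdict[0], grid.imfos[0]):
    print(f"a = {a:4.1f}: {verdict:9s} (instability measure {imfos:+.2e})")

a_star = bisect_boundary_in_a("I", alpha1=0.97, rho=4.5, a_lo=4.5, a_hi=4.6)
print(f"\nbisected boundary: a* = {a_star:.4f}")
print("Nodes left of a* feed back too slowly and destabilize; right of a*")
print("the equilibrium (a^2, a) is asymptotically stable.")
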