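"""Branch structure of the triose-phosphate-limited curve Ap.

With α = 0 (all photorespiratory glycerate returned to the chloroplast) the
A/Ci form of Ap degenerates into its two asymptotes; with α > 0 it is a
genuine left/right-opening hyperbola with an interior Ci interval where no
real rate exists.  The usable branch for fitting is the negative root of the
branch opening right, which *decreases* with Ci when α > 0 — the only way
the model can bend downward at high CO2, yet its asymptote stays horizontal.
"""

import numpy as np

from fvcbgeom import Frame, FvCBParams, rate_in_frame, valid_domain

base = dict(Vcmax=1e6, J=4e6, Tp=12.0, Rd=2.0, Kco=62.1, Gamma_star=3.74, rm=0.4)

for alpha in (0.0, 0.1):
    p = FvCBParams(**base, alpha=alpha)
    dom = valid_domain("p", p, Frame.CI)
    print(f"alpha = {alpha}:")
    print(f"  valid Ci domain starts at {dom.lower:.3f} Pa")
    if dom.excluded is None:
        print("  no excluded interval (degenerate hyperbola: asymptote pair)")
    else:
        lo, hi = dom.excluded
        print(f"  no real Ap on Ci ∈ ({lo:.3f}, {hi:.3f}) Pa")
    for ci in (50.0, 100.0, 300.0, 1000.0):
        a = rate_in_frame("p", p, Frame.CI, ci)
        print(f"  Ap(Ci = {ci:6.0f} Pa) = {'no real value' if a is None else f'{a:.4f}'}")
    print()

print("For alpha = 0.1 the rate decreases toward its horizontal asymptote")
print(f"3·Tp − Rd = {3 * 12.0 - 2.0:.0f} µmol m⁻² s⁻¹ from above as Ci grows.")
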