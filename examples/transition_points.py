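"""Transition points between limitation states in the three CO2 frames.

For a typical C3 parameter set, prints the common (fourth-quadrant) point
and the first-quadrant transition of each state pair in the A/Cc, A/Ci and
A/Ca frames, followed by the limiting-condition report.  The A coordinates
are identical across frames — resistances shift only the CO2 axis — which
is why the critical parameter ratios (J = 4·Vcmax, J = 12·Tp, Vcmax = 3·Tp)
do not depend on gm or gs.
"""

from fvcbgeom import Frame, FvCBParams, all_transitions, limiting_conditions

params = FvCBParams(
    Vcmax=100.0, J=150.0, Tp=12.0, Rd=2.0,
    Kco=62.1, Gamma_star=3.74, rm=0.45, rs=0.4,
)

for frame in (Frame.CC, Frame.CI, Frame.CA):
    print(f"frame {frame.value}:")
    for pair, (pt1, pt2) in all_transitions(params, frame).items():
        tag2 = (
            f"C = {pt2.C:8.3f} Pa  A = {pt2.A:7.3f}  on min-curve: {pt2.on_min_curve}"
            if pt2.finite else "divergent (no first-quadrant transition)"
        )
        print(f"  {pair}:  common point C = {pt1.C:6.3f} Pa, A = {pt1.A:.3f}   | "
              f"first-quadrant {tag2}")
    print()

rep = limiting_conditions(params)
print("limiting-condition report:")
print(f"  J/(4·Vcmax) = {rep.ratio_cj:.4f}   J/(12·Tp) = {rep.ratio_jp:.4f}   "
      f"Vcmax/(3·Tp) = {rep.ratio_cp:.4f}")
print(f"  first-quadrant transitions on the operative curve: {rep.n_first_quadrant}")
print(f"  operative sequence: {' → '.join(s.value for s in rep.operative_sequence)}")
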