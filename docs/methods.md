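# Methods

## Model

Net CO2 assimilation of a C3 leaf at steady state is the minimum of three
limitation-state rates.  Internally every state is held in the uniform
chloroplast-frame form

    A = V·(C_c − Γ*)/(C_c + d) − R_d

with (V, d) = (Vcmax, K_co) for the Rubisco state c, (J/4, 2Γ*) for the
RuBP-regeneration state j, and (3T_p, −(1+3α)Γ*) for the
triose-phosphate-utilisation state p.  The pole sits at C_c = −d, the
horizontal asymptote at A = V − R_d, and every state passes through
(Γ*, −R_d) — except state p with α = 0, for which that point coincides with
the pole and the curve degenerates to the constant 3T_p − R_d.

Measurement frames are linked by the Fick's-law supply line C_c = C − r·A
with r the total diffusional resistance of the frame: 0 (chloroplastic),
r_m (intercellular), r_m + r_s (atmospheric).  The stomatal resistance is
composed serially with the mesophyll resistance; this is an interpretation —
the gas-phase/liquid-phase distinction is not modelled.  Substitution and
clearing of denominators gives the quadratic

    r·A² − (C + d + r·(V − R_d))·A + (V − R_d)·C − R_d·d − V·Γ* = 0.

**Sign convention.**  The A² coefficient is stored as a2 = r > 0, so the
operative branch is always the "negative root" (−a1 − √disc)/(2a2).  With
this convention −a1/a2 equals, at every C, the sum of the two asymptote
values — the observation that the middle coefficient of the quadratic is the
summation of the asymptotes.

**State-p branch structure.**  The discriminant of the state-p quadratic is
negative exactly on

    C ∈ ( r·(3T_p − R_d) + (1+3α)Γ* ± 2·√(3α·Γ*·r·3T_p) ),

derived in closed form; the interval is empty iff α = 0.  The usable branch
for the operative curve and for fitting is the negative root of the branch
opening right (C at or beyond the interval's upper edge; the centre C in the
degenerate α = 0 case).  The left-opening branch is excluded from the
operative minimum: the vectorised min-curve (`net_rate_curve`) masks state p
below that edge, while the scalar `net_rate` reports the minimum over all
states with a real rate, which is the literal min-of-three definition.  The
two agree wherever α = 0 or the curve is sampled in its physical range.

## Conic geometry

Each curve is the implicit conic cxy·C·A + cyy·A² + cx·C + cy·A + c0 = 0 —
there is never a C² term, and cyy = r vanishes in the chloroplast frame.
The anticlockwise rotation eliminating the cross term is
β = ½·atan2(cxy, cxx − cyy) normalised into (0, π/2); for this model
tan 2β = 1/r, hence β ∈ (0, π/4] and β = 45° exactly when r = 0.  The
"zero-sum" check reassembles the C² coefficient from the rotated
standard-form coefficients (axx·cos²β + ayy·sin²β) and verifies it vanishes;
this is why no admissible parameter combination can tilt a horizontal
asymptote negative.

Geometry is computed twice, deliberately:

1. closed forms — oblique asymptote A = (C + d)/r, horizontal A = V − R_d,
   centre (r·(V − R_d) − d, V − R_d), bisector slopes −(r + √(1+r²)) for the
   up/down-opening states c and j and −r + √(1+r²) for the left/right-opening
   state p;
2. numerically from the conic alone — asymptote directions from the roots of
   cyy·m² + cxy·m + cxx = 0, centre from the vanishing gradient, bisector
   from unit-vector angle bisectors, the branch-containing one selected by
   the sign test Q(u)·f(centre) < 0 (with a state-based fallback for the
   degenerate α = 0 state-p line pair).

The test suite requires the two routes to agree to 1e−9.  Vertical
asymptotes (chloroplast frame) are a tagged variant, never an infinite
float.

## Transition points

Index-1 (common) point: (Γ* − r·R_d, −R_d) in every frame and for every
pair; it moves to the third quadrant when R_d·r > Γ*.  Index-2
(first-quadrant) points use the closed forms given in
`fvcbgeom/transitions.py`; frame conversion shifts C by r·A and leaves A
unchanged, so transition rates are invariant to r_m and r_s.  A denominator
smaller than 1e−9 times the numerator scale marks the point divergent
(finite = False with NaN coordinates) — divergence is data, not an error.
The cp closed form uses the factor (1+3α) required by the A_p pole position,
matching the jp pair and verified against an independent root-bracketing
oracle.

The jp and cp coincidence conditions would require T_p < 0 and are reported
only as non-biochemical flags.  `on_min_curve` requires both that the point
lies on the operative minimum and, for pairs involving p, that it sits on
the usable right-opening branch; the jp/cp common points always fail the
branch test.

Limiting-condition classification counts first-quadrant transitions by
scanning the operative min-curve on a 2001-point grid from just above the
domain bound to three times the largest finite transition C (at least
200 Pa) and refining each boundary with Brent's method; the count and the
operative state sequence are invariant to r_m by construction and by test.

## Fitting

The objective is unweighted SSE of the min-of-three negative-root model —
the model's own min operator assigns per-point states, so the transition C
is never constrained.  `scipy.optimize.least_squares` (trust-region
reflective, box bounds: positive rates, α ∈ [0, 1]) is run from a
deterministic multistart (factors 1.0, 0.7, 1.4, 0.85, 1.2 applied to the
heuristic start); the best SSE wins.  Starting values come from the model's
asymptote structure: the plateau seeds J = 4·(plateau + R_d) and
T_p = (plateau + R_d)/3, the low-C points seed Vcmax through the
quasi-rectangular form, and the curve minimum seeds R_d.  Identifiability
flags report free capacity parameters whose state is never the *strict*
minimum at any data point (a single boundary tie carries no information),
and a warning fires below 3 points per free parameter.

## Synthetic data

`generate_curve` evaluates the operative min-curve on a user grid and adds
i.i.d. Gaussian noise (seeded).  Default study conditions used by the tests:
the worked parameter set Vcmax = 100, J = 150, T_p = 12, R_d = 2,
K_co = 62.1 Pa, Γ* = 3.74 Pa, r_m = 0.45, r_s = 0.4 (typical C3 values),
grids of 30–40 points spanning 4–400 Pa, and noise sd 0.5 µmol m⁻² s⁻¹ —
about the repeatability of a modern gas analyser.  The generator emulates
ideal steady-state data: no drift, no leak artefacts, no C_i-dependent g_m,
no inhibition at supraoptimal CO2 (the model itself cannot produce a
negative terminal slope), and homoscedastic noise.  Passing recovery tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to the ways real leaves violate them.

Monte-Carlo recovery (100 seeds, 30 points, sd 0.5, single-start fits)
requires the median relative Vcmax error below 5%; the noiseless-recovery
test requires all free parameters within 0.1%.

## Numerical choices

- Pole detection: |denominator| < 1e−12 × scale raises a pole error naming
  the state and location.
- Discriminants in (−1e−10 × scale, 0) are clamped to zero (float safety at
  branch points); more negative values are a typed no-real-solution marker.
- Tie-breaking in the min rule: alphabetically first state plus an explicit
  tie flag (relative tolerance 1e−9).
- Quadrant labels: zeros on an axis are assigned to the non-negative side
  with an `on_boundary` flag.
- K_co may be given directly or derived as K_c·(1 + O/K_o); the constraint
  K_co > 2Γ* is validated as a warning, not an error.
- Defaults: α = 0, r_s = 0; angles are radians internally, degrees in JSON
  reports.

## Limitations

Temperature dependence of the kinetic constants, the light response of J,
C4/bicarbonate-pump variants, nitrogen-assimilation extensions of α,
flux-weighted or CO2-dependent g_m, and fluorescence-based g_m estimation
are all out of scope.  J and T_p are taken as given capacities.  The package
analyses and fits the steady-state model only; it cannot represent the
experimentally observed decline of A at supraoptimal CO2 — indeed one of its
main analytic results is that no parameterisation of this model can.
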