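# fvcbgeom

Geometry, transition-point analysis and curve fitting for the steady-state
Farquhar–von Caemmerer–Berry (FvCB) model of C3 leaf photosynthesis.

## The problem

Plant physiologists estimate photosynthetic capacities from gas-exchange
response curves: net CO2 assimilation *A* (µmol m⁻² s⁻¹) measured against a
CO2 concentration *C* (Pa).  In the FvCB model *A* proceeds at the minimum
of three limitation-state rates,

    A = min{A_c, A_j, A_p},

where each state is a rectangular hyperbola in the chloroplastic CO2
concentration C_c:

    A_c = Vcmax·(C_c − Γ*)/(C_c + K_co) − R_d          (Rubisco-limited)
    A_j = J·(C_c − Γ*)/(4·C_c + 8·Γ*) − R_d            (RuBP-regeneration-limited)
    A_p = 3·T_p·(C_c − Γ*)/(C_c − (1+3α)·Γ*) − R_d     (triose-phosphate-limited)

Measurements, however, are made against the intercellular (C_i) or
atmospheric (C_a) concentration.  Substituting the Fick's-law supply line
C_c = C − r·A (r = r_m for C_i; r = r_m + r_s for C_a) turns each rate into a
quadratic in *A* — a **non-rectangular hyperbola** whose shape carries the
mesophyll conductance g_m = 1/r_m.

`fvcbgeom` treats these curves as what they are: conic sections.  It
computes, exactly and numerically,

- **asymptotes, centres, bisecting lines** of every limitation-state curve in
  every frame — all three oblique asymptotes share slope g_m, and the
  rotation angle β = ½·arctan(g_m) that removes the cross term is 45° in the
  rectangular limit;
- **transition points** between limitation states: the common point
  (Γ* − r·R_d, −R_d) and the first-quadrant transitions, in closed form, with
  divergence handled as data;
- **limiting conditions**: the critical ratios J = 4·Vcmax, J = 12·T_p and
  Vcmax = 3·T_p at which first-quadrant transitions escape to infinity —
  independent of g_m and g_s;
- **validity domains**, including the C_i interval with no real A_p when
  α > 0;
- **simulation and fitting** of A/C_i curves by bounded least squares on the
  min-of-three model, with the transition C free (never constrained) and
  identifiability diagnostics.

Units are fixed: Pa for CO2, µmol m⁻² s⁻¹ for rates, Pa µmol⁻¹ m² s for
resistances.

## Worked example

```python
from fvcbgeom import FvCBParams, Frame, geometry, transition_in_frame

params = FvCBParams(Vcmax=100, J=150, Tp=12, Rd=2,
                    Kco=62.1, Gamma_star=3.74, rm=0.45, rs=0.4)

g = geometry("c", params, Frame.CI)
print(g.asymptote_1.slope, g.asymptote_2.intercept, g.centre)
# 2.2222  98.0  (-18.0, 98.0)

pt1, pt2 = transition_in_frame("cj", params, Frame.CI)
print(pt1.C, pt1.A, pt2.C, pt2.A)
# 2.84  -2.0  35.49  22.661
```

The Rubisco curve's oblique asymptote has slope 1/r_m = 2.22, its horizontal
asymptote sits at Vcmax − R_d = 98, and the centre at
((Vcmax − R_d)·r_m − K_co, Vcmax − R_d) = (−18, 98).  The c→j limitation
switch occurs at C_i ≈ 35.5 Pa with A ≈ 22.66 µmol m⁻² s⁻¹; the common point
(2.84, −2) is the image of (Γ*, −R_d) under the supply line.  Transition
*rates* never depend on the resistances — only the C coordinates shift.

The `examples/` directory holds narrative scripts, one per capability
(`geometry_report.py`, `transition_points.py`, `simulate_and_fit.py`,
`tpu_branches.py`); each prints the numbers it computes with an explanation.

## Command line

```sh
fvcbgeom simulate   --params leaf.json --frame ci --noise 0.5 --seed 1 --out curve.csv
fvcbgeom analyze    --params leaf.json --frame ci
fvcbgeom transitions --params leaf.json --frame ci
fvcbgeom fit curve.csv --config config.json --out fit.json
```

Parameter files are flat JSON/YAML with keys matching the `FvCBParams`
fields; curve tables are CSV with columns `C_Pa`, `A_umol_m2_s`.

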