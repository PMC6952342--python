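"""Conic-section geometry of the FvCB rate curves.

Each limitation-state curve, in any frame, is an implicit second-degree conic

    cxx·C² + cxy·C·A + cyy·A² + cx·C + cy·A + c0 = 0

with cxx = 0 — the model produces no C² term, which is precisely why its
horizontal asymptotes can never acquire a negative slope.  In the chloroplast
frame cyy = 0 as well (rectangular hyperbola, pure cross term); in the
resistive frames cyy equals the total diffusional resistance r, giving a
non-rectangular hyperbola whose oblique asymptote has slope 1/r = gm (or the
series conductance for the atmospheric frame).

An anticlockwise rotation of the axes by β = ½·arctan(cxy/(cxx − cyy))
eliminates the cross term; for this model tan 2β = 1/r, so β lies in
(0, π/4], reaching 45° exactly in the rectangular limit r → 0.

The closed-form geometry (asymptotes, centre, bisecting line) is hard-coded
from the model's algebra AND recomputed numerically from the conic
coefficients; the test suite compares the two routes — a double-entry check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import NotAHyperbolaError
from .model import quadratic_in_frame
from .params import Frame, FvCBParams, LimitationState, state_hyperbola_constants

__all__ = [
    "ConicCoefficients",
    "Line",
    "HyperbolaGeometry",
    "implicit_conic",
    "rotation_angle",
    "rotate_conic",
    "zero_sum_residual",
    "geometry",
    "geometry_from_conic",
]


@dataclass(frozen=True)
class ConicCoefficients:
    """Implicit form cxx·C² + cxy·C·A + cyy·A² + cx·C + cy·A + c0 = 0."""

    cxx: float
    cxy: float
    cyy: float
    cx: float
    cy: float
    c0: float

    def quadratic_discriminant(self) -> float:
        """cxy² − 4·cxx·cyy; positive for a hyperbola."""
        return self.cxy * self.cxy - 4.0 * self.cxx * self.cyy

    def evaluate(self, C: float, A: float) -> float:
        return (
            self.cxx * C * C
            + self.cxy * C * A
            + self.cyy * A * A
            + self.cx * C
            + self.cy * A
            + self.c0
        )


@dataclass(frozen=True)
class Line:
    """A line in the (C, A) plane; vertical lines carry a C-intercept instead.

    For non-vertical lines: A = slope·C + intercept.  A vertical line is
    tagged (slope is None) and ``intercept`` holds its C position in Pa.
    """

    slope: Optional[float]
    intercept: float

    @property
    def vertical(self) -> bool:
        return self.slope is None

    def value(self, C: float) -> float:
        if self.vertical:
            raise ValueError("a vertical line has no value A(C)")
        return self.slope * C + self.intercept

    def to_dict(self) -> dict:
        if self.vertical:
            return {"type": "vertical", "C": self.intercept}
        return {"type": "line", "slope": self.slope, "intercept": self.intercept}


@dataclass(frozen=True)
class HyperbolaGeometry:
    """Asymptotes, centre, bisecting line and rotation angle of one curve."""

    state: LimitationState
    frame: Frame
    asymptote_1: Line  #: oblique (resistive frames) or vertical (chloroplast)
    asymptote_2: Line  #: horizontal
    centre: tuple[float, float]
    bisecting_line: Line
    beta: float  #: anticlockwise rotation to standard form, radians, in (0, π/2)

    def to_dict(self) -> dict:
        return {
            "state": self.state.value,
            "frame": self.frame.value,
            "asymptote_1": self.asymptote_1.to_dict(),
            "asymptote_2": self.asymptote_2.to_dict(),
            "centre": {"C": self.centre[0], "A": self.centre[1]},
            "bisecting_line": self.bisecting_line.to_dict(),
            "beta_degrees": math.degrees(self.beta),
        }


def implicit_conic(
    state: LimitationState, params: FvCBParams, frame: Frame
) -> ConicCoefficients:
    """Bivariate implicit form of one state's curve in one frame.

    Rearranges the frame quadratic a2·A² + a1(C)·A + a0(C) = 0, whose
    coefficients are affine in C, into conic coefficients.  cxx = 0 always;
    cyy = 0 too in the chloroplast frame.
    """
    q0 = quadratic_in_frame(state, params, Frame(frame), 0.0)
    q1 = quadratic_in_frame(state, params, Frame(frame), 1.0)
    # a1(C) = cxy·C + cy ; a0(C) = cx·C + c0
    return ConicCoefficients(
        cxx=0.0,
        cxy=q1.a1 - q0.a1,
        cyy=q0.a2,
        cx=q1.a0 - q0.a0,
        cy=q0.a1,
        c0=q0.a0,
    )


def rotation_angle(conic: ConicCoefficients) -> float:
    """Anticlockwise rotation β eliminating the cross term, in (0, π/2).

    tan 2β = cxy/(cxx − cyy); the result is normalised into (0, π/2), where
    it is unique.  Rejects conics whose quadratic part is not hyperbolic.
    """
    if conic.quadratic_discriminant() <= 0.0:
        raise NotAHyperbolaError(
            "quadratic part is not hyperbolic (ellipse/parabola rejected)"
        )
    if conic.cxy == 0.0:
        raise NotAHyperbolaError("conic already in standard form (no cross term)")
    beta = 0.5 * math.atan2(conic.cxy, conic.cxx - conic.cyy)
    while beta <= 0.0:
        beta += 0.5 * math.pi
    while beta >= 0.5 * math.pi:
        beta -= 0.5 * math.pi
    return beta


def rotate_conic(conic: ConicCoefficients, beta: float) -> ConicCoefficients:
    """Conic coefficients after rotating the axes anticlockwise by beta."""
    c, s = math.cos(beta), math.sin(beta)
    return ConicCoefficients(
        cxx=conic.cxx * c * c + conic.cxy * c * s + conic.cyy * s * s,
        cxy=2.0 * (conic.cyy - conic.cxx) * c * s + conic.cxy * (c * c - s * s),
        cyy=conic.cxx * s * s - conic.cxy * c * s + conic.cyy * c * c,
        cx=conic.cx * c + conic.cy * s,
        cy=-conic.cx * s + conic.cy * c,
        c0=conic.c0,
    )


def zero_sum_residual(conic: ConicCoefficients) -> float:
    """Reassembled C² coefficient after rotation to standard form.

    Rotating by β gives squared-coordinate coefficients (axx, ayy); mapping
    them back onto the original C axis gives axx·cos²β + ayy·sin²β, the
    "summation of the coefficients of C²" that vanishes identically for
    every curve of this model.
    """
    beta = rotation_angle(conic)
    rot = rotate_conic(conic, beta)
    c, s = math.cos(beta), math.sin(beta)
    return rot.cxx * c * c + rot.cyy * s * s


_BISECTOR_SIGN = {
    LimitationState.c: -1,  # branches open up/down: negative-slope bisector
    LimitationState.j: -1,
    LimitationState.p: +1,  # branches open left/right: positive-slope bisector
}


def geometry(
    state: LimitationState, params: FvCBParams, frame: Frame
) -> HyperbolaGeometry:
    """Closed-form geometry of one state's curve in one frame.

    Chloroplast frame: vertical asymptote at C = −d, horizontal at
    A = V − Rd, centre (−d, V − Rd), bisector slope ∓1, β = 45°.
    Resistive frames: oblique asymptote A = (C + d)/r, horizontal
    A = V − Rd, centre (r·(V − Rd) − d, V − Rd), bisector slopes
    −(r + √(1+r²)) for states c and j, −r + √(1+r²) for state p,
    β = ½·arctan(1/r).
    """
    state = LimitationState(state)
    frame = Frame(frame)
    V, d = state_hyperbola_constants(state, params)
    delta = V - params.Rd
    r = frame.resistance(params)
    sign = _BISECTOR_SIGN[state]
    if r == 0.0:
        asy1 = Line(slope=None, intercept=-d)
        centre = (-d, delta)
        bis_slope = float(sign)
        beta = 0.25 * math.pi
    else:
        asy1 = Line(slope=1.0 / r, intercept=d / r)
        centre = (r * delta - d, delta)
        root = math.sqrt(1.0 + r * r)
        bis_slope = -(r + root) if sign < 0 else (-r + root)
        beta = 0.5 * math.atan(1.0 / r)
    asy2 = Line(slope=0.0, intercept=delta)
    bis = Line(slope=bis_slope, intercept=centre[1] - bis_slope * centre[0])
    return HyperbolaGeometry(
        state=state,
        frame=frame,
        asymptote_1=asy1,
        asymptote_2=asy2,
        centre=centre,
        bisecting_line=bis,
        beta=beta,
    )


def geometry_from_conic(
    conic: ConicCoefficients,
    state: LimitationState,
    frame: Frame,
) -> HyperbolaGeometry:
    """Geometry recovered numerically from the conic coefficients alone.

    Independent of the closed forms: asymptote directions come from the
    roots of cyy·m² + cxy·m + cxx = 0, the centre from the vanishing
    gradient, and the bisecting line from the unit-vector angle bisectors of
    the asymptotes.  The branch-containing bisector is selected by the sign
    test Q(u)·f(centre) < 0 (a point centre + t·u lies on the curve for some
    t only along that bisector); for a degenerate conic (f(centre) = 0, the
    α = 0 state-p line pair) the state's opening rule decides.
    """
    state = LimitationState(state)
    frame = Frame(frame)
    if conic.quadratic_discriminant() <= 0.0:
        raise NotAHyperbolaError("quadratic part is not hyperbolic")

    # asymptote slopes: directions (1, m) with Q(1, m) = 0
    if conic.cyy == 0.0:
        # cxy·m + cxx = 0 plus the vertical direction
        slopes: list[Optional[float]] = [None, -conic.cxx / conic.cxy]
    else:
        disc = math.sqrt(conic.quadratic_discriminant())
        slopes = [
            (-conic.cxy - disc) / (2.0 * conic.cyy),
            (-conic.cxy + disc) / (2.0 * conic.cyy),
        ]
    # order: asymptote_2 is the horizontal one
    horiz = min(slopes, key=lambda m: abs(m) if m is not None else math.inf)
    other = slopes[0] if slopes[1] == horiz else slopes[1]

    # centre: gradient of the conic vanishes
    det = 4.0 * conic.cxx * conic.cyy - conic.cxy * conic.cxy
    c_C = (-2.0 * conic.cyy * conic.cx + conic.cxy * conic.cy) / det
    c_A = (-2.0 * conic.cxx * conic.cy + conic.cxy * conic.cx) / det
    centre = (c_C, c_A)

    if other is None:
        asy1 = Line(slope=None, intercept=c_C)
        u_other = (0.0, 1.0)
    else:
        asy1 = Line(slope=other, intercept=c_A - other * c_C)
        n = math.hypot(1.0, other)
        u_other = (1.0 / n, other / n)
    asy2 = Line(slope=horiz, intercept=c_A - horiz * c_C)
    n2 = math.hypot(1.0, horiz)
    u_horiz = (1.0 / n2, horiz / n2)

    # the two (perpendicular) bisector directions
    bisectors = [
        (u_horiz[0] + u_other[0], u_horiz[1] + u_other[1]),
        (u_horiz[0] - u_other[0], u_horiz[1] - u_other[1]),
    ]
    f0 = conic.evaluate(c_C, c_A)

    def quad_form(u: tuple[float, float]) -> float:
        return (
            conic.cxx * u[0] * u[0]
            + conic.cxy * u[0] * u[1]
            + conic.cyy * u[1] * u[1]
        )

    scale = max(abs(conic.cx), abs(conic.cy), abs(conic.c0), 1.0)
    chosen = None
    if abs(f0) > 1e-9 * scale:
        for u in bisectors:
            if quad_form(u) * f0 < 0.0:
                chosen = u
                break
    if chosen is None:
        # degenerate line pair: fall back to the state's opening rule
        want = _BISECTOR_SIGN[state]
        for u in bisectors:
            slope_sign = math.copysign(1.0, u[1] / u[0]) if u[0] != 0.0 else 1.0
            if slope_sign == want:
                chosen = u
                break
    if chosen[0] == 0.0:
        bis = Line(slope=None, intercept=c_C)
    else:
        m = chosen[1] / chosen[0]
        bis = Line(slope=m, intercept=c_A - m * c_C)

    return HyperbolaGeometry(
        state=state,
        frame=frame,
        asymptote_1=asy1,
        asymptote_2=asy2,
        centre=centre,
        bisecting_line=bis,
        beta=rotation_angle(conic),
    )
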