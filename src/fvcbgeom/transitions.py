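"""Analytic transition points between limitation states and limiting conditions.

Any two limitation-state curves intersect at two points.  The index-1 point
is common to all three pairs: (Γ*, −Rd) in the chloroplast frame, shifted to
(Γ* − r·Rd, −Rd) in a resistive frame — it sits in the fourth quadrant, or
the third when Rd·r > Γ*.  The index-2 point is the physiologically
interesting first-quadrant transition; its closed forms are

    cj:  C2 = (8·Vcmax·Γ* − J·Kco)/(J − 4·Vcmax)
         A2 = ((J − 4·Rd)·Kco + (J + 8·Rd − 12·Vcmax)·Γ*)/(4·Kco − 8·Γ*)
    jp:  C2 = (J + 24·Tp + 3αJ)·Γ*/(J − 12·Tp)
         A2 = (12·Tp + αJ − 4·Rd·(1 + α))/(4·(1 + α))
    cp:  C2 = ((1 + 3α)·Vcmax·Γ* + 3·Tp·Kco)/(Vcmax − 3·Tp)
         A2 = ((3·(Tp + α·Vcmax) − (1 + 3α)·Rd)·Γ* + (3·Tp − Rd)·Kco)
              /(Kco + (1 + 3α)·Γ*)

In a resistive frame the C coordinate shifts by r·A while A is unchanged —
so the transition *rates* are invariant to the diffusional resistances, and
so are the critical parameter ratios at which the index-2 point diverges
(J = 4·Vcmax for cj, J = 12·Tp for jp, Vcmax = 3·Tp for cp) or collapses
onto the common point (Vcmax = J·(Kco + Γ*)/(12·Γ*) for cj; the analogous
jp/cp conditions require Tp < 0 and are flagged as non-biochemical).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError
from .model import net_rate_curve, p_usable_from, rate_in_frame
from .params import Frame, FvCBParams, LimitationState

__all__ = [
    "TransitionPoint",
    "LimitingConditionReport",
    "Segment",
    "transition_cc",
    "transition_in_frame",
    "all_transitions",
    "limiting_conditions",
    "operative_segments",
]

PAIRS = ("cj", "jp", "cp")

#: |denominator| below this fraction of the numerator scale → divergent point
DIVERGENCE_RTOL = 1e-9


@dataclass(frozen=True)
class TransitionPoint:
    """Intersection of two limitation-state curves in one frame.

    index 1 is the common (fourth/third-quadrant) point shared by all pairs;
    index 2 is the first-quadrant transition.  When ``finite`` is False the
    closed form diverges and C/A are NaN markers, not numbers.
    """

    pair: str
    index: int
    frame: Frame
    C: float
    A: float
    finite: bool = True
    on_min_curve: bool = False
    quadrant: Optional[int] = None
    on_boundary: bool = False

    def to_dict(self) -> dict:
        return {
            "pair": self.pair,
            "index": self.index,
            "frame": self.frame.value,
            "C": self.C if self.finite else None,
            "A": self.A if self.finite else None,
            "finite": self.finite,
            "on_min_curve": self.on_min_curve,
            "quadrant": self.quadrant,
            "on_boundary": self.on_boundary,
        }


@dataclass(frozen=True)
class Segment:
    """One operative piece of the min-curve: C interval and its state."""

    interval: tuple[float, float]
    state: LimitationState


@dataclass(frozen=True)
class LimitingConditionReport:
    """Dimensionless parameter ratios governing the transition taxonomy.

    Each ratio equals 1 exactly at the critical condition where the
    corresponding first-quadrant transition diverges to infinity; the cj
    pair additionally collapses onto the common point when
    Vcmax = J·(Kco + Γ*)/(12·Γ*).  None of this depends on rm or rs.
    """

    ratio_cj: float  #: J/(4·Vcmax)
    ratio_jp: float  #: J/(12·Tp)
    ratio_cp: float  #: Vcmax/(3·Tp)
    coincide_cj: bool  #: transitions 1 and 2 of the cj pair coincide
    diverge: dict = field(default_factory=dict)  #: pair → ratio == 1 flag
    nonbiochemical: tuple = ("jp", "cp")  #: pairs whose coincidence needs Tp < 0
    n_first_quadrant: int = 0
    operative_sequence: tuple = ()

    def to_dict(self) -> dict:
        return {
            "ratio_cj": self.ratio_cj,
            "ratio_jp": self.ratio_jp,
            "ratio_cp": self.ratio_cp,
            "coincide_cj": self.coincide_cj,
            "diverge": dict(self.diverge),
            "nonbiochemical_coincidence_pairs": list(self.nonbiochemical),
            "n_first_quadrant": self.n_first_quadrant,
            "operative_sequence": [s.value for s in self.operative_sequence],
        }


def _quadrant(C: float, A: float) -> tuple[int, bool]:
    """Quadrant label (1-4) with boundary flag; zeros go to the non-negative side."""
    boundary = C == 0.0 or A == 0.0
    if C >= 0.0:
        return (1, boundary) if A >= 0.0 else (4, boundary)
    return (2, boundary) if A >= 0.0 else (3, boundary)


def _index2_cc(pair: str, params: FvCBParams) -> tuple[float, float, bool]:
    """Closed-form (C2, A2, finite) of the index-2 point in the Cc frame."""
    p = params
    a = p.alpha
    if pair == "cj":
        num = 8.0 * p.Vcmax * p.Gamma_star - p.J * p.Kco
        den = p.J - 4.0 * p.Vcmax
        a_num = (p.J - 4.0 * p.Rd) * p.Kco + (
            p.J + 8.0 * p.Rd - 12.0 * p.Vcmax
        ) * p.Gamma_star
        a_den = 4.0 * p.Kco - 8.0 * p.Gamma_star
    elif pair == "jp":
        num = (p.J + 24.0 * p.Tp + 3.0 * a * p.J) * p.Gamma_star
        den = p.J - 12.0 * p.Tp
        a_num = 12.0 * p.Tp + a * p.J - 4.0 * p.Rd * (1.0 + a)
        a_den = 4.0 * (1.0 + a)
    elif pair == "cp":
        # factor (1+3α) follows from the Ap pole at (1+3α)·Γ*, consistent
        # with the jp pair; verified against the numeric intersection oracle
        num = (1.0 + 3.0 * a) * p.Vcmax * p.Gamma_star + 3.0 * p.Tp * p.Kco
        den = p.Vcmax - 3.0 * p.Tp
        a_num = (
            3.0 * (p.Tp + a * p.Vcmax) - (1.0 + 3.0 * a) * p.Rd
        ) * p.Gamma_star + (3.0 * p.Tp - p.Rd) * p.Kco
        a_den = p.Kco + (1.0 + 3.0 * a) * p.Gamma_star
    else:
        raise ValueError(f"pair must be one of {PAIRS}, got {pair!r}")
    if abs(den) < DIVERGENCE_RTOL * max(abs(num), 1.0) or abs(
        a_den
    ) < DIVERGENCE_RTOL * max(abs(a_num), 1.0):
        return math.nan, math.nan, False
    return num / den, a_num / a_den, True


def _on_min_curve(
    pair: str, params: FvCBParams, frame: Frame, C: float, A: float
) -> bool:
    """Does the intersection lie on the operative min-of-three curve?

    For pairs involving state p the point must additionally sit on the
    usable right-opening branch of the Ap curve; the common index-1 points
    of jp and cp fall on the left-opening branch and are excluded.
    """
    if "p" in pair and C < p_usable_from(params, frame) - 1e-9:
        return False
    a_net, _ = net_rate_curve(params, Frame(frame), np.array([C]))
    return bool(abs(a_net[0] - A) <= 1e-6 * max(1.0, abs(A)))


def transition_cc(
    pair: str, params: FvCBParams
) -> tuple[TransitionPoint, TransitionPoint]:
    """Both transition points of one state pair in the chloroplast frame."""
    return transition_in_frame(pair, params, Frame.CC)


def transition_in_frame(
    pair: str, params: FvCBParams, frame: Frame
) -> tuple[TransitionPoint, TransitionPoint]:
    """Both transition points of one state pair in any frame.

    The A coordinates equal the chloroplast-frame values; C shifts by r·A
    with r the frame's total resistance.  Divergent index-2 points are
    returned with finite=False (divergence is data, not an exception).
    """
    if pair not in PAIRS:
        raise ValueError(f"pair must be one of {PAIRS}, got {pair!r}")
    frame = Frame(frame)
    r = frame.resistance(params)

    c1 = params.Gamma_star - r * params.Rd
    a1 = -params.Rd
    q1, b1 = _quadrant(c1, a1)
    pt1 = TransitionPoint(
        pair=pair,
        index=1,
        frame=frame,
        C=c1,
        A=a1,
        finite=True,
        on_min_curve=_on_min_curve(pair, params, frame, c1, a1),
        quadrant=q1,
        on_boundary=b1,
    )

    c2c, a2, finite = _index2_cc(pair, params)
    if finite:
        c2 = c2c + r * a2
        q2, b2 = _quadrant(c2, a2)
        pt2 = TransitionPoint(
            pair=pair,
            index=2,
            frame=frame,
            C=c2,
            A=a2,
            finite=True,
            on_min_curve=_on_min_curve(pair, params, frame, c2, a2),
            quadrant=q2,
            on_boundary=b2,
        )
    else:
        pt2 = TransitionPoint(
            pair=pair, index=2, frame=frame, C=math.nan, A=math.nan, finite=False
        )
    return pt1, pt2


def all_transitions(
    params: FvCBParams, frame: Frame
) -> dict[str, tuple[TransitionPoint, TransitionPoint]]:
    """All six transition points (three pairs × two indices) in one frame."""
    return {pair: transition_in_frame(pair, params, frame) for pair in PAIRS}


def operative_segments(
    params: FvCBParams,
    frame: Frame,
    C_range: tuple[float, float],
    n_grid: int = 2001,
) -> list[Segment]:
    """Piecewise argmin of the three negative-root curves over a C range.

    Scans a grid, merges runs of equal operative state and refines each
    boundary by bracketing the root of the difference of the two adjacent
    states' rates.  Boundaries coincide with the on-min-curve index-2
    transition points.
    """
    frame = Frame(frame)
    lo, hi = C_range
    if not (hi > lo):
        raise DomainError(f"empty C range ({lo!r}, {hi!r})")
    bound = params.Gamma_star - frame.resistance(params) * params.Rd
    if lo < bound - 1e-12 * max(1.0, abs(bound)):
        raise DomainError(
            f"C range starts at {lo:g} Pa, below the domain bound {bound:g} Pa"
        )
    grid = np.linspace(lo, hi, n_grid)
    _, states = net_rate_curve(params, frame, grid)

    segments: list[Segment] = []
    start = grid[0]
    for i in range(1, n_grid):
        if states[i] != states[i - 1]:
            s_prev, s_next = states[i - 1], states[i]

            def diff(C: float) -> float:
                a = rate_in_frame(s_prev, params, frame, C)
                b = rate_in_frame(s_next, params, frame, C)
                if a is None or b is None:
                    return math.nan
                return a - b

            try:
                boundary = brentq(diff, grid[i - 1], grid[i], xtol=1e-10)
            except ValueError:
                boundary = 0.5 * (grid[i - 1] + grid[i])
            segments.append(Segment(interval=(start, boundary), state=s_prev))
            start = boundary
    segments.append(Segment(interval=(start, grid[-1]), state=states[-1]))
    return segments


def limiting_conditions(
    params: FvCBParams,
    frame: Frame = Frame.CI,
    C_max: Optional[float] = None,
) -> LimitingConditionReport:
    """Classify the transition taxonomy of a parameter set.

    Reports the three critical dimensionless ratios, flags exact critical
    conditions (relative tolerance 1e−9), and counts first-quadrant
    transition points by scanning the operative min-curve.  The
    classification is independent of rm and rs.
    """
    p = params
    ratio_cj = p.J / (4.0 * p.Vcmax)
    ratio_jp = p.J / (12.0 * p.Tp)
    ratio_cp = p.Vcmax / (3.0 * p.Tp)
    vc_crit = p.J * (p.Kco + p.Gamma_star) / (12.0 * p.Gamma_star)
    coincide_cj = math.isclose(p.Vcmax, vc_crit, rel_tol=1e-9)
    diverge = {
        "cj": math.isclose(ratio_cj, 1.0, rel_tol=1e-9),
        "jp": math.isclose(ratio_jp, 1.0, rel_tol=1e-9),
        "cp": math.isclose(ratio_cp, 1.0, rel_tol=1e-9),
    }

    frame = Frame(frame)
    r = frame.resistance(params)
    lower = p.Gamma_star - r * p.Rd
    if C_max is None:
        finite_c = [
            pt2.C
            for _, pt2 in all_transitions(params, frame).values()
            if pt2.finite and pt2.C > 0
        ]
        C_max = max(200.0, 3.0 * max(finite_c, default=0.0))
    segments = operative_segments(params, frame, (lower + 1e-9, C_max))
    sequence = tuple(seg.state for seg in segments)
    return LimitingConditionReport(
        ratio_cj=ratio_cj,
        ratio_jp=ratio_jp,
        ratio_cp=ratio_cp,
        coincide_cj=coincide_cj,
        diverge=diverge,
        n_first_quadrant=len(sequence) - 1,
        operative_sequence=sequence,
    )
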