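"""Rate equations of the FvCB model in the A/Cc, A/Ci and A/Ca frames.

In the chloroplast frame each limitation state is a rectangular hyperbola

    A_x = V·(Cc − Γ*)/(Cc + d) − Rd

(see :func:`fvcbgeom.params.state_hyperbola_constants` for the per-state
constants).  Substituting the Fick's-law supply line Cc = C − r·A — with
r = rm for the intercellular frame and r = rm + rs for the atmospheric
frame — and clearing denominators yields a quadratic in A:

    r·A² − (C + d + r·(V − Rd))·A + (V − Rd)·C − Rd·d − V·Γ* = 0

The sign convention is fixed so the A² coefficient equals the total
diffusional resistance of the frame (a2 = r > 0), hence the physically
operative "negative root" is (−a1 − √disc)/(2·a2).  With r = 0 the quadratic
degenerates to the linear-in-A rectangular form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np

from .errors import DomainError, PoleError
from .params import Frame, FvCBParams, LimitationState, state_hyperbola_constants

__all__ = [
    "QuadraticForm",
    "Domain",
    "NetRate",
    "rate_cc",
    "quadratic_in_frame",
    "rate_in_frame",
    "net_rate",
    "valid_domain",
]

#: relative tolerance below which a denominator counts as a pole
POLE_RTOL = 1e-12
#: negative discriminants within this relative band are clamped to zero
DISC_CLAMP_RTOL = 1e-10
#: relative tolerance for reporting a tie between limitation states
TIE_RTOL = 1e-9

_STATES = (LimitationState.c, LimitationState.j, LimitationState.p)


@dataclass(frozen=True)
class QuadraticForm:
    """Coefficients of a2·A² + a1·A + a0 = 0 for one state at one C.

    a2 equals the total diffusional resistance of the frame (0 for the
    chloroplast frame, where the form is linear in A).
    """

    a2: float
    a1: float
    a0: float

    def discriminant(self) -> float:
        return self.a1 * self.a1 - 4.0 * self.a2 * self.a0

    def roots(self) -> tuple[Optional[float], Optional[float]]:
        """(negative root, positive root); Nones when no real solution.

        For the rectangular (a2 = 0) case the single root is returned in
        both slots.
        """
        if self.a2 == 0.0:
            root = -self.a0 / self.a1
            return root, root
        disc = self.discriminant()
        scale = max(self.a1 * self.a1, abs(4.0 * self.a2 * self.a0), 1.0)
        if disc < 0.0:
            if disc > -DISC_CLAMP_RTOL * scale:
                disc = 0.0
            else:
                return None, None
        s = math.sqrt(disc)
        return (-self.a1 - s) / (2.0 * self.a2), (-self.a1 + s) / (2.0 * self.a2)


@dataclass(frozen=True)
class Domain:
    """Valid C interval(s) of one limitation state in one frame.

    ``lower`` is the physical lower bound Γ* − r·Rd (Γ* itself in the
    chloroplast frame).  ``excluded`` is the open interval of C with no real
    solution — nonempty only for state p with α > 0 in a resistive frame.
    """

    state: LimitationState
    frame: Frame
    lower: float
    excluded: Optional[tuple[float, float]] = None

    def contains(self, C: float) -> bool:
        if C < self.lower:
            return False
        if self.excluded is not None and self.excluded[0] < C < self.excluded[1]:
            return False
        return True


class NetRate(NamedTuple):
    """Net assimilation with its operative limitation state."""

    A: float
    state: LimitationState
    tie: bool = False


def rate_cc(state: LimitationState, params: FvCBParams, Cc: float) -> float:
    """Rate of one limitation state in the chloroplast (A/Cc) frame.

    Evaluates A = V·(Cc − Γ*)/(Cc + d) − Rd.  All states pass through
    (Γ*, −Rd); for state p with α = 0 that point coincides with the pole.
    """
    V, d = state_hyperbola_constants(state, params)
    den = Cc + d
    if abs(den) < POLE_RTOL * max(abs(Cc), abs(d), 1.0):
        raise PoleError(LimitationState(state), -d)
    return V * (Cc - params.Gamma_star) / den - params.Rd


def quadratic_in_frame(
    state: LimitationState, params: FvCBParams, frame: Frame, C: float
) -> QuadraticForm:
    """Quadratic (in A) obtained by the Fick's-law substitution Cc = C − r·A."""
    V, d = state_hyperbola_constants(state, params)
    r = Frame(frame).resistance(params)
    delta = V - params.Rd
    return QuadraticForm(
        a2=r,
        a1=-(C + d + r * delta),
        a0=delta * C - params.Rd * d - V * params.Gamma_star,
    )


def rate_in_frame(
    state: LimitationState,
    params: FvCBParams,
    frame: Frame,
    C: float,
    root: str = "negative",
) -> Optional[float]:
    """Selected root of the frame quadratic; ``None`` marks no real solution.

    The default "negative" root is the operative branch for nonlinear
    fitting.  A negative discriminant is a genuine feature of state p with
    α ≠ 0, so it is reported as ``None`` rather than raised.
    """
    if root not in ("negative", "positive"):
        raise ValueError(f"root must be 'negative' or 'positive', got {root!r}")
    frame = Frame(frame)
    if frame.resistance(params) == 0.0:
        return rate_cc(state, params, C)
    q = quadratic_in_frame(state, params, frame, C)
    neg, pos = q.roots()
    if neg is None:
        return None
    return neg if root == "negative" else pos


def valid_domain(
    state: LimitationState, params: FvCBParams, frame: Frame
) -> Domain:
    """Valid C domain of one state's operative branch in one frame.

    The lower bound is Γ* − r·Rd, the image of the common point (Γ*, −Rd)
    under the supply line.  For state p with α > 0 in a resistive frame the
    discriminant is negative on an interior interval centred on the
    hyperbola's centre C; its closed-form edges are (r·Δ − d) ± 2·√(3αΓ*·r·3Tp).
    """
    state = LimitationState(state)
    frame = Frame(frame)
    r = frame.resistance(params)
    lower = params.Gamma_star - r * params.Rd
    excluded = None
    if state is LimitationState.p and r > 0.0 and params.alpha > 0.0:
        V, d = state_hyperbola_constants(state, params)
        delta = V - params.Rd
        centre_c = r * delta - d
        half = 2.0 * math.sqrt(3.0 * params.alpha * params.Gamma_star * r * V)
        if half > 0.0:
            excluded = (centre_c - half, centre_c + half)
    return Domain(state=state, frame=frame, lower=lower, excluded=excluded)


def _rates_at(params: FvCBParams, frame: Frame, C: float) -> list[Optional[float]]:
    """Negative-root rate of each state at C, None where not real / at a pole."""
    out: list[Optional[float]] = []
    for state in _STATES:
        try:
            out.append(rate_in_frame(state, params, frame, C))
        except PoleError:
            out.append(None)
    return out


def net_rate(params: FvCBParams, frame: Frame, C: float) -> NetRate:
    """Min-of-three net assimilation rate A = min{Ac, Aj, Ap} at C.

    The minimum is taken over the states whose negative root is real at C.
    Ties (within relative tolerance 1e−9) report the alphabetically first
    state and set the tie flag.
    """
    frame = Frame(frame)
    r = frame.resistance(params)
    lower = params.Gamma_star - r * params.Rd
    if C < lower - POLE_RTOL * max(1.0, abs(lower)):
        raise DomainError(
            f"C = {C:g} Pa below the valid domain bound "
            f"Gamma_star - r*Rd = {lower:g} Pa in frame {frame.value}"
        )
    rates = _rates_at(params, frame, C)
    candidates = [(a, s) for a, s in zip(rates, _STATES) if a is not None]
    if not candidates:
        raise DomainError(f"no limitation state has a real rate at C = {C:g} Pa")
    a_min = min(a for a, _ in candidates)
    tol = TIE_RTOL * max(1.0, abs(a_min))
    tied = [s for a, s in candidates if a - a_min <= tol]
    return NetRate(A=a_min, state=tied[0], tie=len(tied) > 1)


def p_usable_from(params: FvCBParams, frame: Frame) -> float:
    """Lowest C of the usable right-opening branch of the state-p curve.

    The operative branch for the min-curve and for nonlinear fitting is the
    negative root of the branch opening right; the left-opening branch is
    outside the applicable C domain.  Returns the upper edge of the excluded
    interval (α > 0) or the centre/pole C (α = 0, degenerate line pair).
    """
    frame = Frame(frame)
    r = frame.resistance(params)
    V, d = state_hyperbola_constants(LimitationState.p, params)
    dom = valid_domain(LimitationState.p, params, frame)
    if dom.excluded is not None:
        return dom.excluded[1]
    return r * (V - params.Rd) - d


def net_rate_curve(
    params: FvCBParams, frame: Frame, C: np.ndarray
) -> tuple[np.ndarray, list[LimitationState]]:
    """Vectorised operative min-curve over a C grid (simulation and fitting).

    Unlike :func:`net_rate` this never raises on out-of-domain points, and
    the state-p rate participates in the minimum only on its usable
    right-opening branch (states c and j are real everywhere, so a value
    always exists).
    """
    frame = Frame(frame)
    A, states, _ = _min_curve(params, frame, C)
    return A, states


def _min_curve(
    params: FvCBParams, frame: Frame, C: np.ndarray
) -> tuple[np.ndarray, list[LimitationState], np.ndarray]:
    """Min-curve values, argmin states and the full (3, n) rate matrix."""
    frame = Frame(frame)
    C = np.asarray(C, dtype=float)
    rates = np.full((len(_STATES), C.size), np.nan)
    for k, state in enumerate(_STATES):
        V, d = state_hyperbola_constants(state, params)
        r = frame.resistance(params)
        delta = V - params.Rd
        if r == 0.0:
            den = C + d
            with np.errstate(divide="ignore", invalid="ignore"):
                rates[k] = V * (C - params.Gamma_star) / den - params.Rd
            rates[k, np.abs(den) < POLE_RTOL * np.maximum(np.abs(C), 1.0)] = np.nan
        else:
            a1 = -(C + d + r * delta)
            a0 = delta * C - params.Rd * d - V * params.Gamma_star
            disc = a1 * a1 - 4.0 * r * a0
            scale = np.maximum(a1 * a1, np.maximum(np.abs(4.0 * r * a0), 1.0))
            disc = np.where((disc < 0) & (disc > -DISC_CLAMP_RTOL * scale), 0.0, disc)
            with np.errstate(invalid="ignore"):
                rates[k] = (-a1 - np.sqrt(disc)) / (2.0 * r)
        if state is LimitationState.p:
            rates[k, C < p_usable_from(params, frame)] = np.nan
    idx = np.nanargmin(rates, axis=0)
    A = rates[idx, np.arange(C.size)]
    states = [_STATES[i] for i in idx]
    return A, states, rates
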