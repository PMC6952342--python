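"""Synthetic gas-exchange curves and nonlinear fitting of the FvCB model.

The fitted model is the min-of-three negative-root curve in the chosen
frame; limitation-state assignment is implicit through the min operator (no
pre-segmentation, and the transition C is never constrained).  The objective
is the unweighted sum of squared residuals, minimised with a bounded
trust-region least-squares solver from a deterministic multistart grid.

Initial values use the model's own asymptote structure: the Rubisco-limited
low-C points seed Vcmax, the plateau seeds J/4 − Rd and 3·Tp − Rd, and the
lowest observation seeds Rd.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, FitError
from .model import _min_curve, net_rate_curve, valid_domain
from .params import Frame, FvCBParams, LimitationState
from .transitions import TransitionPoint, all_transitions

__all__ = ["ResponseCurve", "FitResult", "generate_curve", "fit_curve"]

_PARAM_NAMES = ("Vcmax", "J", "Tp", "Rd", "Kco", "Gamma_star", "rm", "rs", "alpha")

#: lower/upper box bounds per parameter for the optimiser
_BOUNDS = {
    "Vcmax": (1e-6, 1e4),
    "J": (1e-6, 1e4),
    "Tp": (1e-6, 1e4),
    "Rd": (1e-6, 1e3),
    "Kco": (1e-6, 1e4),
    "Gamma_star": (1e-6, 1e3),
    "rm": (0.0, 1e3),
    "rs": (0.0, 1e3),
    "alpha": (0.0, 1.0),
}

#: deterministic multiplicative perturbations of the heuristic start
_MULTISTART_FACTORS = (1.0, 0.7, 1.4, 0.85, 1.2)


@dataclass
class ResponseCurve:
    """Sampled (C, A) gas-exchange response curve in one frame.

    C must be strictly increasing.  ``states`` carries the operative
    limitation state per point where known (generated curves record the
    truth), else None.  ``meta`` is free-form provenance.
    """

    C: np.ndarray
    A: np.ndarray
    frame: Frame
    states: Optional[list[LimitationState]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.frame = Frame(self.frame)
        if self.C.shape != self.A.shape or self.C.ndim != 1:
            raise DomainError("C and A must be 1-D arrays of equal length")
        if self.C.size >= 2 and not np.all(np.diff(self.C) > 0):
            raise DomainError("C must be strictly increasing")

    def __len__(self) -> int:
        return int(self.C.size)


@dataclass
class FitResult:
    """Outcome of fitting the min-of-three model to a response curve."""

    estimates: FvCBParams
    fixed_mask: dict  #: parameter name → True if held fixed
    residual_sse: float
    per_point_state: list[LimitationState]
    transition_estimates: dict[str, tuple[TransitionPoint, TransitionPoint]]
    converged: bool
    identifiability_flags: list[str]
    n_starts: int = 1

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates.to_dict(),
            "fixed_mask": dict(self.fixed_mask),
            "residual_sse": self.residual_sse,
            "per_point_state": [s.value for s in self.per_point_state],
            "transition_estimates": {
                pair: [pt.to_dict() for pt in pts]
                for pair, pts in self.transition_estimates.items()
            },
            "converged": self.converged,
            "identifiability_flags": list(self.identifiability_flags),
            "n_starts": self.n_starts,
        }


def generate_curve(
    params: FvCBParams,
    frame: Frame,
    C_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> ResponseCurve:
    """Simulate a response curve from known parameters.

    A = net rate + Gaussian noise (sd = noise_sd, seeded).  The grid must
    lie inside the valid domain: above Γ* − r·Rd and, when α > 0, outside
    the state-p interval with no real solution.
    """
    frame = Frame(frame)
    if noise_sd < 0:
        raise DomainError(f"noise_sd must be >= 0, got {noise_sd!r}")
    C = np.asarray(list(C_grid), dtype=float)
    if C.size == 0:
        raise DomainError("empty C grid")
    lower = params.Gamma_star - frame.resistance(params) * params.Rd
    below = C[C < lower]
    if below.size:
        raise DomainError(
            f"C grid values below the domain bound {lower:g} Pa: "
            f"{', '.join(f'{c:g}' for c in below)}"
        )
    dom_p = valid_domain(LimitationState.p, params, frame)
    if dom_p.excluded is not None:
        lo, hi = dom_p.excluded
        inside = C[(C > lo) & (C < hi)]
        if inside.size:
            raise DomainError(
                f"C grid values inside the no-real-solution interval "
                f"({lo:g}, {hi:g}) Pa of the triose-phosphate state: "
                f"{', '.join(f'{c:g}' for c in inside)}"
            )
    A, states = net_rate_curve(params, frame, C)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    return ResponseCurve(
        C=C,
        A=A,
        frame=frame,
        states=states,
        meta={
            "generator": "fvcbgeom.fitting.generate_curve",
            "seed": seed,
            "noise_sd": noise_sd,
            "params": params.to_dict(),
            "true_states": [s.value for s in states],
        },
    )


def _heuristic_init(
    curve: ResponseCurve, fixed: Mapping[str, float]
) -> dict[str, float]:
    """Data-driven starting values for the free parameters.

    Uses the model's asymptote results: plateau level ≈ J/4 − Rd and
    3·Tp − Rd; the low-C quasi-rectangular form seeds Vcmax.
    """
    C, A = curve.C, curve.A
    a_min, a_max = float(A.min()), float(A.max())
    rd0 = fixed.get("Rd", max(0.5, -a_min) if a_min < 0 else 1.0)
    plateau = max(a_max, a_min + 1.0)
    gamma0 = fixed.get("Gamma_star", 3.7)
    kco0 = fixed.get("Kco", 60.0)
    rm0 = fixed.get("rm", 0.4)

    # Rubisco-limited estimate from the lower-C half of the curve
    low = C <= np.quantile(C, 0.5)
    cc = C[low] - rm0 * A[low]
    mask = cc > gamma0 + 0.5
    if mask.any():
        v_est = float(
            np.median((A[low][mask] + rd0) * (cc[mask] + kco0) / (cc[mask] - gamma0))
        )
        vcmax0 = min(max(v_est, 5.0), 1e3)
    else:
        vcmax0 = 2.0 * (plateau + rd0)

    init = {
        "Vcmax": vcmax0,
        "J": 4.0 * (plateau + rd0),
        "Tp": (plateau + rd0) / 3.0,
        "Rd": rd0,
        "Kco": kco0,
        "Gamma_star": gamma0,
        "rm": rm0,
        "rs": 0.2,
        "alpha": 0.05,
    }
    return init


def fit_curve(
    curve: ResponseCurve,
    fixed: Mapping[str, float],
    init: Optional[Mapping[str, float]] = None,
    multistart: int = 5,
) -> FitResult:
    """Fit the min-of-three model to a response curve by bounded least squares.

    Parameters named in ``fixed`` are held at the given values; all other
    model parameters are free.  ``init`` optionally overrides the heuristic
    starting values of free parameters.  ``multistart`` deterministic starts
    (multiplicative perturbations of the start vector) guard against local
    minima; the best SSE wins.
    """
    if len(curve) < 3:
        raise FitError(f"need at least 3 points to fit, got {len(curve)}")
    fixed = dict(fixed)
    unknown = sorted(set(fixed) - set(_PARAM_NAMES))
    if unknown:
        raise FitError(f"unknown fixed parameter(s): {', '.join(unknown)}")
    free = [name for name in _PARAM_NAMES if name not in fixed]
    if not free:
        raise FitError("no free parameters to fit")
    if len(curve) < 3 * len(free):
        warnings.warn(
            f"only {len(curve)} points for {len(free)} free parameters; "
            "at least 3 points per free parameter is recommended",
            UserWarning,
            stacklevel=2,
        )

    start = _heuristic_init(curve, fixed)
    if init:
        start.update({k: float(v) for k, v in init.items() if k in _PARAM_NAMES})
    x0 = np.array([start[name] for name in free])
    lo = np.array([_BOUNDS[name][0] for name in free])
    hi = np.array([_BOUNDS[name][1] for name in free])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    def build_params(x: np.ndarray) -> FvCBParams:
        values = dict(fixed)
        values.update({name: float(v) for name, v in zip(free, x)})
        return FvCBParams(**values)

    def residuals(x: np.ndarray) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = build_params(x)
        model_a, _ = net_rate_curve(p, curve.frame, curve.C)
        res = curve.A - model_a
        return np.where(np.isfinite(res), res, 1e3)

    best = None
    n_starts = max(1, int(multistart))
    for k in range(n_starts):
        factor = _MULTISTART_FACTORS[k % len(_MULTISTART_FACTORS)]
        xk = np.clip(x0 * factor, lo + 1e-12, hi - 1e-12)
        try:
            sol = least_squares(
                residuals, xk, bounds=(lo, hi), method="trf", x_scale="jac"
            )
        except Exception:  # optimiser failure at one start is not fatal
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)

    if best is None:
        raise FitError("all optimiser starts failed")
    sse, sol = best
    converged = bool(sol.success)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        estimates = build_params(sol.x)
    _, per_point_state, rate_matrix = _min_curve(estimates, curve.frame, curve.C)

    flags: list[str] = []
    for k, (name, state) in enumerate(
        (("Vcmax", LimitationState.c), ("J", LimitationState.j),
         ("Tp", LimitationState.p))
    ):
        if name not in free:
            continue
        # a state identifies its parameter only where it is the strict
        # minimum; a single boundary tie carries no information
        own = rate_matrix[k]
        others = np.nanmin(np.delete(rate_matrix, k, axis=0), axis=0)
        margin = 1e-6 * np.maximum(1.0, np.abs(others))
        strict = np.isfinite(own) & (own < others - margin)
        if not strict.any():
            flags.append(f"state {state.value} never operative")
    if not converged:
        flags.append("optimiser did not report convergence")

    return FitResult(
        estimates=estimates,
        fixed_mask={name: name in fixed for name in _PARAM_NAMES},
        residual_sse=sse,
        per_point_state=per_point_state,
        transition_estimates=all_transitions(estimates, curve.frame),
        converged=converged,
        identifiability_flags=flags,
        n_starts=n_starts,
    )
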