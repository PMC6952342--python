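"""Biochemical parameter set and enumerations of the steady-state FvCB model.

The model describes net CO2 assimilation A (µmol m⁻² s⁻¹) of a C3 leaf as the
minimum of three limitation-state rates: Rubisco-limited (state ``c``),
RuBP-regeneration-limited (state ``j``) and triose-phosphate-utilisation
limited (state ``p``).  Each rate is a hyperbola in the CO2 concentration of
the chosen reference frame: chloroplastic (Cc), intercellular (Ci) or
atmospheric (Ca), the frames being linked by Fick's-law supply lines through
the mesophyll resistance rm = 1/gm and the stomatal resistance rs = 1/gs.

Units are fixed throughout the package: CO2 concentrations in Pa, rates in
µmol m⁻² s⁻¹ and resistances in Pa µmol⁻¹ m² s.  There is no unit-conversion
layer.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .errors import ParameterError

__all__ = [
    "FvCBParams",
    "Frame",
    "LimitationState",
    "derive_kco",
    "KcoConstraintWarning",
]


class KcoConstraintWarning(UserWarning):
    """Kco does not exceed twice the photocompensation point.

    The limiting-condition analysis assumes Kco > 2·Γ*, the range reported
    for C3 plants.  Violating it is physically unusual but not an error.
    """


class LimitationState(str, Enum):
    """The three limitation states of the FvCB model."""

    c = "c"  #: Rubisco (carboxylation) limited
    j = "j"  #: RuBP-regeneration (electron transport) limited
    p = "p"  #: triose-phosphate-utilisation limited

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Frame(str, Enum):
    """CO2 reference frame: which concentration sits on the x axis."""

    CC = "cc"  #: chloroplastic CO2 (rectangular hyperbolae)
    CI = "ci"  #: intercellular CO2 (non-rectangular, resistance rm)
    CA = "ca"  #: atmospheric CO2 (non-rectangular, resistance rm + rs)

    def resistance(self, params: "FvCBParams") -> float:
        """Total diffusional resistance between this frame and the chloroplast."""
        if self is Frame.CC:
            return 0.0
        if self is Frame.CI:
            return params.rm
        return params.rm + params.rs

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FvCBParams:
    """Full biochemical/diffusional parameter set of the FvCB model.

    Attributes
    ----------
    Vcmax:
        Maximum carboxylation rate of Rubisco, µmol m⁻² s⁻¹.
    J:
        Electron transport rate, µmol m⁻² s⁻¹ (taken as given; its light
        dependence on Jmax is out of scope).
    Tp:
        Triose phosphate export rate from the chloroplast, µmol m⁻² s⁻¹.
    Rd:
        Day (light) respiration, µmol m⁻² s⁻¹.
    Kco:
        Apparent Michaelis–Menten constant Kc(1 + O/Ko), Pa.
    Gamma_star:
        Chloroplast CO2 photocompensation point Γ*, Pa.
    rm:
        Mesophyll resistance to CO2 diffusion (1/gm), Pa µmol⁻¹ m² s.
    rs:
        Stomatal resistance to CO2 diffusion (1/gs), Pa µmol⁻¹ m² s.
    alpha:
        Fraction of photorespiratory glycerate not returned to the
        chloroplast, dimensionless in [0, 1].
    """

    Vcmax: float
    J: float
    Tp: float
    Rd: float
    Kco: float
    Gamma_star: float
    rm: float = 0.0
    rs: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Vcmax", "J", "Tp", "Rd", "Kco", "Gamma_star"):
            v = getattr(self, name)
            if not (v > 0):
                raise ParameterError(f"{name} must be > 0, got {v!r}")
        for name in ("rm", "rs"):
            v = getattr(self, name)
            if not (v >= 0):
                raise ParameterError(f"{name} must be >= 0, got {v!r}")
        if not (0.0 <= self.alpha <= 1.0):
            raise ParameterError(f"alpha must be in [0, 1], got {self.alpha!r}")
        if not (self.Kco > 2.0 * self.Gamma_star):
            warnings.warn(
                f"Kco = {self.Kco:g} Pa does not exceed 2*Gamma_star = "
                f"{2 * self.Gamma_star:g} Pa; the limiting-condition analysis "
                "assumes Kco > 2*Gamma_star for C3 plants",
                KcoConstraintWarning,
                stacklevel=2,
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "FvCBParams":
        """Build a parameter set from a flat mapping; unknown keys are rejected."""
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - fields)
        if unknown:
            raise ParameterError(
                f"unknown parameter key(s): {', '.join(unknown)}; "
                f"expected a subset of {sorted(fields)}"
            )
        try:
            values = {k: float(v) for k, v in mapping.items()}
        except (TypeError, ValueError) as exc:
            raise ParameterError(f"non-numeric parameter value: {exc}") from exc
        return cls(**values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **changes: float) -> "FvCBParams":
        return dataclasses.replace(self, **changes)


def derive_kco(Kc: float, Ko: float, O: float) -> float:
    """Apparent Michaelis–Menten constant from Rubisco kinetics.

    Kco = Kc·(1 + O/Ko), the standard FvCB combination of the carboxylation
    constant Kc, oxygenation constant Ko and oxygen partial pressure O
    (all Pa).  Returns Kco in Pa; Kco > Kc whenever O > 0.
    """
    for name, v in (("Kc", Kc), ("Ko", Ko)):
        if not (v > 0):
            raise ParameterError(f"{name} must be > 0, got {v!r}")
    if not (O >= 0):
        raise ParameterError(f"O must be >= 0, got {O!r}")
    return Kc * (1.0 + O / Ko)


def state_hyperbola_constants(
    state: LimitationState, params: FvCBParams
) -> tuple[float, float]:
    """Per-state constants (V, d) of the uniform rate form.

    Every limitation-state rate in the chloroplast frame can be written as

        A = V·(Cc − Γ*)/(Cc + d) − Rd

    with (V, d) = (Vcmax, Kco) for state c, (J/4, 2Γ*) for state j and
    (3Tp, −(1+3α)Γ*) for state p.  The pole sits at Cc = −d and the
    horizontal asymptote at A = V − Rd.
    """
    state = LimitationState(state)
    if state is LimitationState.c:
        return params.Vcmax, params.Kco
    if state is LimitationState.j:
        return params.J / 4.0, 2.0 * params.Gamma_star
    return 3.0 * params.Tp, -(1.0 + 3.0 * params.alpha) * params.Gamma_star
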