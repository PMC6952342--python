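import numpy as np
import pytest

from fvcbgeom import FvCBParams


@pytest.fixture
def worked_params() -> FvCBParams:
    """Worked-example parameter set: Vcmax 100, J 150, Rd 2, rm 0.45, rs 0.4,
    Kco 62.1, Gamma* 3.74 (µmol m⁻² s⁻¹ / Pa units).  Tp is set huge so the
    triose-phosphate state never binds unless a test overrides it."""
    return FvCBParams(
        Vcmax=100.0, J=150.0, Tp=1e6, Rd=2.0,
        Kco=62.1, Gamma_star=3.74, rm=0.45, rs=0.4, alpha=0.0,
    )


@pytest.fixture
def worked_tp12(worked_params) -> FvCBParams:
    """Same set with a realistic Tp of 12, giving the c→j→p sequence."""
    return worked_params.replace(Tp=12.0)


@pytest.fixture
def ap_params() -> FvCBParams:
    """Triose-phosphate-focused set: Tp 12, Rd 2, rm 0.4, Gamma* 3.74;
    Vcmax and J huge so only state p shapes the min-curve."""
    return FvCBParams(
        Vcmax=1e6, J=4e6, Tp=12.0, Rd=2.0,
        Kco=62.1, Gamma_star=3.74, rm=0.4, rs=0.0, alpha=0.0,
    )


def random_params(rng: np.random.Generator, alpha_max: float = 0.0) -> FvCBParams:
    """A physiologically plausible random parameter draw."""
    gamma = rng.uniform(2.0, 6.0)
    return FvCBParams(
        Vcmax=rng.uniform(30.0, 200.0),
        J=rng.uniform(50.0, 400.0),
        Tp=rng.uniform(5.0, 20.0),
        Rd=rng.uniform(0.5, 4.0),
        Kco=rng.uniform(2.5 * gamma, 120.0),
        Gamma_star=gamma,
        rm=rng.uniform(0.05, 1.0),
        rs=rng.uniform(0.0, 0.8),
        alpha=rng.uniform(0.0, alpha_max) if alpha_max > 0 else 0.0,
    )
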