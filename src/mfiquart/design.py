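"""Sample-size planning for ICC reliability studies.

Implements the Walter-Eliasziw functional approximation for the number of
subjects needed to distinguish an acceptable reliability ``rho0`` from an
expected reliability ``rho1`` with ``k`` observations per subject:

    C_j = 1 + k * rho_j / (1 - rho_j)
    n   = 1 + 2 k (z_alpha + z_beta)^2 / ((k - 1) (ln(C0 / C1))^2)

with one-sided normal quantiles ``z_alpha = Phi^-1(1 - alpha)`` and
``z_beta = Phi^-1(1 - beta)``, rounded up to a whole subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .errors import DesignInfeasibleError

#: designs requiring more subjects than this are reported as infeasible
N_CAP = 1_000_000


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design parameters for an ICC reliability study.

    rho0: null (minimally acceptable) ICC; rho1: expected ICC (> rho0);
    k: observations per subject; alpha: one-sided type-I level; beta:
    type-II level (power = 1 - beta).
    """

    rho0: float
    rho1: float
    k: int = 2
    alpha: float = 0.05
    beta: float = 0.20

    def __post_init__(self) -> None:
        if not (0 < self.rho0 < 1 and 0 < self.rho1 < 1):
            raise ValueError("rho0 and rho1 must lie in (0, 1)")
        if self.rho1 <= self.rho0:
            raise ValueError("rho1 must exceed rho0 (effect in the tested direction)")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if not (0 < self.alpha < 0.5 and 0 < self.beta < 0.5):
            raise ValueError("alpha and beta must lie in (0, 0.5)")


@dataclass(frozen=True)
class SampleSizeResult:
    """Subject count with the intermediate quantities, for auditability."""

    n: int
    n_exact: float
    z_alpha: float
    z_beta: float
    c0: float
    c1: float
    spec: SampleSizeSpec


def walter_eliasziw_n(spec: SampleSizeSpec, cap: int = N_CAP) -> int:
    """Minimum number of subjects (rounded up) for the given design."""
    return walter_eliasziw_details(spec, cap=cap).n


def walter_eliasziw_details(spec: SampleSizeSpec, cap: int = N_CAP) -> SampleSizeResult:
    """Full computation including z quantiles and the C_j variance factors."""
    z_a = float(norm.ppf(1 - spec.alpha))
    z_b = float(norm.ppf(1 - spec.beta))
    c0 = 1 + spec.k * spec.rho0 / (1 - spec.rho0)
    c1 = 1 + spec.k * spec.rho1 / (1 - spec.rho1)
    log_ratio = math.log(c0 / c1)
    n_exact = 1 + 2 * spec.k * (z_a + z_b) ** 2 / ((spec.k - 1) * log_ratio ** 2)
    if not math.isfinite(n_exact) or n_exact > cap:
        raise DesignInfeasibleError(
            f"required n exceeds cap of {cap} (effect rho1 - rho0 too small)"
        )
    return SampleSizeResult(
        n=math.ceil(n_exact), n_exact=n_exact, z_alpha=z_a, z_beta=z_b,
        c0=c0, c1=c1, spec=spec,
    )
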