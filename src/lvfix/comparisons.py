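"""Classical fixation-probability formulas for deterministically growing
populations, with the exact parameter translations into this model.

For the frequency-independent dominance case (a = b, c = d) the competition
matrix reduces to density dependence plus a selection differential, and the
model maps onto logistic-growth population-genetics settings via

    s = 1/d - 1/b          (selective advantage through competition deaths)
    r = beta - gamma       (logistic growth rate)
    K = (beta - gamma) a M (carrying capacity)
    b_birth = beta, xi = 0 (Uecker-Hermisson birth and neutral replacement)
    Q = K z M (s + r) / (s K + r z M)   (effective-size factor)

These formulas assume an advantageous mutant (s > 0) and were derived for
parameter regimes (M s >> 1, r < 0.1) that the fluctuating-size model does
not occupy, which is why they disagree quantitatively with the
weak-selection result here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .model import ModelSpec, validate_model


@dataclass(frozen=True)
class ComparisonParams:
    """Translated parameters of the logistic-growth comparison models.

    ``b_birth`` is the birth rate symbol of the Uecker-Hermisson model
    (their b, translated as beta) -- named to avoid the clash with the
    competition payoff b.
    """

    s: float
    K: float
    r: float
    b_birth: float
    xi: float
    Q: float
    zM: float


def translate_params(spec: ModelSpec, z: float) -> ComparisonParams:
    """Map a model spec and initial scaled size z to comparison parameters.

    The translation is exact for frequency-independent specs (a = b,
    c = d); other specs are allowed with a warning since s = 1/d - 1/b
    then captures only part of the selection.
    """
    validate_model(spec, for_weak_selection=True)
    if spec.a != spec.b or spec.c != spec.d:
        warnings.warn(
            "comparison translations assume frequency independence (a = b, c = d)",
            stacklevel=2,
        )
    beta, gamma = spec.beta, spec.gamma
    s = 1.0 / spec.d - 1.0 / spec.b
    r = beta - gamma
    K = r * spec.a * spec.M
    zM = z * spec.M
    if s == 0.0:
        Q = K
    else:
        Q = K * zM * (s + r) / (s * K + r * zM)
    return ComparisonParams(s=s, K=K, r=r, b_birth=beta, xi=0.0, Q=Q, zM=zM)


def phi_otto_whitlock(spec: ModelSpec, z: float) -> float:
    """Single-mutant fixation probability under deterministic logistic growth
    (diffusion approximation): 2 s K (s + r) / (s K + r z M).

    Valid only for an advantageous mutant; s <= 0 raises.
    """
    pr = translate_params(spec, z)
    if pr.s <= 0:
        raise ValueError("approximation requires an advantageous mutant (s > 0)")
    return 2.0 * pr.s * pr.K * (pr.s + pr.r) / (pr.s * pr.K + pr.r * pr.zM)


def phi_kimura_ohta(spec: ModelSpec, z: float) -> float:
    """Single-mutant fixation probability from the Kolmogorov backward
    equation with effective-size factor Q:

        (1 - exp(-4 Q s / (zM))) / (1 - exp(-4 Q s)),

    evaluated with expm1 for stability; the s -> 0 limit is 1/(zM).
    """
    pr = translate_params(spec, z)
    x = 4.0 * pr.Q * pr.s
    if abs(x) < 1e-12:
        return 1.0 / pr.zM
    return math.expm1(-x / pr.zM) / math.expm1(-x)


def phi_uecker_hermisson(spec: ModelSpec, z: float, p: float | None = None) -> float:
    """Branching-process fixation probability with explicit ecology.

    The single-mutant value is

        s(r+s) / (s(r+s) + (b_birth + xi)(s + r zM / K) + r zM (r+s)/K);

    for a general initial frequency p the replicates are treated as
    independent lines: phi = 1 - (1 - phi_single)^(p zM), with the real
    exponent p zM (non-integer allowed).  s <= 0 raises.
    """
    pr = translate_params(spec, z)
    if pr.s <= 0:
        raise ValueError("branching approximation requires a beneficial mutant (s > 0)")
    s, r, K, zM = pr.s, pr.r, pr.K, pr.zM
    single = s * (r + s) / (
        s * (r + s) + (pr.b_birth + pr.xi) * (s + r * zM / K) + r * zM * (r + s) / K
    )
    if p is None:
        return single
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p == 0.0:
        return 0.0
    return -math.expm1(p * zM * math.log1p(-single))
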