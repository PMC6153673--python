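"""Diffusion-level descriptions: the two-dimensional SDE system, generic
one-dimensional hitting probabilities via scale functions, and the
center-manifold projected diffusion.

The scaled abundances (x, y) = (X, Y)/M follow Ito SDEs whose drift is the
deterministic Lotka-Volterra field and whose demographic noise scales like
1/sqrt(M).  Projecting the nearly-neutral dynamics onto the slow frequency
direction along the center manifold of constant population size yields a
one-dimensional diffusion in q = x/(a(beta-gamma)),

    dq = q(1-q)(1/d - 1/b - (1/a + 1/d - 1/b - 1/c) q) dt
         + sqrt(2 beta q(1-q) / (M (beta-gamma)^2)) dW,

whose absorption probability at q = 1 follows from the scale function.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad

from . import _kernels
from .model import ModelSpec, validate_model
from .ssa import _seed_words


@dataclass(frozen=True)
class DiffusionModel1D:
    """A one-dimensional diffusion dq = drift(q) dt + sqrt(variance(q)) dW
    on a bounded interval with absorbing endpoints."""

    drift: Callable[[float], float]
    variance: Callable[[float], float]
    q_lo: float = 0.0
    q_hi: float = 1.0
    description: str = ""


@dataclass(frozen=True)
class SDEPath:
    """Euler-Maruyama path of the scaled two-type system."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    seed: int
    spec: ModelSpec = field(repr=False, compare=False, default=None)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("time,x,y\n")
            for t, x, y in zip(self.t, self.x, self.y):
                fh.write(f"{t:.9g},{x:.9g},{y:.9g}\n")


def simulate_sde(
    spec: ModelSpec,
    x0: float,
    y0: float,
    dt: float = 1e-3,
    t_end: float = 10.0,
    seed: int = 0,
    record_every: int = 1,
) -> SDEPath:
    """Euler-Maruyama discretization of the two-type SDE system.

    Independent Gaussian increments drive the two noise terms; a coordinate
    proposed below zero is set to zero and frozen (absorbing truncation).
    """
    validate_model(spec)
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if x0 < 0 or y0 < 0:
        raise ValueError("initial scaled abundances must be non-negative")
    n_steps = int(round(t_end / dt))
    seed_word = int(_seed_words(seed, 1)[0])
    t, x, y = _kernels.sde_path(
        spec.a, spec.b, spec.c, spec.d,
        spec.beta_x, spec.beta_y, spec.gamma_x, spec.gamma_y, spec.M,
        float(x0), float(y0), float(dt), n_steps, seed_word, int(record_every),
    )
    return SDEPath(t=t, x=x, y=y, dt=dt, seed=seed, spec=spec)


def sde_fixation_frequency(
    spec: ModelSpec,
    x0: float,
    y0: float,
    n_paths: int,
    seed: int,
    dt: float = 1e-3,
    t_max: float = 2000.0,
) -> tuple[float, int]:
    """Fraction of Euler-Maruyama paths in which x outlives y.

    Returns (frequency, n_timeout); paths not absorbed within ``t_max`` are
    excluded from the frequency.
    """
    validate_model(spec)
    seeds = _seed_words(seed, n_paths)
    n_xf, n_yf, n_to = _kernels.sde_absorption_batch(
        spec.a, spec.b, spec.c, spec.d,
        spec.beta_x, spec.beta_y, spec.gamma_x, spec.gamma_y, spec.M,
        float(x0), float(y0), float(dt), int(round(t_max / dt)), seeds,
    )
    n_eff = n_xf + n_yf
    if n_eff == 0:
        raise RuntimeError("no SDE path reached absorption; increase t_max")
    if n_to > 0:
        warnings.warn(f"{n_to}/{n_paths} SDE paths timed out and are excluded", stacklevel=2)
    return n_xf / n_eff, int(n_to)


def scale_fixation_probability(model: DiffusionModel1D, q0: float) -> float:
    """Probability of hitting q_hi before q_lo, via the scale function.

    S(q) = int_lo^q exp(-int 2 drift/variance) du; the answer is
    S(q0)/S(q_hi).  The inner integral is accumulated separately and the
    outer integrand exponentiated with a max-shift so that strong drift
    cannot overflow; quadrature is adaptive Gauss-Kronrod with 1e-10
    relative tolerance.  Endpoints return exactly 0 and 1.
    """
    lo, hi = model.q_lo, model.q_hi
    if not lo < hi:
        raise ValueError("need q_lo < q_hi")
    if q0 <= lo:
        return 0.0
    if q0 >= hi:
        return 1.0

    def log_density_slope(u):
        v = model.variance(u)
        if v <= 0:
            raise RuntimeError("diffusion variance must be positive on the open interval")
        return 2.0 * model.drift(u) / v

    mid = 0.5 * (lo + hi)

    def neg_log_density(u):
        val, err = quad(log_density_slope, mid, u, epsabs=1e-12, epsrel=1e-10, limit=500)
        return -val

    # max-shift over a probe grid to keep the exponentials in range
    probes = np.linspace(lo, hi, 65)[1:-1]
    try:
        shift = max(neg_log_density(u) for u in probes)
    except Exception as exc:  # pragma: no cover - singular densities
        raise RuntimeError(f"non-integrable scale density: {exc}") from exc

    def density(u):
        return math.exp(neg_log_density(u) - shift)

    num, en = quad(density, lo, q0, epsabs=1e-14, epsrel=1e-10, limit=500)
    rest, er = quad(density, q0, hi, epsabs=1e-14, epsrel=1e-10, limit=500)
    den = num + rest
    if not (np.isfinite(den) and den > 0):
        raise RuntimeError("non-integrable scale density")
    return float(num / den)


def cm_projected_model(spec: ModelSpec) -> DiffusionModel1D:
    """Center-manifold projected one-dimensional diffusion on [0, 1].

    Drift q(1-q)(1/d - 1/b - (1/a + 1/d - 1/b - 1/c) q); variance
    2 beta q(1-q)/(M (beta-gamma)^2).  For a neutral spec the payoff
    reciprocals cancel and the drift vanishes identically.
    """
    validate_model(spec, for_weak_selection=True)
    beta, gamma, M = spec.beta, spec.gamma, spec.M
    if not beta > gamma:
        raise ValueError("projection requires a viable population (beta > gamma)")
    s_lin = 1.0 / spec.d - 1.0 / spec.b
    s_quad = 1.0 / spec.a + 1.0 / spec.d - 1.0 / spec.b - 1.0 / spec.c
    noise = 2.0 * beta / (M * (beta - gamma) ** 2)

    def drift(q):
        return q * (1.0 - q) * (s_lin - s_quad * q)

    def variance(q):
        return noise * q * (1.0 - q)

    return DiffusionModel1D(
        drift=drift, variance=variance, q_lo=0.0, q_hi=1.0,
        description=f"center-manifold projection (a={spec.a}, b={spec.b}, c={spec.c}, d={spec.d})",
    )


def phi_constable_mckane(
    p: float, z: float, spec: ModelSpec, mapping: str = "frequency"
) -> float:
    """Fixation probability from the center-manifold projected diffusion.

    The initial condition (p, z) must be assigned a position q0 on the
    manifold.  Population size is the fast variable, so the relaxation onto
    the manifold approximately conserves the mutant frequency; the default
    ``mapping="frequency"`` places the start at the manifold point with the
    same frequency, q0 = p d / (p d + (1-p) a)  (q0 = p when a = d).

    ``mapping="manifold"`` instead reads the coordinate literally,
    q0 = x0/(a(beta-gamma)) with x0 = p z.  The two coincide for starts on
    the manifold (z at the carrying-capacity scale) but the literal reading
    degrades badly off-manifold; q0 outside [0, 1] is clamped with a
    warning.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    model = cm_projected_model(spec)
    if mapping == "frequency":
        q0 = p * spec.d / (p * spec.d + (1.0 - p) * spec.a)
    elif mapping == "manifold":
        q0 = p * z / (spec.a * (spec.beta - spec.gamma))
        if q0 < 0.0 or q0 > 1.0:
            warnings.warn(
                f"manifold coordinate q0 = {q0:.4g} outside [0, 1]; clamped", stacklevel=2
            )
            q0 = min(max(q0, 0.0), 1.0)
    else:
        raise ValueError("mapping must be 'frequency' or 'manifold'")
    return scale_fixation_probability(model, q0)
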