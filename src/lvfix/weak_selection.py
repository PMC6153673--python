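"""Weak-selection approximation of the mutant fixation probability.

For nearly-neutral competition matrices the fixation probability of the
mutant is a first-order perturbation of the neutral value p,

    phi(p, z) = p + p(1-p)(1 - p/p*)(1 - d/b) psi(z) + O((1-d/b)^2)

for games with an interior equilibrium p* (coexistence, coordination), and

    phi_dom(p, z) = p + p(1-p)(1 - d/b) psi(z) + O((1-d/b)^2)

for dominance games.  The amplitude psi(z) depends only on the initial
scaled population size z (and on d, beta, gamma, M) and solves a linear
second-order boundary-value ODE whose two regimes ("internal" and
"dominance") are implemented exactly as stated, including their different
d-scalings:

internal:   0 = (z + 1/M) + z((b-g)d - z) psi'
                - (3/(zM))((b+g)d + z) psi + (z/(2M))((b+g)d + z) psi''
dominance:  0 = (1/d)(z + 1/M) + z(b-g - z/d) psi'
                - (1/(zM))(b+g + z/d) psi + (z/(2M))(b+g + z/d) psi''

with b = beta, g = gamma.  z = 0 is a singular point; the bounded solution
behaves like psi ~ z/(3(b+g)d) (internal) resp. z/((b+g)d) (dominance)
there, which provides the near-origin boundary condition.  At large z the
leading balance z((b-g)d - z) psi' + z ~ 0 yields the far-field slope.
The solver works in the log variable t = ln z, which resolves the
origin's resonant z^2 ln z structure on a smooth mesh.
"""

from __future__ import annotations

import functools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_bvp
from scipy.interpolate import PchipInterpolator

from .model import (
    GameClass,
    ModelSpec,
    classify_game,
    validate_model,
    weak_selection_diagnostics,
)

_INTERNAL = "internal"
_DOMINANCE = "dominance"

#: conditions-magnitude threshold above which results are flagged
CONDITION_THRESHOLD = 0.1


def _ode_coeffs(z, d, beta, gamma, M, regime):
    """(inhomogeneous, psi', psi, psi'') coefficients of the printed ODEs."""
    z = np.asarray(z, dtype=float)
    if regime == _INTERNAL:
        F = z + 1.0 / M
        A = z * ((beta - gamma) * d - z)
        C = -(3.0 / (z * M)) * ((beta + gamma) * d + z)
        D = (z / (2.0 * M)) * ((beta + gamma) * d + z)
    elif regime == _DOMINANCE:
        F = (z + 1.0 / M) / d
        A = z * (beta - gamma - z / d)
        C = -(1.0 / (z * M)) * (beta + gamma + z / d)
        D = (z / (2.0 * M)) * (beta + gamma + z / d)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return F, A, C, D


def psi_ode_residual(z, psi, psi_prime, psi_double_prime, spec: ModelSpec, regime: str):
    """Left-hand side of the psi ODE for the given regime, as printed.

    Vanishes identically on an exact solution; z = 0 is rejected (singular
    point of the equation).
    """
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise ValueError("the psi ODE is singular at z = 0; need z > 0")
    F, A, C, D = _ode_coeffs(z, spec.d, spec.beta, spec.gamma, spec.M, regime)
    return F + A * np.asarray(psi_prime) + C * np.asarray(psi) + D * np.asarray(psi_double_prime)


@dataclass(frozen=True)
class PsiSolution:
    """Numerical solution of the psi(z) boundary-value problem.

    The solution is positive and non-decreasing for all z > 0; both
    invariants are checked on the output grid at solve time.  Evaluation
    between grid points uses shape-preserving (monotone cubic) interpolation
    so positivity and monotonicity survive interpolation.
    """

    regime: str
    z_grid: np.ndarray
    psi: np.ndarray
    psi_prime: np.ndarray
    max_residual: float
    z_min: float
    z_max: float
    bc_origin: float  # Dirichlet value imposed near z = 0
    bc_farfield_slope: float
    d: float
    beta: float
    gamma: float
    M: float
    n_nodes: int
    _interp: PchipInterpolator = field(repr=False, compare=False)
    _interp_prime: PchipInterpolator = field(repr=False, compare=False)

    def __call__(self, z):
        z = np.asarray(z, dtype=float)
        if np.any(z < self.z_min * (1 - 1e-12)) or np.any(z > self.z_max * (1 + 1e-12)):
            raise ValueError(
                f"z outside solved range [{self.z_min}, {self.z_max}]; re-solve with larger z_max"
            )
        return self._interp(np.clip(z, self.z_min, self.z_max))

    def prime(self, z):
        z = np.asarray(z, dtype=float)
        return self._interp_prime(np.clip(z, self.z_min, self.z_max))

    def to_csv(self, path) -> None:
        """``z,psi,psi_prime`` rows; JSON sidecar written next to it."""
        with open(path, "w") as fh:
            fh.write("z,psi,psi_prime\n")
            for z, p, dp in zip(self.z_grid, self.psi, self.psi_prime):
                fh.write(f"{z:.12g},{p:.12g},{dp:.12g}\n")
        sidecar = {
            "regime": self.regime,
            "z_min": self.z_min,
            "z_max": self.z_max,
            "bc_origin": self.bc_origin,
            "bc_farfield_slope": self.bc_farfield_slope,
            "max_residual": self.max_residual,
            "d": self.d,
            "beta": self.beta,
            "gamma": self.gamma,
            "M": self.M,
            "n_grid": int(self.z_grid.size),
            "n_nodes": self.n_nodes,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)


def regime_for(spec: ModelSpec) -> str:
    """BVP regime matching the spec's game class (neutral uses internal)."""
    cls = classify_game(spec)
    if cls in (GameClass.DOMINANCE_MUTANT, GameClass.DOMINANCE_WILDTYPE):
        return _DOMINANCE
    return _INTERNAL


def solve_psi(
    spec: ModelSpec,
    regime: str | None = None,
    z_max: float | None = None,
    n_grid: int = 2000,
    z_min: float = 1e-3,
    tol: float = 1e-8,
    max_nodes: int = 500_000,
) -> PsiSolution:
    """Solve the psi boundary-value problem by collocation.

    The ODE is integrated in the log variable t = ln z on [ln z_min,
    ln z_max] (a mesh geometric in z, denser near the singular origin).
    Boundary conditions: the bounded-solution regularity value at z_min and
    the far-field slope 1/(z_max - (beta-gamma)d) at z_max.  The output grid
    carries ``n_grid`` points graded toward the origin.

    Raises RuntimeError with grid diagnostics on non-convergence, which
    occurs for population scales M well beyond ~1000.
    """
    validate_model(spec, for_weak_selection=True)
    beta, gamma, d, M = spec.beta, spec.gamma, spec.d, spec.M
    if not beta > gamma:
        raise ValueError("psi requires a viable population (beta > gamma)")
    if regime is None:
        regime = regime_for(spec)
    if regime not in (_INTERNAL, _DOMINANCE):
        raise ValueError(f"unknown regime {regime!r}")
    if z_max is None:
        z_max = 10.0 * d * (beta - gamma)
    if z_max <= d * (beta - gamma):
        raise ValueError("z_max must exceed the carrying-capacity scale d(beta-gamma)")
    if z_min <= 0 or z_min >= z_max:
        raise ValueError("need 0 < z_min < z_max")

    if regime == _INTERNAL:
        bc0 = z_min / (3.0 * (beta + gamma) * d)
    else:
        bc0 = z_min / ((beta + gamma) * d)
    slope_inf = 1.0 / (z_max - (beta - gamma) * d)

    def fun(t, u):
        z = np.exp(t)
        F, A, C, D = _ode_coeffs(z, d, beta, gamma, M, regime)
        dpsi_dt = z * u[1]
        ddpsi = -(F + A * u[1] + C * u[0]) / D
        return np.vstack([dpsi_dt, z * ddpsi])

    def bc(ua, ub):
        return np.array([ua[0] - bc0, ub[1] - slope_inf])

    t_mesh = np.linspace(np.log(z_min), np.log(z_max), 2001)
    z_mesh = np.exp(t_mesh)
    guess = np.vstack([(bc0 / z_min) * z_mesh, np.full_like(z_mesh, bc0 / z_min)])
    res = solve_bvp(fun, bc, t_mesh, guess, tol=tol, max_nodes=max_nodes)
    if res.status != 0:
        raise RuntimeError(
            f"psi BVP did not converge (status={res.status}, nodes={res.x.size}, "
            f"max rms residual={res.rms_residuals.max():.2e}); the collocation "
            f"method is unstable for large M (here M={M:g})"
        )

    # output grid graded toward the origin (geometric spacing)
    z_grid = np.geomspace(z_min, z_max, n_grid)
    t_grid = np.log(z_grid)
    psi = res.sol(t_grid)[0]
    psi_prime = res.sol(t_grid)[1]
    # second derivative from the collocation spline: d(psi')/dz = (d/dt psi') / z
    psi_pp = res.sol(t_grid, 1)[1] / z_grid
    resid = psi_ode_residual(z_grid, psi, psi_prime, psi_pp, spec, regime)
    max_residual = float(np.abs(resid).max())

    if np.any(psi <= 0):
        raise RuntimeError("solved psi is not strictly positive; solution rejected")
    if np.any(np.diff(psi) < -1e-12 * np.abs(psi[-1])):
        raise RuntimeError("solved psi is not non-decreasing; solution rejected")

    return PsiSolution(
        regime=regime,
        z_grid=z_grid,
        psi=psi,
        psi_prime=psi_prime,
        max_residual=max_residual,
        z_min=float(z_min),
        z_max=float(z_max),
        bc_origin=float(bc0),
        bc_farfield_slope=float(slope_inf),
        d=d,
        beta=beta,
        gamma=gamma,
        M=M,
        n_nodes=int(res.x.size),
        _interp=PchipInterpolator(z_grid, psi),
        _interp_prime=PchipInterpolator(z_grid, psi_prime),
    )


@functools.lru_cache(maxsize=64)
def _solve_psi_cached(regime: str, d: float, beta: float, gamma: float, M: float,
                      z_max: float | None) -> PsiSolution:
    # psi depends on the payoffs only through d, so one solve serves every
    # (a, b, c) combination sharing (d, beta, gamma, M) and regime.
    spec = ModelSpec(a=d, b=d, c=d, d=d, beta_x=beta, beta_y=beta,
                     gamma_x=gamma, gamma_y=gamma, M=M)
    return solve_psi(spec, regime=regime, z_max=z_max)


def psi_for(spec: ModelSpec, regime: str | None = None,
            z_max: float | None = None) -> PsiSolution:
    """Cached psi solution keyed on (regime, d, beta, gamma, M)."""
    if regime is None:
        regime = regime_for(spec)
    return _solve_psi_cached(regime, spec.d, spec.beta, spec.gamma, spec.M, z_max)


@dataclass(frozen=True)
class WeakSelectionResult:
    """First-order fixation probability with approximation diagnostics.

    ``phi`` is the first-order value clamped to [0, 1]; ``raw`` the
    unclamped value.  ``conditions_violated`` flags any weak-selection
    condition magnitude above 0.1, signalling that the first-order formula
    is outside its trust region.
    """

    phi: float | np.ndarray
    raw: float | np.ndarray
    selection: float  # 1 - d/b
    regime: str
    game_class: GameClass
    conditions_violated: bool


def phi_weak_selection(
    p,
    z,
    spec: ModelSpec,
    psi: PsiSolution | None = None,
    full_result: bool = False,
):
    """First-order fixation probability of the mutant.

    Uses the interior-equilibrium formula for coexistence/coordination
    games, the dominance formula otherwise, and phi = p for neutral specs.
    The boundary values phi(0, z) = 0 and phi(1, z) = 1 are exact.  With
    ``full_result`` a :class:`WeakSelectionResult` is returned; otherwise
    just the clamped probability (scalar or array, following the inputs).
    """
    validate_model(spec, for_weak_selection=True)
    p_arr = np.asarray(p, dtype=float)
    z_arr = np.asarray(z, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr > 1):
        raise ValueError("p must lie in [0, 1]")
    cls = classify_game(spec)
    sel = 1.0 - spec.d / spec.b

    if cls is GameClass.NEUTRAL:
        raw = p_arr * np.ones_like(z_arr * p_arr)
        regime = "neutral"
    else:
        regime = regime_for(spec)
        if psi is None:
            psi = psi_for(spec, regime)
        elif psi.regime != regime:
            raise ValueError(
                f"psi solved for regime {psi.regime!r} but the spec is a "
                f"{cls.value} game requiring {regime!r}"
            )
        psi_z = psi(z_arr)
        if regime == _INTERNAL:
            from .model import p_star

            ps = p_star(spec)
            raw = p_arr + p_arr * (1 - p_arr) * (1 - p_arr / ps) * sel * psi_z
        else:
            raw = p_arr + p_arr * (1 - p_arr) * sel * psi_z
    phi = np.clip(raw, 0.0, 1.0)
    if np.ndim(p) == 0 and np.ndim(z) == 0:
        phi = float(phi)
        raw = float(raw)
    if not full_result:
        return phi
    diag = weak_selection_diagnostics(spec)
    return WeakSelectionResult(
        phi=phi,
        raw=raw,
        selection=sel,
        regime=regime,
        game_class=cls,
        conditions_violated=diag.violated(CONDITION_THRESHOLD),
    )


def phi_near_equilibrium(
    epsilon,
    z,
    spec: ModelSpec,
    psi: PsiSolution | None = None,
):
    """Fixation probability for initial frequencies p* + epsilon.

    phi(p* + eps, z) =
        (p* + eps)(1 - (eps/p*)(1 - p* - eps)(1 - d/b) psi(z)),

    accurate to O((1-d/b)^2).  Around a stable equilibrium (d < b) the
    probability is below neutral for positive deviations; around an
    unstable one (d > b) it is above.  Defined only for games with an
    interior equilibrium.
    """
    from .model import p_star

    validate_model(spec, for_weak_selection=True)
    cls = classify_game(spec)
    if cls not in (GameClass.COEXISTENCE, GameClass.COORDINATION):
        raise ValueError("phi_near_equilibrium needs an interior equilibrium")
    ps = p_star(spec)
    eps = np.asarray(epsilon, dtype=float)
    z_arr = np.asarray(z, dtype=float)
    if np.any(ps + eps < 0) or np.any(ps + eps > 1):
        raise ValueError("p* + epsilon must lie in [0, 1]")
    if psi is None:
        psi = psi_for(spec, _INTERNAL)
    val = (ps + eps) * (1.0 - (eps / ps) * (1.0 - ps - eps) * (1.0 - spec.d / spec.b) * psi(z_arr))
    if np.ndim(epsilon) == 0 and np.ndim(z) == 0:
        return float(val)
    return val


def generator_apply(p_grid, z_grid, phi_values, spec: ModelSpec):
    """Apply the transformed (p, z) infinitesimal generator to a surface.

    ``phi_values[i, j]`` is the surface at (p_grid[i], z_grid[j]).  The five
    partial-derivative terms are evaluated with central finite differences;
    the returned residual covers the interior points
    (p_grid[1:-1], z_grid[1:-1]).  The exact solution of the absorption
    problem makes this residual vanish; applying it to the first-order
    weak-selection surface leaves a residual of order (1 - d/b)^2.

    Requires common birth/death rates and an interior equilibrium p*
    (neutral specs are allowed: every p*-dependent term carries the factor
    1 - d/b = 0).
    """
    from .model import p_star

    validate_model(spec, for_weak_selection=True)
    p_grid = np.asarray(p_grid, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    phi_values = np.asarray(phi_values, dtype=float)
    if p_grid.size < 5 or z_grid.size < 5:
        raise ValueError("grid too coarse for the central-difference stencil")
    if phi_values.shape != (p_grid.size, z_grid.size):
        raise ValueError("phi_values must have shape (len(p_grid), len(z_grid))")
    beta, gamma, d = spec.beta, spec.gamma, spec.d
    M = spec.M
    db, dc, da = d / spec.b, d / spec.c, d / spec.a
    sel = 1.0 - db
    if sel == 0.0:
        inv_ps = 0.0  # p* enters only multiplied by 1 - d/b
    else:
        inv_ps = 1.0 / p_star(spec)

    phi_p = np.gradient(phi_values, p_grid, axis=0)
    phi_z = np.gradient(phi_values, z_grid, axis=1)
    phi_pp = np.gradient(phi_p, p_grid, axis=0)
    phi_zz = np.gradient(phi_z, z_grid, axis=1)
    phi_pz = np.gradient(phi_p, z_grid, axis=1)

    P, Z = np.meshgrid(p_grid, z_grid, indexing="ij")
    drift_z_bracket = beta - gamma - (Z / d) * (
        1.0 - P * (2.0 - dc - db) + sel * inv_ps * P**2
    )
    diff_p_bracket = beta + gamma + (Z / d) * (
        db + P * (1.0 + da - 2.0 * db) - sel * inv_ps * P**2
    )
    diff_z_bracket = beta + gamma + (Z / d) * (
        1.0 - P * (2.0 - dc - db) + sel * inv_ps * P**2
    )

    res = (
        (P * (1 - P) / d) * sel * (1.0 - inv_ps * P) * (Z + 1.0 / M) * phi_p
        + Z * drift_z_bracket * phi_z
        + (P * (1 - P) / (2.0 * Z * M)) * diff_p_bracket * phi_pp
        + (P * (1 - P) * Z / (d * M)) * sel * (inv_ps * P - 1.0) * phi_pz
        + (Z / (2.0 * M)) * diff_z_bracket * phi_zz
    )
    return res[1:-1, 1:-1]


def weak_selection_surface(p_grid, z_grid, spec: ModelSpec,
                           psi: PsiSolution | None = None) -> np.ndarray:
    """First-order phi surface on a (p, z) grid (unclamped)."""
    validate_model(spec, for_weak_selection=True)
    cls = classify_game(spec)
    p_grid = np.asarray(p_grid, dtype=float)
    z_grid = np.asarray(z_grid, dtype=float)
    P, Z = np.meshgrid(p_grid, z_grid, indexing="ij")
    if cls is GameClass.NEUTRAL:
        return P.copy()
    regime = regime_for(spec)
    if psi is None:
        psi = psi_for(spec, regime)
    psi_z = psi(z_grid)[None, :]
    sel = 1.0 - spec.d / spec.b
    if regime == _INTERNAL:
        from .model import p_star

        ps = p_star(spec)
        return P + P * (1 - P) * (1 - P / ps) * sel * psi_z
    return P + P * (1 - P) * sel * psi_z
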