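"""Model parameterization, game classification and deterministic dynamics.

The population consists of mutants X and wild-types Y.  Each individual
reproduces at a constant per-capita rate (beta_X, beta_Y), dies spontaneously
(gamma_X, gamma_Y) and dies through pairwise competition.  Competition rates
are inverse payoffs of an evolutionary game scaled by the population-size
parameter M: an X dies from meeting another X at rate 1/(aM), from meeting a
Y at 1/(bM); a Y dies from meeting an X at 1/(cM) and from another Y at
1/(dM).  In the large-M limit the mean dynamics are the competitive
Lotka-Volterra equations

    dX/dt = X (beta_X - gamma_X - X/(aM) - Y/(bM)),
    dY/dt = Y (beta_Y - gamma_Y - X/(cM) - Y/(dM)).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq  # noqa: F401  (re-exported convenience)


class ModelValidationError(ValueError):
    """Raised for invalid model parameters; carries a short ``code``."""

    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


class ViabilityWarning(UserWarning):
    """Emitted when the net growth rate beta - gamma is not positive."""


class GameClass(str, enum.Enum):
    """Classification of the competition matrix as a two-player game.

    * ``coexistence``  -- a < c and b > d; interior equilibrium, stable.
    * ``coordination`` -- a > c and b < d; interior equilibrium, unstable.
    * ``dominance_mutant`` / ``dominance_wildtype`` -- one type's payoffs
      weakly dominate; no interior equilibrium.
    * ``neutral`` -- a = b = c = d; types are exchangeable.
    """

    COEXISTENCE = "coexistence"
    COORDINATION = "coordination"
    DOMINANCE_MUTANT = "dominance_mutant"
    DOMINANCE_WILDTYPE = "dominance_wildtype"
    NEUTRAL = "neutral"


_SPEC_KEYS = ("a", "b", "c", "d", "beta_x", "beta_y", "gamma_x", "gamma_y", "M")


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterization of the two-type competitive Lotka-Volterra system.

    Parameters
    ----------
    a, b, c, d
        Competition payoffs (dimensionless, strictly positive).  They enter
        the model as inverse competition rates 1/(aM), ..., 1/(dM).
    beta_x, beta_y
        Per-capita birth rates of mutant and wild-type (1/time).
    gamma_x, gamma_y
        Per-capita spontaneous death rates (1/time).
    M
        Population scale; the monomorphic mutant population fluctuates
        around a (beta - gamma) M individuals.
    """

    a: float
    b: float
    c: float
    d: float
    beta_x: float
    beta_y: float
    gamma_x: float
    gamma_y: float
    M: float

    @classmethod
    def create(
        cls,
        a: float,
        b: float,
        c: float,
        d: float,
        M: float,
        beta: float | None = None,
        gamma: float | None = None,
        beta_x: float | None = None,
        beta_y: float | None = None,
        gamma_x: float | None = None,
        gamma_y: float | None = None,
    ) -> "ModelSpec":
        """Build a spec; a single ``beta``/``gamma`` sets both types' rates."""
        if beta is not None:
            if beta_x is not None or beta_y is not None:
                raise ModelValidationError(
                    "ambiguous_rates", "give either beta or beta_x/beta_y, not both"
                )
            beta_x = beta_y = beta
        if gamma is not None:
            if gamma_x is not None or gamma_y is not None:
                raise ModelValidationError(
                    "ambiguous_rates", "give either gamma or gamma_x/gamma_y, not both"
                )
            gamma_x = gamma_y = gamma
        if None in (beta_x, beta_y, gamma_x, gamma_y):
            raise ModelValidationError("missing_rates", "birth/death rates not fully specified")
        return validate_model(
            cls(
                a=float(a), b=float(b), c=float(c), d=float(d),
                beta_x=float(beta_x), beta_y=float(beta_y),
                gamma_x=float(gamma_x), gamma_y=float(gamma_y), M=float(M),
            )
        )

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        """Build a spec from a flat key-value mapping.

        Accepted keys: a, b, c, d, M, beta_x, beta_y, gamma_x, gamma_y and
        the shorthands beta / gamma setting both types.  Unknown keys raise.
        """
        allowed = set(_SPEC_KEYS) | {"beta", "gamma"}
        unknown = set(data) - allowed
        if unknown:
            raise ModelValidationError(
                "unknown_key", f"unknown model keys: {sorted(unknown)}"
            )
        missing = {"a", "b", "c", "d", "M"} - set(data)
        if missing:
            raise ModelValidationError("missing_key", f"missing model keys: {sorted(missing)}")
        kwargs = {k: float(v) for k, v in data.items()}
        return cls.create(**kwargs)

    def to_dict(self) -> dict:
        """Flat key-value representation (beta/gamma collapsed when common)."""
        out = {"a": self.a, "b": self.b, "c": self.c, "d": self.d, "M": self.M}
        if self.beta_x == self.beta_y and self.gamma_x == self.gamma_y:
            out["beta"] = self.beta_x
            out["gamma"] = self.gamma_x
        else:
            out.update(
                beta_x=self.beta_x, beta_y=self.beta_y,
                gamma_x=self.gamma_x, gamma_y=self.gamma_y,
            )
        return out

    # -- convenience accessors -------------------------------------------------

    @property
    def has_common_rates(self) -> bool:
        return self.beta_x == self.beta_y and self.gamma_x == self.gamma_y

    @property
    def beta(self) -> float:
        """Common birth rate; defined only when both types share it."""
        if self.beta_x != self.beta_y:
            raise ModelValidationError("unequal_rates", "beta_x != beta_y: no common beta")
        return self.beta_x

    @property
    def gamma(self) -> float:
        if self.gamma_x != self.gamma_y:
            raise ModelValidationError("unequal_rates", "gamma_x != gamma_y: no common gamma")
        return self.gamma_x

    def replace(self, **changes) -> "ModelSpec":
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(changes)
        return validate_model(ModelSpec(**{k: float(v) for k, v in current.items()}))


@dataclass(frozen=True)
class ScaledState:
    """Scaled abundances x = X/M, y = Y/M with frequency/size coordinates.

    The weak-selection theory works in the coordinates p = x/(x+y) (mutant
    fraction) and z = x + y (scaled total size).
    """

    x: float
    y: float

    @classmethod
    def from_counts(cls, X: float, Y: float, M: float) -> "ScaledState":
        return cls(x=X / M, y=Y / M)

    @classmethod
    def from_pz(cls, p: float, z: float) -> "ScaledState":
        return cls(x=p * z, y=(1.0 - p) * z)

    @property
    def p(self) -> float:
        tot = self.x + self.y
        if tot == 0:
            raise ValueError("mutant fraction undefined at total size zero")
        return self.x / tot

    @property
    def z(self) -> float:
        return self.x + self.y


@dataclass(frozen=True)
class InternalEquilibrium:
    """Interior fixed point of the deterministic dynamics.

    ``X_star``/``Y_star`` are counts, ``p_star`` the mutant fraction and
    ``z_star`` the scaled total size at the equilibrium.
    """

    X_star: float
    Y_star: float
    p_star: float
    z_star: float


@dataclass(frozen=True)
class WeakSelectionDiagnostics:
    """Magnitudes of the weak-selection smallness conditions.

    All five quantities must be small (<< 1) for the first-order fixation
    formula to be accurate.  ``cond_iv`` requires an interior equilibrium and
    ``cond_v`` requires b != d; they are ``None`` when undefined.
    """

    cond_i: float
    cond_ii: float
    cond_iii: float
    cond_iv: float | None
    cond_v: float | None

    def max_defined(self) -> float:
        vals = [v for v in (self.cond_i, self.cond_ii, self.cond_iii, self.cond_iv, self.cond_v)
                if v is not None]
        return max(vals)

    def violated(self, threshold: float = 0.1) -> bool:
        """True when any defined condition magnitude exceeds ``threshold``."""
        return self.max_defined() > threshold


def validate_model(spec: ModelSpec, for_weak_selection: bool = False) -> ModelSpec:
    """Check the type invariants of a :class:`ModelSpec`.

    Raises :class:`ModelValidationError` (with ``code``) for non-positive
    payoffs, negative rates, non-positive M, and -- when
    ``for_weak_selection`` -- unequal birth or death rates across types.
    A non-viable net growth rate (beta <= gamma) only triggers a
    :class:`ViabilityWarning` since the stochastic process is still defined.
    """
    for name in ("a", "b", "c", "d"):
        if not getattr(spec, name) > 0:
            raise ModelValidationError(
                "nonpositive_payoff",
                f"payoff {name} = {getattr(spec, name)} must be > 0 "
                f"(it appears as the divisor 1/({name}M))",
            )
    for name in ("beta_x", "beta_y", "gamma_x", "gamma_y"):
        if getattr(spec, name) < 0:
            raise ModelValidationError("negative_rate", f"rate {name} must be >= 0")
    if not spec.M > 0:
        raise ModelValidationError("nonpositive_M", "population scale M must be > 0")
    if for_weak_selection and not spec.has_common_rates:
        raise ModelValidationError(
            "unequal_rates",
            "the weak-selection theory assumes beta_x = beta_y and gamma_x = gamma_y",
        )
    if spec.beta_x <= spec.gamma_x or spec.beta_y <= spec.gamma_y:
        warnings.warn(
            "non-viable: beta <= gamma (non-positive net growth)", ViabilityWarning,
            stacklevel=2,
        )
    return spec


def classify_game(spec: ModelSpec) -> GameClass:
    """Classify the competition matrix.

    Exact neutrality requires a = b = c = d.  Boundary equalities in the
    pairwise comparisons (a = c or b = d without full neutrality) are
    assigned to the dominance classes (weak dominance), where the dominance
    first-order formula remains valid.
    """
    a, b, c, d = spec.a, spec.b, spec.c, spec.d
    if a == b == c == d:
        return GameClass.NEUTRAL
    if a < c and b > d:
        return GameClass.COEXISTENCE
    if a > c and b < d:
        return GameClass.COORDINATION
    # remaining: weak dominance (including boundary ties)
    if (a > c) or (b > d):
        return GameClass.DOMINANCE_MUTANT
    if (a < c) or (b < d):
        return GameClass.DOMINANCE_WILDTYPE
    # a == c and b == d but not all four equal: degenerate tie; the types
    # exert identical competitive pressure, treated as weak mutant dominance.
    return GameClass.DOMINANCE_MUTANT


def p_star(spec: ModelSpec) -> float:
    """Interior equilibrium mutant fraction p* = ac(b-d) / (ac(b-d) + bd(c-a))."""
    a, b, c, d = spec.a, spec.b, spec.c, spec.d
    num = a * c * (b - d)
    den = a * c * (b - d) + b * d * (c - a)
    cls = classify_game(spec)
    if cls not in (GameClass.COEXISTENCE, GameClass.COORDINATION):
        raise ModelValidationError(
            "no_interior_equilibrium",
            f"no interior equilibrium for a {cls.value} game",
        )
    return num / den


def internal_fixed_point(spec: ModelSpec) -> InternalEquilibrium:
    """Closed-form interior fixed point of the deterministic dynamics.

    X* = ac(b-d)/(bc-ad) (beta_X - gamma_X) M,
    Y* = bd(c-a)/(bc-ad) (beta_Y - gamma_Y) M.

    Exists only for coexistence and coordination games; raises
    ``no_interior_equilibrium`` otherwise.
    """
    a, b, c, d = spec.a, spec.b, spec.c, spec.d
    cls = classify_game(spec)
    if cls not in (GameClass.COEXISTENCE, GameClass.COORDINATION):
        raise ModelValidationError(
            "no_interior_equilibrium",
            f"no interior equilibrium for a {cls.value} game",
        )
    den = b * c - a * d
    X = a * c * (b - d) / den * (spec.beta_x - spec.gamma_x) * spec.M
    Y = b * d * (c - a) / den * (spec.beta_y - spec.gamma_y) * spec.M
    if X <= 0 or Y <= 0:
        raise ModelValidationError(
            "no_interior_equilibrium", "interior fixed point has a non-positive coordinate"
        )
    ps = a * c * (b - d) / (a * c * (b - d) + b * d * (c - a))
    return InternalEquilibrium(X_star=X, Y_star=Y, p_star=ps, z_star=(X + Y) / spec.M)


def deterministic_rhs(spec: ModelSpec, X: float, Y: float) -> tuple[float, float]:
    """Right-hand side of the deterministic Lotka-Volterra equations (counts)."""
    dX = X * (spec.beta_x - spec.gamma_x - X / (spec.a * spec.M) - Y / (spec.b * spec.M))
    dY = Y * (spec.beta_y - spec.gamma_y - X / (spec.c * spec.M) - Y / (spec.d * spec.M))
    return dX, dY


@dataclass(frozen=True)
class DeterministicTrajectory:
    """Continuous-time solution of the mean-field equations."""

    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray


def integrate_deterministic(
    spec: ModelSpec,
    X0: float,
    Y0: float,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: np.ndarray | None = None,
) -> DeterministicTrajectory:
    """Integrate the deterministic dynamics with an adaptive stiff-capable solver.

    Non-negativity is preserved by the multiplicative structure of the
    equations; solver failures raise with the solver's diagnostic message.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")

    def rhs(_t, u):
        return deterministic_rhs(spec, u[0], u[1])

    sol = solve_ivp(
        rhs, (0.0, float(t_end)), [float(X0), float(Y0)],
        method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"deterministic integration failed: {sol.message}")
    X = np.clip(sol.y[0], 0.0, None)
    Y = np.clip(sol.y[1], 0.0, None)
    return DeterministicTrajectory(t=sol.t, X=X, Y=Y)


def weak_selection_diagnostics(spec: ModelSpec) -> WeakSelectionDiagnostics:
    """Evaluate the magnitudes of the weak-selection conditions.

    (i)   (1 - d/b)^2
    (ii)  (1 - d/b)(2 - d/c - d/b)
    (iii) (1 - d/b)(1 + d/a - 2 d/b)
    (iv)  (1 - d/b)(1/p* - 2)            [interior-equilibrium games only]
    (v)   (1 - d/b)(1 + (db/ac)(c-a)/(b-d))   [undefined when b = d]

    Magnitudes (absolute values) are returned; the caller decides thresholds.
    """
    a, b, c, d = spec.a, spec.b, spec.c, spec.d
    sel = 1.0 - d / b
    cond_i = sel**2
    cond_ii = abs(sel * (2.0 - d / c - d / b))
    cond_iii = abs(sel * (1.0 + d / a - 2.0 * d / b))
    cls = classify_game(spec)
    if cls in (GameClass.COEXISTENCE, GameClass.COORDINATION):
        ps = a * c * (b - d) / (a * c * (b - d) + b * d * (c - a))
        cond_iv = abs(sel * (1.0 / ps - 2.0))
    else:
        cond_iv = None
    if b != d:
        cond_v = abs(sel * (1.0 + (d * b / (a * c)) * (c - a) / (b - d)))
    else:
        cond_v = None
    return WeakSelectionDiagnostics(
        cond_i=cond_i, cond_ii=cond_ii, cond_iii=cond_iii, cond_iv=cond_iv, cond_v=cond_v
    )


def carrying_capacity_mutant(spec: ModelSpec) -> float:
    """Monomorphic mutant equilibrium a (beta_X - gamma_X) M (counts)."""
    return spec.a * (spec.beta_x - spec.gamma_x) * spec.M


def carrying_capacity_wildtype(spec: ModelSpec) -> float:
    """Monomorphic wild-type equilibrium d (beta_Y - gamma_Y) M (counts)."""
    return spec.d * (spec.beta_y - spec.gamma_y) * spec.M


def _require_finite(x: float, name: str) -> float:
    if not math.isfinite(x):
        raise ModelValidationError("non_finite", f"{name} must be finite")
    return x
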