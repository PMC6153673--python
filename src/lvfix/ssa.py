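"""Exact stochastic simulation of the eight-reaction system.

The population evolves by a continuous-time Markov jump process with
reactions

    X -> 2X  (beta_X)      Y -> 2Y  (beta_Y)
    X -> 0   (gamma_X)     Y -> 0   (gamma_Y)
    X+X -> X (1/(aM))      X+Y -> Y (1/(bM))
    X+Y -> X (1/(cM))      Y+Y -> Y (1/(dM))

simulated by the direct (Gillespie) method: exponential waiting times at the
total propensity and categorical reaction choice proportional to the
individual propensities.  Fixation of the mutant X means the wild-type count
hits zero while X > 0.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import _kernels
from .model import ModelSpec, validate_model

_OUTCOMES = {_kernels.FIXATION: "fixation", _kernels.LOSS: "loss", _kernels.TIMEOUT: "timeout"}


@dataclass(frozen=True)
class PopulationState:
    """Integer type counts at a point in time."""

    X: int
    Y: int
    t: float = 0.0

    def __post_init__(self):
        if self.X < 0 or self.Y < 0 or self.t < 0:
            raise ValueError("counts and time must be non-negative")


@dataclass(frozen=True)
class Trajectory:
    """Event records (t, X, Y), possibly thinned; absorption always recorded."""

    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    thin: int = 1

    def __len__(self) -> int:
        return self.t.size

    def to_csv(self, path) -> None:
        """Write ``time,X,Y`` rows; times with 9 significant digits."""
        with open(path, "w") as fh:
            fh.write("time,X,Y\n")
            for t, x, y in zip(self.t, self.X, self.Y):
                fh.write(f"{t:.9g},{x:d},{y:d}\n")

    def time_average(self, t0: float, t1: float) -> tuple[float, float]:
        """Time-weighted averages of (X, Y) over the window [t0, t1].

        The counts are piecewise constant between events (valid only for
        unthinned trajectories).
        """
        if self.thin != 1:
            raise ValueError("time averages require an unthinned trajectory")
        ts = np.append(self.t, max(t1, self.t[-1]))
        w = np.clip(np.minimum(ts[1:], t1) - np.maximum(ts[:-1], t0), 0.0, None)
        if w.sum() == 0:
            raise ValueError("window does not overlap the trajectory")
        return float(np.average(self.X, weights=w)), float(np.average(self.Y, weights=w))


@dataclass(frozen=True)
class AbsorptionRecord:
    """Outcome of one replicate run to absorption (or timeout)."""

    outcome: str  # "fixation" | "loss" | "timeout"
    t_abs: float
    n_events: int
    final_state: PopulationState
    trajectory: Trajectory | None = None


@dataclass(frozen=True)
class FixationEstimate:
    """Monte Carlo fixation-probability estimate with a Wilson interval."""

    n_runs: int
    n_fixed: int
    n_timeout: int
    p_hat: float
    ci_low: float
    ci_high: float
    ci_level: float
    seed: int
    spec: ModelSpec = field(repr=False, compare=False, default=None)
    x0: int = 0
    y0: int = 0

    @property
    def se(self) -> float:
        """Binomial standard error of p_hat."""
        n_eff = self.n_runs - self.n_timeout
        return math.sqrt(self.p_hat * (1.0 - self.p_hat) / n_eff)

    def to_json(self) -> str:
        from . import __version__

        return json.dumps(
            {
                "params": self.spec.to_dict() if self.spec is not None else None,
                "x0": self.x0,
                "y0": self.y0,
                "n_runs": self.n_runs,
                "n_fixed": self.n_fixed,
                "n_timeout": self.n_timeout,
                "p_hat": self.p_hat,
                "ci": [self.ci_low, self.ci_high],
                "ci_level": self.ci_level,
                "seed": self.seed,
                "tool_version": __version__,
            },
            indent=2,
        )


def reaction_propensities(state: PopulationState, spec: ModelSpec) -> np.ndarray:
    """The eight reaction propensities at a state.

    Order: [birth_X, birth_Y, death_X, death_Y, comp_XX, comp_XY_b,
    comp_XY_c, comp_YY] where comp_XY_b (rate XY/(bM)) removes one X and
    comp_XY_c (rate XY/(cM)) removes one Y; intra-type competition uses the
    distinct-pair count X(X-1) resp. Y(Y-1).
    """
    X, Y = state.X, state.Y
    return np.array(
        [
            spec.beta_x * X,
            spec.beta_y * Y,
            spec.gamma_x * X,
            spec.gamma_y * Y,
            X * (X - 1) / (spec.a * spec.M),
            X * Y / (spec.b * spec.M),
            X * Y / (spec.c * spec.M),
            Y * (Y - 1) / (spec.d * spec.M),
        ]
    )


#: net count change of each reaction, same order as reaction_propensities
REACTION_STOICHIOMETRY = np.array(
    [(1, 0), (0, 1), (-1, 0), (0, -1), (-1, 0), (-1, 0), (0, -1), (0, -1)]
)


def _seed_words(seed: int, n: int) -> np.ndarray:
    """Per-replicate seed words from a master seed (prefix-stable in n)."""
    return np.asarray(np.random.SeedSequence(seed).generate_state(n), dtype=np.int64)


def run_to_absorption(
    spec: ModelSpec,
    X0: int,
    Y0: int,
    seed: int,
    max_events: int = 10_000_000,
    t_max: float = math.inf,
    record: bool = False,
    thin: int = 1,
) -> AbsorptionRecord:
    """Simulate one replicate until X = 0 or Y = 0 (or a timeout).

    Timeouts (event budget or ``t_max`` exhausted) are reported as a third
    outcome class, never silently truncated into loss or fixation.
    Identical (spec, X0, Y0, seed) reproduce the identical trajectory.
    """
    validate_model(spec)
    X0, Y0 = int(X0), int(Y0)
    if X0 < 0 or Y0 < 0 or X0 + Y0 == 0:
        raise ValueError("need non-negative initial counts with X0 + Y0 > 0")
    if X0 == 0 or Y0 == 0:
        # already absorbed at t = 0 (fixation requires X > 0)
        outcome = "loss" if X0 == 0 else "fixation"
        traj = Trajectory(np.array([0.0]), np.array([X0]), np.array([Y0]), thin) if record else None
        return AbsorptionRecord(outcome, 0.0, 0, PopulationState(X0, Y0, 0.0), traj)
    args = (
        spec.a, spec.b, spec.c, spec.d,
        spec.beta_x, spec.beta_y, spec.gamma_x, spec.gamma_y, spec.M,
        X0, Y0, int(max_events), float(t_max),
    )
    seed_word = int(_seed_words(seed, 1)[0])
    if record:
        out, t, n_ev, X, Y, ts, Xs, Ys = _kernels.ssa_run_record(*args, seed_word, int(thin), 1)
        traj = Trajectory(ts, Xs, Ys, thin)
    else:
        out, t, n_ev, X, Y = _kernels.ssa_run(*args, seed_word)
        traj = None
    return AbsorptionRecord(
        outcome=_OUTCOMES[out],
        t_abs=float(t),
        n_events=int(n_ev),
        final_state=PopulationState(int(X), int(Y), float(t)),
        trajectory=traj,
    )


def run_timed(
    spec: ModelSpec,
    X0: int,
    Y0: int,
    t_max: float,
    seed: int,
    max_events: int = 100_000_000,
    thin: int = 1,
) -> Trajectory:
    """Simulate for a fixed time window without stopping at monomorphism.

    A type hitting zero stays extinct (no propensity revives it) but the
    surviving type keeps evolving; used e.g. for stationary statistics of a
    monomorphic population.  The run ends at ``t_max``, the event budget,
    or total extinction.
    """
    validate_model(spec)
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    seed_word = int(_seed_words(seed, 1)[0])
    out, t, n_ev, X, Y, ts, Xs, Ys = _kernels.ssa_run_record(
        spec.a, spec.b, spec.c, spec.d,
        spec.beta_x, spec.beta_y, spec.gamma_x, spec.gamma_y, spec.M,
        int(X0), int(Y0), int(max_events), float(t_max), seed_word, int(thin), 0,
    )
    return Trajectory(ts, Xs, Ys, thin)


def estimate_fixation_probability(
    spec: ModelSpec,
    X0: int,
    Y0: int,
    n_runs: int,
    seed: int,
    ci_level: float = 0.95,
    max_events: int = 10_000_000,
    t_max: float = math.inf,
) -> FixationEstimate:
    """Monte Carlo fixation probability over independent replicates.

    Per-replicate seeds derive deterministically from the master seed and
    are prefix-stable: increasing ``n_runs`` extends the replicate set
    without re-randomizing earlier replicates.  Timeouts are excluded from
    the denominator with a warning; an all-timeout batch raises.
    """
    validate_model(spec)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    X0, Y0 = int(X0), int(Y0)
    if X0 < 0 or Y0 < 0 or X0 + Y0 == 0:
        raise ValueError("need non-negative initial counts with X0 + Y0 > 0")
    if X0 == 0 or Y0 == 0:
        n_fixed = 0 if X0 == 0 else n_runs
        p_hat = float(n_fixed) / n_runs
        return FixationEstimate(
            n_runs=n_runs, n_fixed=n_fixed, n_timeout=0, p_hat=p_hat,
            ci_low=p_hat, ci_high=p_hat, ci_level=ci_level, seed=seed,
            spec=spec, x0=X0, y0=Y0,
        )
    seeds = _seed_words(seed, n_runs)
    n_fix, n_loss, n_to, _ = _kernels.ssa_batch(
        spec.a, spec.b, spec.c, spec.d,
        spec.beta_x, spec.beta_y, spec.gamma_x, spec.gamma_y, spec.M,
        X0, Y0, int(max_events), float(t_max), seeds,
    )
    n_eff = n_runs - n_to
    if n_eff == 0:
        raise RuntimeError("all replicates timed out; increase max_events or t_max")
    if n_to > 0:
        warnings.warn(
            f"{n_to}/{n_runs} replicates timed out and are excluded from the estimate",
            stacklevel=2,
        )
    p_hat = n_fix / n_eff
    lo, hi = proportion_confint(n_fix, n_eff, alpha=1.0 - ci_level, method="wilson")
    return FixationEstimate(
        n_runs=n_runs, n_fixed=int(n_fix), n_timeout=int(n_to), p_hat=float(p_hat),
        ci_low=float(lo), ci_high=float(hi), ci_level=ci_level, seed=seed,
        spec=spec, x0=X0, y0=Y0,
    )
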