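"""Numba-compiled inner loops for the jump-process and SDE simulators.

Each replicate owns one RNG stream seeded from a per-replicate word derived
outside; identical seeds reproduce identical trajectories bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# outcome codes shared with ssa.py
FIXATION = 0
LOSS = 1
TIMEOUT = 2


@njit(cache=False)
def ssa_run(a, b, c, d, beta_x, beta_y, gamma_x, gamma_y, M,
            X0, Y0, max_events, t_max, seed):
    """One exact-simulation replicate; returns (outcome, t, n_events, X, Y)."""
    np.random.seed(seed)
    X = X0
    Y = Y0
    t = 0.0
    n_ev = 0
    while X > 0 and Y > 0:
        if n_ev >= max_events:
            return TIMEOUT, t, n_ev, X, Y
        r0 = beta_x * X
        r1 = beta_y * Y
        r2 = gamma_x * X
        r3 = gamma_y * Y
        r4 = X * (X - 1) / (a * M)
        r5 = X * Y / (b * M)
        r6 = X * Y / (c * M)
        r7 = Y * (Y - 1) / (d * M)
        total = r0 + r1 + r2 + r3 + r4 + r5 + r6 + r7
        t += -np.log(np.random.random()) / total
        if t > t_max:
            return TIMEOUT, t_max, n_ev, X, Y
        u = np.random.random() * total
        if u < r0:
            X += 1
        elif u < r0 + r1:
            Y += 1
        elif u < r0 + r1 + r2:
            X -= 1
        elif u < r0 + r1 + r2 + r3:
            Y -= 1
        elif u < r0 + r1 + r2 + r3 + r4:
            X -= 1  # intra-mutant competition
        elif u < r0 + r1 + r2 + r3 + r4 + r5:
            X -= 1  # X+Y -> Y at 1/(bM)
        elif u < r0 + r1 + r2 + r3 + r4 + r5 + r6:
            Y -= 1  # X+Y -> X at 1/(cM)
        else:
            Y -= 1  # intra-wild-type competition
        n_ev += 1
    if Y == 0 and X > 0:
        return FIXATION, t, n_ev, X, Y
    return LOSS, t, n_ev, X, Y


@njit(cache=False)
def ssa_run_record(a, b, c, d, beta_x, beta_y, gamma_x, gamma_y, M,
                   X0, Y0, max_events, t_max, seed, thin, stop_on_boundary):
    """One replicate recording every ``thin``-th event (plus start and end).

    With ``stop_on_boundary`` the run ends when either count hits zero
    (absorption); without it the remaining monomorphic population keeps
    evolving until ``t_max``/``max_events`` or total extinction.  Returns
    (outcome, t, n_events, X, Y, ts, Xs, Ys) with record arrays trimmed to
    length.
    """
    np.random.seed(seed)
    cap = 4096
    ts = np.empty(cap)
    Xs = np.empty(cap, np.int64)
    Ys = np.empty(cap, np.int64)
    X = X0
    Y = Y0
    t = 0.0
    n_ev = 0
    n_rec = 0
    ts[0] = 0.0
    Xs[0] = X
    Ys[0] = Y
    n_rec = 1
    outcome = TIMEOUT
    while (X > 0 and Y > 0) or (stop_on_boundary == 0 and X + Y > 0):
        if n_ev >= max_events:
            outcome = TIMEOUT
            break
        r0 = beta_x * X
        r1 = beta_y * Y
        r2 = gamma_x * X
        r3 = gamma_y * Y
        r4 = X * (X - 1) / (a * M)
        r5 = X * Y / (b * M)
        r6 = X * Y / (c * M)
        r7 = Y * (Y - 1) / (d * M)
        total = r0 + r1 + r2 + r3 + r4 + r5 + r6 + r7
        t += -np.log(np.random.random()) / total
        if t > t_max:
            t = t_max
            outcome = TIMEOUT
            break
        u = np.random.random() * total
        if u < r0:
            X += 1
        elif u < r0 + r1:
            Y += 1
        elif u < r0 + r1 + r2:
            X -= 1
        elif u < r0 + r1 + r2 + r3:
            Y -= 1
        elif u < r0 + r1 + r2 + r3 + r4:
            X -= 1
        elif u < r0 + r1 + r2 + r3 + r4 + r5:
            X -= 1
        elif u < r0 + r1 + r2 + r3 + r4 + r5 + r6:
            Y -= 1
        else:
            Y -= 1
        n_ev += 1
        if stop_on_boundary == 1:
            absorbed = X == 0 or Y == 0
        else:
            absorbed = X + Y == 0
        if n_ev % thin == 0 or absorbed:
            if n_rec >= cap:
                cap *= 2
                ts2 = np.empty(cap)
                Xs2 = np.empty(cap, np.int64)
                Ys2 = np.empty(cap, np.int64)
                ts2[:n_rec] = ts[:n_rec]
                Xs2[:n_rec] = Xs[:n_rec]
                Ys2[:n_rec] = Ys[:n_rec]
                ts = ts2
                Xs = Xs2
                Ys = Ys2
            ts[n_rec] = t
            Xs[n_rec] = X
            Ys[n_rec] = Y
            n_rec += 1
        if absorbed:
            outcome = FIXATION if (Y == 0 and X > 0) else LOSS
            break
    return outcome, t, n_ev, X, Y, ts[:n_rec], Xs[:n_rec], Ys[:n_rec]


@njit(cache=False)
def ssa_batch(a, b, c, d, beta_x, beta_y, gamma_x, gamma_y, M,
              X0, Y0, max_events, t_max, seeds):
    """Independent replicates; returns (n_fixed, n_loss, n_timeout, total_events)."""
    n_fix = 0
    n_loss = 0
    n_to = 0
    tot_ev = 0
    for i in range(seeds.size):
        out, t, n_ev, X, Y = ssa_run(
            a, b, c, d, beta_x, beta_y, gamma_x, gamma_y, M,
            X0, Y0, max_events, t_max, seeds[i]
        )
        tot_ev += n_ev
        if out == FIXATION:
            n_fix += 1
        elif out == TIMEOUT:
            n_to += 1
        else:
            n_loss += 1
    return n_fix, n_loss, n_to, tot_ev


@njit(cache=False)
def sde_path(a, b, c, d, beta_x, beta_y, gamma_x, gamma_y, M,
             x0, y0, dt, n_steps, seed, record_every):
    """Euler-Maruyama path of the scaled-abundance SDE system.

    States are truncated at 0 and frozen there (absorbing).  Returns
    (t, x, y) arrays thinned to every ``record_every``-th step.
    """
    np.random.seed(seed)
    n_rec = n_steps // record_every + 1
    ts = np.empty(n_rec)
    xs = np.empty(n_rec)
    ys = np.empty(n_rec)
    x = x0
    y = y0
    ts[0] = 0.0
    xs[0] = x
    ys[0] = y
    sqdt = np.sqrt(dt)
    sqM = np.sqrt(M)
    k = 1
    for i in range(1, n_steps + 1):
        if x > 0.0:
            drift_x = x * ((beta_x - gamma_x) - x / a - y / b)
            noise_x = np.sqrt(x * (beta_x + gamma_x + x / a + y / b)) / sqM
            x = x + drift_x * dt + noise_x * sqdt * np.random.normal()
            if x <= 0.0:
                x = 0.0
        if y > 0.0:
            drift_y = y * ((beta_y - gamma_y) - x / c - y / d)
            noise_y = np.sqrt(y * (beta_y + gamma_y + x / c + y / d)) / sqM
            y = y + drift_y * dt + noise_y * sqdt * np.random.normal()
            if y <= 0.0:
                y = 0.0
        if i % record_every == 0:
            ts[k] = i * dt
            xs[k] = x
            ys[k] = y
            k += 1
    return ts[:k], xs[:k], ys[:k]


@njit(cache=False)
def sde_absorption_batch(a, b, c, d, beta_x, beta_y, gamma_x, gamma_y, M,
                         x0, y0, dt, max_steps, seeds):
    """Euler-Maruyama replicates run to absorption of either coordinate.

    Returns (n_x_fixed, n_y_fixed, n_timeout).
    """
    n_xf = 0
    n_yf = 0
    n_to = 0
    sqdt = np.sqrt(dt)
    sqM = np.sqrt(M)
    for r in range(seeds.size):
        np.random.seed(seeds[r])
        x = x0
        y = y0
        absorbed = False
        for _ in range(max_steps):
            drift_x = x * ((beta_x - gamma_x) - x / a - y / b)
            noise_x = np.sqrt(x * (beta_x + gamma_x + x / a + y / b)) / sqM
            x = x + drift_x * dt + noise_x * sqdt * np.random.normal()
            drift_y = y * ((beta_y - gamma_y) - x / c - y / d)
            noise_y = np.sqrt(y * (beta_y + gamma_y + x / c + y / d)) / sqM
            y = y + drift_y * dt + noise_y * sqdt * np.random.normal()
            if x <= 0.0:
                n_yf += 1
                absorbed = True
                break
            if y <= 0.0:
                n_xf += 1
                absorbed = True
                break
        if not absorbed:
            n_to += 1
    return n_xf, n_yf, n_to
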