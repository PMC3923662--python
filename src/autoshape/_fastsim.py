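"""Compiled fast path for engagement-curve simulation on the default task.

Parameter fitting evaluates thousands of candidate agents, so the trial loop
of :func:`autoshape.protocols.run_trial` is re-implemented here as a numba
kernel specialised to the default eight-state topology and the main
(planner + feature-value) variant, tracking only engagement flags.  It is an
optimisation of the same algorithm, not a second model: a statistical
equivalence test against the reference implementation guards it.

The kernel exploits that the default task is deterministic: each learned
transition row carries probability mass on a single successor, so the
model-based transition table reduces to one scalar per (state, action) and
one backward sweep of value iteration is exact.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# state indices: PRE=0 CS=1 CSL=2 CSM=3 CSE=4 USF=5 USC=6 END=7
# feature indices: 0=None 1=Lever 2=Magazine 3=Food
_N_ACT = np.array([1, 3, 1, 1, 1, 1, 1, 0], dtype=np.int64)
_NEXT = np.array([
    [1, 7, 7],   # PRE: exp -> CS
    [2, 3, 4],   # CS: goL, goM, exp
    [5, 7, 7],   # CSL: eng -> USF
    [6, 7, 7],   # CSM: eng -> USC
    [5, 7, 7],   # CSE: exp -> USF
    [6, 7, 7],   # USF: goM -> USC
    [7, 7, 7],   # USC: eat -> END
    [7, 7, 7],
], dtype=np.int64)
_FEAT = np.array([
    [0, 0, 0],
    [1, 2, 0],
    [1, 0, 0],
    [2, 0, 0],
    [0, 0, 0],
    [3, 0, 0],
    [3, 0, 0],
    [0, 0, 0],
], dtype=np.int64)
_SWEEP = np.array([6, 5, 4, 3, 2, 1, 0], dtype=np.int64)


@njit(cache=True)
def _agent_flags(omega, alpha, gamma, beta, u, v0m, v0f, r_food,
                 n_trials, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    V = np.zeros(4)
    V[2] = v0m
    V[3] = v0f
    m = np.zeros((8, 3))
    R = np.zeros((8, 3))
    Q = np.zeros((8, 3))
    lever = np.zeros(n_trials)
    magazine = np.zeros(n_trials)
    P = np.zeros(3)
    w = np.zeros(3)
    for t in range(n_trials):
        V[2] *= 1.0 - u
        s = 0
        went_lever = False
        went_mag = False
        while s != 7:
            na = _N_ACT[s]
            # integrated values
            qmax = Q[s, 0]
            for k in range(1, na):
                if Q[s, k] > qmax:
                    qmax = Q[s, k]
            pmax = -1e300
            for k in range(na):
                P[k] = omega * V[_FEAT[s, k]] + (1.0 - omega) * (Q[s, k] - qmax)
                if P[k] > pmax:
                    pmax = P[k]
            tot = 0.0
            for k in range(na):
                w[k] = np.exp((P[k] - pmax) / beta)
                tot += w[k]
            r01 = np.random.random() * tot
            a = na - 1
            acc = 0.0
            for k in range(na):
                acc += w[k]
                if r01 <= acc:
                    a = k
                    break
            s2 = _NEXT[s, a]
            rew = r_food if (s == 6 and a == 0) else 0.0
            if s == 1 and a == 0:
                went_lever = True
            elif s == 1 and a == 1:
                went_mag = True
            # feature-level TD update
            future = 0.0
            if s2 != 7:
                future = V[_FEAT[s2, 0]]
                for k in range(1, _N_ACT[s2]):
                    fv = V[_FEAT[s2, k]]
                    if fv > future:
                        future = fv
            f = _FEAT[s, a]
            delta = rew + gamma * future - V[f]
            if f != 0:
                V[f] += alpha * delta
            # model learning + one exact backward sweep
            m[s, a] += alpha * (1.0 - m[s, a])
            R[s, a] += alpha * (rew - R[s, a])
            for i in range(7):
                ss = _SWEEP[i]
                for k in range(_N_ACT[ss]):
                    nxt = _NEXT[ss, k]
                    q = R[ss, k]
                    if nxt != 7:
                        nq = Q[nxt, 0]
                        for k2 in range(1, _N_ACT[nxt]):
                            if Q[nxt, k2] > nq:
                                nq = Q[nxt, k2]
                        q += gamma * m[ss, k] * nq
                    Q[ss, k] = q
            s = s2
        lever[t] = 1.0 if went_lever else 0.0
        magazine[t] = 1.0 if went_mag else 0.0
    return lever, magazine


def simulate_agent_curves(config, n_agents: int, n_sessions: int,
                          trials_per_session: int, seed_key,
                          block_trials: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Per-agent engagement per block, shape (n_agents, n_blocks)."""
    n_trials = n_sessions * trials_per_session
    n_blocks = n_trials // block_trials
    lev = np.zeros((n_agents, n_blocks))
    mag = np.zeros((n_agents, n_blocks))
    base = np.random.SeedSequence(list(seed_key)).generate_state(n_agents)
    for ai in range(n_agents):
        lf, mf = _agent_flags(
            config.omega, config.alpha, config.gamma, config.beta, config.u,
            config.v0_magazine, config.v0_food, config.r_food,
            n_trials, int(base[ai] % (2**31 - 1)),
        )
        lev[ai] = lf[: n_blocks * block_trials].reshape(n_blocks, block_trials).mean(axis=1)
        mag[ai] = mf[: n_blocks * block_trials].reshape(n_blocks, block_trials).mean(axis=1)
    return lev, mag


def simulate_group_curves(config, n_agents: int, n_sessions: int,
                          trials_per_session: int, seed_key,
                          block_trials: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Mean lever / magazine engagement per block for one group."""
    lev, mag = simulate_agent_curves(config, n_agents, n_sessions,
                                     trials_per_session, seed_key, block_trials)
    return lev.mean(axis=0), mag.mean(axis=0)
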