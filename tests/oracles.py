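"""Independent oracles used by the test suite.

These deliberately avoid the package's own update machinery: the SSA is a
textbook Gillespie direct method over state counts, the CTMC marginals
come from the matrix exponential, and mass action is integrated with
scipy's ODE solver.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm


def rate_matrix(scheme) -> np.ndarray:
    """Generator matrix Q (1/s) of a unimolecular-only scheme."""
    idx = {s: i for i, s in enumerate(scheme.states)}
    n = len(scheme.states)
    Q = np.zeros((n, n))
    for t in scheme.transitions:
        if t.order != 1:
            raise ValueError("oracle requires a clamped (unimolecular) scheme")
        Q[idx[t.source], idx[t.target]] += t.rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def ctmc_marginals(scheme, t_grid_s) -> np.ndarray:
    """Exact state-occupancy probabilities at the requested times."""
    Q = rate_matrix(scheme)
    idx = {s: i for i, s in enumerate(scheme.states)}
    p0 = np.zeros(len(scheme.states))
    p0[idx[scheme.initial_state]] = 1.0
    return np.array([p0 @ expm(Q * t) for t in t_grid_s])


def gillespie_counts(scheme, n_molecules, t_grid_s, rng) -> np.ndarray:
    """Direct-method SSA over a population of identical CTMC molecules.

    Returns state counts sampled at ``t_grid_s`` (shape [n_times, n_states]).
    """
    idx = {s: i for i, s in enumerate(scheme.states)}
    edges = [(idx[t.source], idx[t.target], t.rate) for t in scheme.transitions
             if t.rate > 0]
    counts = np.zeros(len(scheme.states), dtype=np.int64)
    counts[idx[scheme.initial_state]] = n_molecules
    out = np.zeros((len(t_grid_s), len(scheme.states)), dtype=np.int64)
    t = 0.0
    k = 0
    t_grid_s = np.asarray(t_grid_s, dtype=float)
    while k < len(t_grid_s):
        props = np.array([r * counts[s] for s, _, r in edges])
        a0 = props.sum()
        if a0 <= 0:
            while k < len(t_grid_s):
                out[k] = counts
                k += 1
            break
        t_next = t + rng.exponential(1.0 / a0)
        while k < len(t_grid_s) and t_grid_s[k] < t_next:
            out[k] = counts
            k += 1
        j = rng.choice(len(edges), p=props / a0)
        s, tgt, _ = edges[j]
        counts[s] -= 1
        counts[tgt] += 1
        t = t_next
    return out


def mass_action_binding(kon, volume_nm3, n_G0, n_R0, t_grid_s, avogadro=6.02214076e23):
    """Deterministic A + B association in a closed volume: bound(t)."""
    kv = kon / (avogadro * volume_nm3 * 1e-24)  # per molecule-pair rate, 1/s

    def rhs(t, y):
        G, R = y
        return [-kv * G * R, -kv * G * R]

    sol = solve_ivp(rhs, [0, max(t_grid_s)], [n_G0, n_R0], dense_output=True,
                    rtol=1e-10, atol=1e-12)
    return np.array([n_R0 - sol.sol(t)[1] for t in t_grid_s])
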