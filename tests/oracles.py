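"""Independent reference implementations used only to check the package.

These deliberately trade efficiency for transparency: brute-force window
enumeration for the survival estimator, a stochastic Gillespie walker
simulation for the route ODEs, and a closed-form irreversible-chain
solution.  They share no code with the implementations they validate.
"""

from __future__ import annotations

import numpy as np


def survival_window_enumeration(starts, lengths, m):
    """Brute-force survival probability: enumerate every (i, j) window.

    Returns an array p[j-1] for j = 1..m, averaging N(i,j)/N(i,1) over all
    window starts i = 1..m-j+1 with N(i,1) > 0; NaN where no window start
    has occupancy.
    """
    starts = np.asarray(starts)
    ends = starts + np.asarray(lengths) - 1
    p = np.full(m, np.nan)
    for j in range(1, m + 1):
        ratios = []
        for i in range(1, m - j + 2):
            n1 = int(np.sum((starts <= i) & (ends >= i)))
            if n1 == 0:
                continue
            nij = int(np.sum((starts <= i) & (ends >= i + j - 1)))
            ratios.append(nij / n1)
        if ratios:
            p[j - 1] = float(np.mean(ratios))
    return p


def gillespie_absorption_times(R, p0, t_max, n_walkers, rng):
    """Continuous-time Markov walkers on generator R (R[dst, src] convention).

    Returns each walker's absorption time into the last (absorbing) state,
    inf if not absorbed by t_max.  Vectorized over walkers grouped by state.
    """
    n_states = R.shape[0]
    absorbing = n_states - 1
    state = rng.choice(n_states, size=n_walkers, p=p0)
    t = np.zeros(n_walkers)
    absorbed_at = np.full(n_walkers, np.inf)
    active = (state != absorbing) & (t < t_max)
    absorbed_at[state == absorbing] = 0.0
    while np.any(active):
        for s in range(n_states - 1):
            sel = active & (state == s)
            if not np.any(sel):
                continue
            total = -R[s, s]
            if total <= 0:
                active[sel] = False  # stuck state: never leaves
                continue
            n_sel = int(sel.sum())
            t[sel] += rng.exponential(1.0 / total, size=n_sel)
            probs = R[:, s].copy()
            probs[s] = 0.0
            probs = probs / total
            state[sel] = rng.choice(n_states, size=n_sel, p=probs)
        newly_absorbed = active & (state == absorbing)
        absorbed_at[newly_absorbed] = t[newly_absorbed]
        active &= (state != absorbing) & (t < t_max)
    return absorbed_at


def irreversible_chain_completion(ks, t):
    """Completion fraction of an irreversible chain with distinct rates.

    For rates k_1..k_n the absorbed fraction is
    1 - sum_i [prod_{j != i} k_j/(k_j - k_i)] exp(-k_i t).
    """
    ks = np.asarray(ks, dtype=float)
    t = np.asarray(t, dtype=float)
    out = np.ones_like(t)
    for i, ki in enumerate(ks):
        coef = np.prod([kj / (kj - ki) for j, kj in enumerate(ks) if j != i])
        out = out - coef * np.exp(-ki * t)
    return out
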