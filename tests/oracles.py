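"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most transparent route
available — exhaustive enumeration and flood fill — and share no code
with the implementation they check.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def flood_fill_clusters(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """4-connected components of a boolean mask on a periodic lattice,
    by breadth-first flood fill."""
    n_rows, n_cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    out: list[set[tuple[int, int]]] = []
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if mask[r0, c0] and not seen[r0, c0]:
                comp = set()
                q = deque([(r0, c0)])
                seen[r0, c0] = True
                while q:
                    r, c = q.popleft()
                    comp.add((r, c))
                    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                        rr, cc = (r + dr) % n_rows, (c + dc) % n_cols
                        if mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            q.append((rr, cc))
                out.append(comp)
    return out


# ---------------------------------------------------------------------------
# Exact stationary distribution of the 2x2-lattice, 2-integrin Markov chain.
#
# The chain is enumerated state by state: for each ordered configuration
# ((site0, state0), (site1, state1)) all stochastic branches of one sweep
# are expanded analytically — the 2 update orders, every reaction/diffusion
# outcome of each integrin in turn (with the second integrin's branches
# conditioned on the first one's outcome), and the deterministic orphan
# cleanup.  The stationary vector comes from the left null space of P - I.

SITES_2X2 = [(0, 0), (0, 1), (1, 0), (1, 1)]


def _adjacent(a: tuple[int, int], b: tuple[int, int]) -> bool:
    # 2x2 periodic: 4-neighbours collapse to one vertical + one horizontal
    return (a[0] != b[0]) ^ (a[1] != b[1])


def _diffusion_targets(site: tuple[int, int]) -> list[tuple[int, int]]:
    r, c = site
    return [((r + 1) % 2, c), (r, (c + 1) % 2)]  # each drawn w.p. 1/2


def _cleanup(cfg):
    (s0, st0), (s1, st1) = cfg
    if st0 == 3 and not (st1 == 3 and _adjacent(s0, s1)):
        st0 = 2
    if st1 == 3 and not (st0 == 3 and _adjacent(s0, s1)):
        st1 = 2
    return ((s0, st0), (s1, st1))


def _update_one(cfg, idx, probs):
    """Branches of one integrin's update: list of (new_cfg, probability)."""
    p_act, p_inact, p_bind, p_unbind, p_assoc, p_disassoc = probs
    me = list(cfg[idx])
    other = cfg[1 - idx]
    site, st = tuple(me[0]), me[1]
    o_site, o_st = other

    def with_state(new_st, new_site=None):
        entry = (new_site or site, new_st)
        return (entry, other) if idx == 0 else (other, entry)

    branches = []
    p_no_event = 1.0
    if st == 0:
        branches.append((with_state(1), p_act))
        p_no_event -= p_act
    elif st == 1:
        branches.append((with_state(0), p_inact))
        branches.append((with_state(2), p_bind))
        p_no_event -= p_inact + p_bind
    elif st == 2:
        branches.append((with_state(1), p_unbind))
        p_no_event -= p_unbind
        eligible = _adjacent(site, o_site) and o_st in (2, 3)
        if eligible:
            if o_st == 3:
                branches.append((with_state(3), p_assoc))
            else:  # recruit the bound neighbour: both become associated
                pair = with_state(3)
                pair = ((pair[0][0], 3), (pair[1][0], 3))
                branches.append((pair, p_assoc))
            p_no_event -= p_assoc
    else:
        branches.append((with_state(2), p_disassoc))
        p_no_event -= p_disassoc

    # no reaction: diffusion attempt unless associated
    if st == 3:
        branches.append((cfg, p_no_event))
    else:
        for tgt in _diffusion_targets(site):
            if tgt == o_site:
                branches.append((cfg, p_no_event / 2.0))  # rejected hop
            else:
                branches.append((with_state(st, new_site=tgt), p_no_event / 2.0))
    return branches


def all_configs():
    cfgs = []
    for s0, s1 in itertools.permutations(SITES_2X2, 2):
        for st0 in range(4):
            for st1 in range(4):
                cfgs.append(((s0, st0), (s1, st1)))
    return cfgs


def transition_row(cfg, probs):
    """Distribution over next configurations after one full sweep."""
    out: dict = {}
    for order in ((0, 1), (1, 0)):
        for mid, p1 in _update_one(cfg, order[0], probs):
            for end, p2 in _update_one(mid, order[1], probs):
                final = _cleanup(end)
                w = 0.5 * p1 * p2
                if w > 0:
                    out[final] = out.get(final, 0.0) + w
    return out


def stationary_distribution(probs) -> dict:
    cfgs = all_configs()
    index = {c: i for i, c in enumerate(cfgs)}
    n = len(cfgs)
    P = np.zeros((n, n))
    for c in cfgs:
        for nxt, w in transition_row(c, probs).items():
            P[index[c], index[nxt]] += w
    assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
    # left eigenvector for eigenvalue 1
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return {c: pi[i] for c, i in index.items()}


def category(cfg) -> tuple:
    """Observable used for the occupancy comparison: the sorted state pair
    plus whether the two integrins sit on adjacent sites."""
    (s0, st0), (s1, st1) = cfg
    return (tuple(sorted((st0, st1))), _adjacent(s0, s1))


def category_distribution(probs) -> dict:
    dist: dict = {}
    for cfg, p in stationary_distribution(probs).items():
        k = category(cfg)
        dist[k] = dist.get(k, 0.0) + p
    return dist
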