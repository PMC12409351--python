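"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by exhaustive enumeration rather
than calling the library's own algorithms.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np

from panphage.io_formats import Phylogeny


def fitch_min_changes(tree: Phylogeny, leaf_states: dict[str, int]) -> int:
    """Minimum number of state-changing branches over all internal labelings."""
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf[i]]
    best = None
    for bits in itertools.product((0, 1), repeat=len(internal)):
        states = {}
        for i, b in zip(internal, bits):
            states[i] = b
        for i in tree.leaf_indices:
            states[int(i)] = leaf_states[tree.names[i]]
        changes = sum(
            1
            for i in range(1, tree.n_nodes)
            if states[i] != states[int(tree.parent[i])]
        )
        if best is None or changes < best:
            best = changes
    return best


def exact_null_tails(
    weights: np.ndarray,
    gain_branches: set[int],
    loss_branches: set[int],
    k_gain: int,
    k_loss: int,
) -> tuple[dict[int, float], dict[int, float]]:
    """Exact tail probabilities P(score >= s) of the placement null.

    Enumerates every ordered draw of k distinct positive-weight branches
    with sequential probability w_i / (remaining weight), and every
    equally likely assignment of which drawn branches are gains. Returns
    (simultaneous tails, dissociation tails) as {s: P(score >= s)}.
    """
    k = k_gain + k_loss
    positive = [i for i, w in enumerate(weights) if w > 0]
    total = float(sum(weights[i] for i in positive))
    sim_pmf: dict[int, float] = {}
    dis_pmf: dict[int, float] = {}
    n_assign = comb(k, k_gain)
    for perm in itertools.permutations(positive, k):
        p = 1.0
        rem = total
        for b in perm:
            p *= weights[b] / rem
            rem -= weights[b]
        for gain_pos in itertools.combinations(range(k), k_gain):
            chosen_g = {perm[i] for i in gain_pos}
            chosen_l = set(perm) - chosen_g
            w = p / n_assign
            sim = len(chosen_g & gain_branches) + len(chosen_l & loss_branches)
            dis = len(chosen_g & loss_branches) + len(chosen_l & gain_branches)
            sim_pmf[sim] = sim_pmf.get(sim, 0.0) + w
            dis_pmf[dis] = dis_pmf.get(dis, 0.0) + w

    def tails(pmf: dict[int, float]) -> dict[int, float]:
        smax = max(pmf)
        out = {}
        acc = 0.0
        for s in range(smax, -1, -1):
            acc += pmf.get(s, 0.0)
            out[s] = acc
        return out

    return tails(sim_pmf), tails(dis_pmf)


def bh_stepup(p: list[float], m: int) -> list[float]:
    """Literal Benjamini-Hochberg step-up, computed from the definition."""
    order = sorted(range(len(p)), key=lambda i: p[i])
    q = [0.0] * len(p)
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(p[j] * m / (order.index(j) + 1) for j in order[rank_pos - 1 :]), 1.0
        )
    return q
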