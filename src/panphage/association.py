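"""Phylogeny-aware co-occurrence testing of entity pairs.

Two entities are *associated* when their gain/loss events coincide on the
same branches more often than expected under neutral, independent
evolution, and *dissociated* when opposite-direction events coincide. The
observed statistic for a pair is

* simultaneous score: number of branches carrying a gain for both entities
  plus branches carrying a loss for both;
* dissociation score: number of branches where one entity gains and the
  other loses.

The null distribution is obtained by conditional simulation: one entity's
events are held fixed, the other's observed numbers of gains and losses
are kept but their branch locations are redrawn without replacement with
probability proportional to branch length, and event-type labels are
assigned uniformly at random to the drawn branches. Empirical one-sided
p-values use add-one smoothing, p = (1 + #{null >= observed}) / (g + 1),
and are corrected per score type by Benjamini-Hochberg with the family
size counting every eligible pair (score-0 pairs enter with p = 1).

Simulated placements are cached per (n_gains, n_losses) configuration and
scored distributions per (fixed-event-set signature, n_gains, n_losses),
with per-cache-key seed substreams derived from the master seed, so runs
are reproducible and independent of pair iteration order.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestral import EventHistory
from .io_formats import Phylogeny

logger = logging.getLogger(__name__)

SCORE_ASSOCIATION = "association"
SCORE_DISSOCIATION = "dissociation"
COINCIDENCE_MODES = (SCORE_ASSOCIATION, SCORE_DISSOCIATION, "both")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the association analysis.

    ``null_samples`` is the number of simulated placements per cached null
    configuration; ``min_events`` excludes entities gained/lost fewer times
    than required for a detectable repeated pattern; ``ancestral_confidence``
    is reserved for a future probabilistic reconstruction mode and has no
    effect under parsimony.
    """

    null_samples: int = 50000
    coincidence: str = "both"
    fdr_alpha: float = 0.05
    min_events: int = 2
    seed: int = 0
    ancestral_confidence: float = 0.999

    def __post_init__(self) -> None:
        if self.null_samples < 100:
            raise ValueError("null_samples must be >= 100")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")
        if self.coincidence not in COINCIDENCE_MODES:
            raise ValueError(f"coincidence must be one of {COINCIDENCE_MODES}")

    @property
    def score_types(self) -> tuple[str, ...]:
        if self.coincidence == "both":
            return (SCORE_ASSOCIATION, SCORE_DISSOCIATION)
        return (self.coincidence,)


@dataclass
class AssociationResult:
    """One tested entity pair for one score type."""

    entity_a: str
    entity_b: str
    category_a: str
    category_b: str
    score_type: str
    observed_score: int
    p_value: float
    q_value: float
    significant: bool


# ---------------------------------------------------------------------------
# observed scores
# ---------------------------------------------------------------------------

Events = Iterable[tuple[str, str]]


def _split(ev: Events) -> tuple[set, set]:
    gains = {b for b, t in ev if t == "gain"}
    losses = {b for b, t in ev if t == "loss"}
    return gains, losses


def simultaneous_score(ev_i: Events, ev_j: Events) -> int:
    """Branches where both entities gain plus branches where both lose."""
    gi, li = _split(ev_i)
    gj, lj = _split(ev_j)
    return len(gi & gj) + len(li & lj)


def dissociation_score(ev_i: Events, ev_j: Events) -> int:
    """Branches where one entity gains and the other loses."""
    gi, li = _split(ev_i)
    gj, lj = _split(ev_j)
    return len(gi & lj) + len(li & gj)


# ---------------------------------------------------------------------------
# simulated null
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Empirical null score distribution from g simulated placements.

    Both score types are computed from the same placement samples and
    stored as tail-friendly count vectors (``sim_counts[s]`` = number of
    samples with simultaneous score s).
    """

    sim_counts: np.ndarray
    dis_counts: np.ndarray
    g: int

    def pvalue(self, observed: int, score_type: str = SCORE_ASSOCIATION) -> float:
        counts = self.sim_counts if score_type == SCORE_ASSOCIATION else self.dis_counts
        tail = int(counts[min(observed, counts.size) :].sum()) if observed < counts.size else 0
        if observed <= 0:
            tail = self.g
        return (1 + tail) / (self.g + 1)


def _substream_seed(master: int, *key) -> int:
    digest = hashlib.sha256(repr((int(master),) + tuple(key)).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _positive_branches(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    idx = np.flatnonzero(tree.blen[1:] > 0) + 1  # node indices with a branch above
    return idx, tree.blen[idx]


def sample_placements(
    tree: Phylogeny, k_gain: int, k_loss: int, g: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate g random placements of k_gain + k_loss events on the tree.

    Branches are drawn without replacement with probability proportional to
    branch length (zero-length branches are never drawn); which of the drawn
    branches carry gains is uniform over all subsets of size ``k_gain``.
    Returns ``branches`` (g, k) node indices of the drawn branches and
    ``gain_mask`` (g, k) marking which of them carry gains.
    """
    k = k_gain + k_loss
    if k < 1:
        raise ValueError("at least one event is required")
    idx, w = _positive_branches(tree)
    if k > idx.size:
        raise ValueError(
            f"cannot place {k} events on {idx.size} positive-length branches"
        )
    rng = np.random.default_rng(seed)
    # Gumbel top-k == sequential weighted sampling without replacement
    keys = np.log(w)[None, :] + rng.gumbel(size=(g, idx.size))
    chosen = np.argpartition(-keys, k - 1, axis=1)[:, :k]  # positions into idx
    branches = idx[chosen].astype(np.int32)  # (g, k) node indices

    gain_mask = np.zeros((g, k), dtype=bool)
    if 0 < k_gain < k:
        u = rng.random((g, k))
        order = np.argsort(u, axis=1)
        np.put_along_axis(gain_mask, order[:, :k_gain], True, axis=1)
    elif k_gain == k:
        gain_mask[:] = True
    return branches, gain_mask


def _score_placements(
    branches: np.ndarray,
    gain_mask: np.ndarray,
    gain_lookup: np.ndarray,
    loss_lookup: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneous/dissociation scores of each placement against fixed events.

    ``gain_lookup``/``loss_lookup`` are boolean per-node indicators of the
    fixed entity's gain and loss branches.
    """
    hit_gain = gain_lookup[branches]  # (g, k): drawn branch is a fixed gain
    hit_loss = loss_lookup[branches]
    sim = (hit_gain & gain_mask).sum(axis=1) + (hit_loss & ~gain_mask).sum(axis=1)
    dis = (hit_loss & gain_mask).sum(axis=1) + (hit_gain & ~gain_mask).sum(axis=1)
    return sim, dis


def null_distribution(
    ev_i: Events,
    k_gain_j: int,
    k_loss_j: int,
    tree: Phylogeny,
    g: int,
    seed: int,
) -> NullDistribution:
    """Null score distribution of a pair: ev_i fixed, j's events redrawn.

    ``ev_i`` is a set of (branch_id, "gain"|"loss") as produced by
    :meth:`EventHistory.events_of`.
    """
    name_to_node = {tree.node_name(i): i for i in range(tree.n_nodes)}
    gi, li = _split(ev_i)
    gain_lookup = np.zeros(tree.n_nodes, dtype=bool)
    loss_lookup = np.zeros(tree.n_nodes, dtype=bool)
    gain_lookup[[name_to_node[b] for b in gi]] = True
    loss_lookup[[name_to_node[b] for b in li]] = True
    branches, gain_mask = sample_placements(tree, k_gain_j, k_loss_j, g, seed)
    sim, dis = _score_placements(branches, gain_mask, gain_lookup, loss_lookup)
    return NullDistribution(
        sim_counts=np.bincount(sim), dis_counts=np.bincount(dis), g=g
    )


def pair_pvalue(
    observed: int,
    null: NullDistribution | Sequence[int],
    g: int | None = None,
    score_type: str = SCORE_ASSOCIATION,
) -> float:
    """One-sided add-one-smoothed empirical p-value.

    p = (1 + #{null samples with score >= observed}) / (g + 1). ``null``
    may be a :class:`NullDistribution` or a raw sequence of g null scores.
    """
    if isinstance(null, NullDistribution):
        return null.pvalue(observed, score_type)
    scores = np.asarray(null)
    g = scores.size if g is None else g
    return (1 + int((scores >= observed).sum())) / (g + 1)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def bh_adjust(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1.

    ``m`` is the total number of hypotheses in the family and may exceed
    ``len(p_values)`` when untested-but-counted pairs are part of the
    family; by default m = len(p_values).
    """
    p = np.asarray(p_values, dtype=np.float64)
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError("m must be >= number of p-values")
    if n == 0:
        return np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# full pairwise analysis
# ---------------------------------------------------------------------------


class _NullCache:
    """Two-level cache: placements per (kg, kl), scored nulls per pair key."""

    def __init__(self, tree: Phylogeny, g: int, master_seed: int) -> None:
        self.tree = tree
        self.g = g
        self.master_seed = master_seed
        self._placements: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        self._nulls: dict[tuple, NullDistribution] = {}

    def placements(self, kg: int, kl: int) -> tuple[np.ndarray, np.ndarray]:
        key = (kg, kl)
        if key not in self._placements:
            seed = _substream_seed(self.master_seed, "placement", kg, kl)
            self._placements[key] = sample_placements(self.tree, kg, kl, self.g, seed)
        return self._placements[key]

    def null(
        self,
        sig: tuple,
        gain_lookup: np.ndarray,
        loss_lookup: np.ndarray,
        kg: int,
        kl: int,
    ) -> NullDistribution:
        key = (sig, kg, kl)
        if key not in self._nulls:
            branches, gain_mask = self.placements(kg, kl)
            sim, dis = _score_placements(branches, gain_mask, gain_lookup, loss_lookup)
            self._nulls[key] = NullDistribution(
                sim_counts=np.bincount(sim), dis_counts=np.bincount(dis), g=self.g
            )
        return self._nulls[key]


def test_all_pairs(
    events: EventHistory,
    categories: Mapping[str, str],
    tree: Phylogeny,
    cfg: AnalysisConfig,
) -> list[AssociationResult]:
    """Test every unordered pair of eligible entities for co-occurrence.

    Entities with fewer than ``cfg.min_events`` events are excluded. Pairs
    with observed score 0 receive p = 1 without simulation; all eligible
    pairs count towards the BH family of their score type. The entity that
    sorts first lexicographically is held fixed in the null while the
    other's events are redrawn, so results are symmetric in the pair.
    """
    counts = events.counts()
    keep = np.flatnonzero(counts >= cfg.min_events)
    if keep.size < 2:
        logger.warning(
            "fewer than two entities with >= %d events; nothing to test",
            cfg.min_events,
        )
        return []
    order = sorted(keep, key=lambda i: events.entity_ids[i])
    ids = [events.entity_ids[i] for i in order]
    G = events.gains[order].astype(np.int32)
    L = events.losses[order].astype(np.int32)
    S = G @ G.T + L @ L.T
    D = G @ L.T + L @ G.T
    kg = G.sum(axis=1)
    kl = L.sum(axis=1)
    gain_lookup = events.gains[order]
    loss_lookup = events.losses[order]
    sigs = [
        (
            tuple(np.flatnonzero(gain_lookup[i]).tolist()),
            tuple(np.flatnonzero(loss_lookup[i]).tolist()),
        )
        for i in range(len(order))
    ]

    cache = _NullCache(tree, cfg.null_samples, cfg.seed)
    n = len(order)
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    want_assoc = SCORE_ASSOCIATION in cfg.score_types
    want_dis = SCORE_DISSOCIATION in cfg.score_types

    p_assoc = np.ones(len(pairs))
    p_dis = np.ones(len(pairs))
    for ipair, (a, b) in enumerate(pairs):
        obs_s = int(S[a, b])
        obs_d = int(D[a, b])
        need_s = want_assoc and obs_s > 0
        need_d = want_dis and obs_d > 0
        if not (need_s or need_d):
            continue
        null = cache.null(sigs[a], gain_lookup[a], loss_lookup[a], int(kg[b]), int(kl[b]))
        if need_s:
            p_assoc[ipair] = null.pvalue(obs_s, SCORE_ASSOCIATION)
        if need_d:
            p_dis[ipair] = null.pvalue(obs_d, SCORE_DISSOCIATION)

    results: list[AssociationResult] = []
    for score_type, pvec, obs_mat in (
        (SCORE_ASSOCIATION, p_assoc, S),
        (SCORE_DISSOCIATION, p_dis, D),
    ):
        if score_type not in cfg.score_types:
            continue
        q = bh_adjust(pvec, m=len(pairs))
        for ipair, (a, b) in enumerate(pairs):
            results.append(
                AssociationResult(
                    entity_a=ids[a],
                    entity_b=ids[b],
                    category_a=categories[ids[a]],
                    category_b=categories[ids[b]],
                    score_type=score_type,
                    observed_score=int(obs_mat[a, b]),
                    p_value=float(pvec[ipair]),
                    q_value=float(q[ipair]),
                    significant=bool(q[ipair] <= cfg.fdr_alpha),
                )
            )
    return results


_SHORT = {"bacterial_gene": "gene", "phage": "phage", "phage_gene": "phagegene"}


def summarize_results(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Count significant pairs per unordered category pair and score type."""
    rows: dict[tuple[str, str], int] = {}
    for r in results:
        if not r.significant:
            continue
        pair = "-".join(sorted((_SHORT[r.category_a], _SHORT[r.category_b])))
        key = (r.score_type, pair)
        rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [(st, pair, n) for (st, pair), n in sorted(rows.items())],
        columns=["score_type", "category_pair", "significant_pairs"],
    )
    return df
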