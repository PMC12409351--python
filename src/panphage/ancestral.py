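"""Ancestral presence/absence reconstruction and gain/loss event extraction.

For every entity (bacterial gene, phage infection pattern or phage gene
family) the presence state at internal nodes of the strain phylogeny is
reconstructed by Fitch small parsimony, and each branch on which the state
changes is recorded as a gain (0 -> 1) or loss (1 -> 0) event. These event
sets are what the association test scores.

The reconstruction is deterministic: ambiguity at the root resolves to
*absent* (accessory genes and phage susceptibilities are typically rare and
derived states), and each internal node inherits its parent's state
whenever that state is parsimony-optimal for it. Polytomies are resolved
into caterpillars of zero-length branches beforehand; since zero-length
branches carry zero weight in the association null, artificial edges can
never host simulated events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import Phylogeny, PresenceMatrix, ValidationError


@dataclass
class AncestralStates:
    """Per-entity binary state for every node of the tree.

    ``states`` has shape (n_entities, n_nodes); node columns follow the
    tree's preorder indexing. Leaf columns equal the observed matrix.
    """

    entity_ids: list[str]
    states: np.ndarray
    tree: Phylogeny

    def states_of(self, entity_id: str) -> dict[str, int]:
        row = self.states[self.entity_ids.index(entity_id)]
        return {self.tree.node_name(i): int(row[i]) for i in range(self.tree.n_nodes)}


@dataclass
class EventHistory:
    """Per-entity gain/loss events, one boolean per (entity, branch).

    A branch is identified by the node below it; column 0 (the root, which
    has no branch above it) is always False. At most one event per branch
    per entity holds by construction, and the number of events equals the
    entity's parsimony score.
    """

    entity_ids: list[str]
    gains: np.ndarray  # bool (n_entities, n_nodes)
    losses: np.ndarray  # bool (n_entities, n_nodes)
    tree: Phylogeny

    def events_of(self, entity_id: str) -> set[tuple[str, str]]:
        i = self.entity_ids.index(entity_id)
        out: set[tuple[str, str]] = set()
        for j in np.flatnonzero(self.gains[i]):
            out.add((self.tree.node_name(int(j)), "gain"))
        for j in np.flatnonzero(self.losses[i]):
            out.add((self.tree.node_name(int(j)), "loss"))
        return out

    def counts(self) -> np.ndarray:
        """Total number of events (parsimony score) per entity."""
        return self.gains.sum(axis=1) + self.losses.sum(axis=1)

    def write_tsv(self, path) -> None:
        """Dump per-entity events as entity / branch / event_type rows."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("entity\tbranch\tevent_type\n")
            for i, eid in enumerate(self.entity_ids):
                for j in range(1, self.tree.n_nodes):
                    if self.gains[i, j]:
                        fh.write(f"{eid}\t{self.tree.node_name(j)}\tgain\n")
                    elif self.losses[i, j]:
                        fh.write(f"{eid}\t{self.tree.node_name(j)}\tloss\n")


# ---------------------------------------------------------------------------
# tree preparation
# ---------------------------------------------------------------------------


def resolve_polytomies(tree: Phylogeny) -> Phylogeny:
    """Return a strictly binary tree, deterministically.

    Each polytomy is expanded into a caterpillar of zero-length branches,
    combining children two at a time in lexicographic order of their labels
    (an internal child is labelled by its smallest descendant leaf).
    Unifurcations are suppressed, adding their branch lengths. Already
    binary trees are returned unchanged (same object).
    """
    if tree.is_binary():
        return tree

    # mutable nested representation: [name, blen, children]
    def build(i: int) -> list:
        return [tree.names[i], float(tree.blen[i]), [build(c) for c in tree.children[i]]]

    root = build(0)

    def min_leaf(node: list) -> str:
        if not node[2]:
            return node[0]
        return min(min_leaf(c) for c in node[2])

    def fix(node: list) -> list:
        node[2] = [fix(c) for c in node[2]]
        while len(node[2]) == 1:  # suppress unifurcation
            child = node[2][0]
            node[0], node[2] = child[0], child[2]
            node[1] += child[1]
        if len(node[2]) > 2:
            kids = sorted(node[2], key=min_leaf)
            current = kids[0]
            for nxt in kids[1:-1]:
                current = [None, 0.0, [current, nxt]]
            node[2] = [current, kids[-1]]
        return node

    root = fix(root)

    parent: list[int] = []
    blen: list[float] = []
    names: list[str | None] = []

    def emit(node: list, parent_idx: int) -> None:
        i = len(parent)
        parent.append(parent_idx)
        blen.append(node[1] if parent_idx >= 0 else 0.0)
        names.append(node[0] if not node[2] else None)
        for c in node[2]:
            emit(c, i)

    emit(root, -1)
    return Phylogeny(parent, blen, names)


# ---------------------------------------------------------------------------
# Fitch reconstruction
# ---------------------------------------------------------------------------


def reconstruct_fitch(m: PresenceMatrix, tree: Phylogeny) -> AncestralStates:
    """Two-pass Fitch small parsimony for all entities at once.

    Bottom-up, each node's candidate state set is the intersection of its
    children's sets when non-empty, otherwise their union. Top-down, the
    root takes 0 when ambiguous, and every other node takes its parent's
    state when that state is in its set, otherwise its set's unique state.
    The assignment attains the minimum parsimony score for every entity.
    """
    if not tree.is_binary():
        raise ValidationError("tree must be binary; call resolve_polytomies first")
    leaf_idx = tree.leaf_indices
    labels = [tree.names[i] for i in leaf_idx]
    if set(labels) != set(m.strain_ids):
        diff = sorted(set(labels) ^ set(m.strain_ids))
        raise ValidationError(f"tree leaves and matrix strains differ: {diff}")

    n_ent, n_nodes = m.n_entities, tree.n_nodes
    col_of = {s: j for j, s in enumerate(m.strain_ids)}
    # candidate sets as 2-bit masks: bit0 = state 0 possible, bit1 = state 1
    mask = np.zeros((n_ent, n_nodes), dtype=np.uint8)
    for i, label in zip(leaf_idx, labels):
        obs = m.values[:, col_of[label]]
        mask[:, i] = np.where(obs == 1, 2, 1)

    for i in range(n_nodes - 1, -1, -1):  # preorder reversed = valid postorder
        kids = tree.children[i]
        if not kids:
            continue
        acc_and = np.full(n_ent, 3, dtype=np.uint8)
        acc_or = np.zeros(n_ent, dtype=np.uint8)
        for c in kids:
            acc_and &= mask[:, c]
            acc_or |= mask[:, c]
        mask[:, i] = np.where(acc_and != 0, acc_and, acc_or)

    states = np.zeros((n_ent, n_nodes), dtype=np.uint8)
    states[:, 0] = np.where(mask[:, 0] & 1, 0, 1)  # root ambiguity -> absent
    for i in range(1, n_nodes):
        sp = states[:, tree.parent[i]]
        keep = (mask[:, i] >> sp) & 1  # parent's state is in this node's set
        states[:, i] = np.where(keep, sp, np.where(mask[:, i] == 2, 1, 0))

    return AncestralStates(entity_ids=list(m.entity_ids), states=states, tree=tree)


def extract_events(states: AncestralStates, tree: Phylogeny) -> EventHistory:
    """Read gain/loss events off the reconstructed states, branch by branch."""
    s = states.states
    n_ent, n_nodes = s.shape
    gains = np.zeros((n_ent, n_nodes), dtype=bool)
    losses = np.zeros((n_ent, n_nodes), dtype=bool)
    for i in range(1, n_nodes):
        sp = s[:, tree.parent[i]]
        gains[:, i] = (sp == 0) & (s[:, i] == 1)
        losses[:, i] = (sp == 1) & (s[:, i] == 0)
    return EventHistory(
        entity_ids=list(states.entity_ids), gains=gains, losses=losses, tree=tree
    )
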