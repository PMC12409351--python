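"""Synthetic trees, pangenomes, host ranges and phage genomes with truth.

The generators emulate the inputs of the pipeline at desk scale so every
stage can be validated against known ground truth:

* a Yule (pure-birth) strain tree with exponential branch lengths;
* accessory genes evolving independently along the tree as a two-state
  (absent/present) Markov chain with gain and loss rates, the root drawn
  from the stationary distribution;
* planted associated gene pairs whose partner copies the template's
  events with probability rho (rho = 1 gives identical histories);
* a host range driven by receptor genes (infection requires the receptor)
  and/or defense genes (infection requires the defense gene's absence),
  with independent per-cell flip noise epsilon;
* phage genomes as gene families: private families per phage plus one
  marker family shared by phages with the same receptor, with synthetic
  protein sequences whose within-family identity is > 80% and
  between-family identity < 80% by construction.

Everything is bit-reproducible under a fixed seed. Gene evolution is
simulated through the chain's exact transition probabilities per branch,
so a recorded event is the *net* state change of a branch (as in the
parsimony reconstruction downstream); multiple cancelling flips within a
single branch are not represented.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ancestral import EventHistory, extract_events, reconstruct_fitch
from .io_formats import (
    CATEGORY_BACTERIAL_GENE,
    DEFAULT_PHAGE_NAMESPACE,
    HostRangeMatrix,
    Phylogeny,
    PresenceMatrix,
    ProteinRecord,
)
from .matrix_builder import GeneFamily

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimTruth:
    """Ground truth of a simulation scenario."""

    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    receptor_of: dict[str, str] = field(default_factory=dict)
    defense_of: dict[str, str] = field(default_factory=dict)
    noise_rate: float = 0.0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "planted_pairs": [list(p) for p in self.planted_pairs],
                    "receptor_of": self.receptor_of,
                    "defense_of": self.defense_of,
                    "noise_rate": self.noise_rate,
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# tree
# ---------------------------------------------------------------------------


def simulate_tree(n_leaves: int, model: str = "yule", seed: int = 0) -> Phylogeny:
    """Random rooted binary Yule tree with exponential branch lengths.

    Pure-birth process with rate 1: starting from two lineages, each
    lineage splits at rate 1 until ``n_leaves`` are alive, then all pending
    branches are extended by a final exponential waiting time. Leaves are
    labelled s1..sn in preorder.
    """
    if model != "yule":
        raise ValueError(f"unknown tree model: {model!r}")
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(seed)
    # node: [name, blen, children]; active lineages carry their birth time
    root = [None, 0.0, []]
    left = [None, 0.0, []]
    right = [None, 0.0, []]
    root[2] = [left, right]
    t = 0.0
    active: list[tuple[list, float]] = [(left, 0.0), (right, 0.0)]
    while len(active) < n_leaves:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node[1] = t - born
        a = [None, 0.0, []]
        b = [None, 0.0, []]
        node[2] = [a, b]
        active.extend([(a, t), (b, t)])
    t += rng.exponential(1.0 / n_leaves)
    for node, born in active:
        node[1] = t - born

    parent: list[int] = []
    blen: list[float] = []
    names: list[str | None] = []
    counter = [0]

    def emit(node: list, parent_idx: int) -> None:
        i = len(parent)
        parent.append(parent_idx)
        blen.append(node[1])
        if node[2]:
            names.append(None)
        else:
            counter[0] += 1
            names.append(f"s{counter[0]}")
        for c in node[2]:
            emit(c, i)

    emit(root, -1)
    return Phylogeny(parent, blen, names)


# ---------------------------------------------------------------------------
# neutral gene evolution
# ---------------------------------------------------------------------------


def _transition_probs(gain: float, loss: float, t: float) -> tuple[float, float]:
    """(P(0 -> 1), P(1 -> 0)) over a branch of length t."""
    total = gain + loss
    if total == 0:
        return 0.0, 0.0
    decay = math.exp(-total * t)
    return gain / total * (1 - decay), loss / total * (1 - decay)


def simulate_neutral_genes(
    tree: Phylogeny,
    m_genes: int,
    gain_rate: float = 0.1,
    loss_rate: float = 0.1,
    seed: int = 0,
) -> tuple[PresenceMatrix, EventHistory]:
    """Independent two-state evolution of m genes down the tree.

    Root states are stationary (gain / (gain + loss)); each branch changes
    state with the chain's exact transition probability. Returns the leaf
    presence matrix and the true per-branch net events.
    """
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    if gain_rate == 0 and loss_rate == 0:
        logger.warning("both rates are 0: all genes are constant")
    rng = np.random.default_rng(seed)
    n_nodes = tree.n_nodes
    states = np.zeros((m_genes, n_nodes), dtype=np.uint8)
    pi1 = gain_rate / (gain_rate + loss_rate) if gain_rate + loss_rate > 0 else 0.0
    states[:, 0] = rng.random(m_genes) < pi1
    gains = np.zeros((m_genes, n_nodes), dtype=bool)
    losses = np.zeros((m_genes, n_nodes), dtype=bool)
    for i in range(1, n_nodes):
        p01, p10 = _transition_probs(gain_rate, loss_rate, float(tree.blen[i]))
        sp = states[:, tree.parent[i]]
        u = rng.random(m_genes)
        flip = np.where(sp == 0, u < p01, u < p10)
        states[:, i] = sp ^ flip
        gains[:, i] = flip & (sp == 0)
        losses[:, i] = flip & (sp == 1)

    gene_ids = [f"g{j + 1}" for j in range(m_genes)]
    leaf_idx = tree.leaf_indices
    matrix = PresenceMatrix(
        entity_ids=gene_ids,
        strain_ids=[tree.names[i] for i in leaf_idx],
        values=states[:, leaf_idx],
        entity_category={g: CATEGORY_BACTERIAL_GENE for g in gene_ids},
    )
    events = EventHistory(entity_ids=gene_ids, gains=gains, losses=losses, tree=tree)
    return matrix, events


def plant_associated_pairs(
    matrix: PresenceMatrix,
    events: EventHistory,
    n_pairs: int,
    rho: float = 1.0,
    seed: int = 0,
    min_template_events: int = 2,
) -> tuple[PresenceMatrix, EventHistory, SimTruth]:
    """Turn n_pairs of neutral genes into associated template/partner pairs.

    Templates are drawn from genes with >= ``min_template_events`` events;
    each template is paired with another gene whose history is rewritten:
    every template event is copied with probability rho, every original
    partner event is kept with probability 1 - rho (rho = 1 gives an
    identical history and leaf pattern, rho = 0 leaves the partner's
    neutral history untouched). Leaf states are regenerated from the
    modified histories by treating events as state toggles down the tree.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tree = events.tree
    counts = events.counts()
    eligible = np.flatnonzero(counts >= min_template_events)
    if eligible.size < 2 * n_pairs:
        raise ValueError(
            f"need {2 * n_pairs} genes with >= {min_template_events} events, "
            f"have {eligible.size}"
        )
    picked = rng.choice(eligible, size=2 * n_pairs, replace=False)
    templates, partners = picked[:n_pairs], picked[n_pairs:]

    values = matrix.values.copy()
    gains = events.gains.copy()
    losses = events.losses.copy()
    leaf_idx = tree.leaf_indices
    truth = SimTruth(noise_rate=0.0, seed=seed)
    for tmpl, part in zip(templates, partners):
        tmpl_ev = gains[tmpl] | losses[tmpl]
        part_ev = gains[part] | losses[part]
        copied = tmpl_ev & (rng.random(tree.n_nodes) < rho)
        retained = part_ev & (rng.random(tree.n_nodes) >= rho)
        toggles = copied | retained
        # root state follows the template exactly when the history does
        src = tmpl if rng.random() < rho else part
        root_state = _consistent_root_state(int(src), events)
        new_states = np.zeros(tree.n_nodes, dtype=np.uint8)
        new_states[0] = root_state
        new_gains = np.zeros(tree.n_nodes, dtype=bool)
        new_losses = np.zeros(tree.n_nodes, dtype=bool)
        for i in range(1, tree.n_nodes):
            sp = new_states[tree.parent[i]]
            if toggles[i]:
                new_states[i] = 1 - sp
                if sp == 0:
                    new_gains[i] = True
                else:
                    new_losses[i] = True
            else:
                new_states[i] = sp
        gains[part] = new_gains
        losses[part] = new_losses
        values[part] = new_states[leaf_idx]
        truth.planted_pairs.append(
            (events.entity_ids[int(tmpl)], events.entity_ids[int(part)], rho)
        )

    new_matrix = PresenceMatrix(
        entity_ids=list(matrix.entity_ids),
        strain_ids=list(matrix.strain_ids),
        values=values,
        entity_category=dict(matrix.entity_category),
        annotations=dict(matrix.annotations),
    )
    new_events = EventHistory(
        entity_ids=list(events.entity_ids), gains=gains, losses=losses, tree=tree
    )
    return new_matrix, new_events, truth


def _consistent_root_state(row: int, events: EventHistory) -> int:
    """Root state implied by a gene's gain/loss history.

    A gain requires parent state 0 and a loss parent state 1, so at most
    one root state is consistent with a non-empty history; event-free
    histories default to the rarer presence state 0.
    """
    tree = events.tree
    for root_state in (0, 1):
        ok = True
        states = np.zeros(tree.n_nodes, dtype=np.uint8)
        states[0] = root_state
        for i in range(1, tree.n_nodes):
            sp = states[tree.parent[i]]
            if events.gains[row, i]:
                if sp != 0:
                    ok = False
                    break
                states[i] = 1
            elif events.losses[row, i]:
                if sp != 1:
                    ok = False
                    break
                states[i] = 0
            else:
                states[i] = sp
        if ok:
            return root_state
    raise AssertionError("event history is internally inconsistent")


# ---------------------------------------------------------------------------
# host range
# ---------------------------------------------------------------------------


def simulate_host_range(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    n_phages: int,
    mode: str = "receptor",
    epsilon: float = 0.0,
    seed: int = 0,
    min_gene_events: int = 3,
    namespace: str = DEFAULT_PHAGE_NAMESPACE,
) -> tuple[HostRangeMatrix, SimTruth]:
    """Generate a host range driven by receptor and/or defense genes.

    mode "receptor": phage p infects strain s iff s carries p's receptor
    gene. mode "defense": iff s lacks p's defense gene. mode "both": iff s
    carries the receptor AND lacks the defense gene. Every cell then flips
    independently with probability epsilon. Driver genes are drawn without
    replacement from genes whose parsimony event count on the tree is at
    least ``min_gene_events`` (detection requires repeated joint gains and
    losses along the phylogeny).
    """
    if mode not in ("receptor", "defense", "both"):
        raise ValueError(f"unknown mode: {mode!r}")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    rng = np.random.default_rng(seed)
    from .ancestral import resolve_polytomies

    btree = resolve_polytomies(tree)
    events = extract_events(reconstruct_fitch(matrix, btree), btree)
    counts = events.counts()
    eligible = np.flatnonzero(counts >= min_gene_events)
    need = n_phages * (2 if mode == "both" else 1)
    if eligible.size < need:
        raise ValueError(
            f"need {need} genes with >= {min_gene_events} events, have {eligible.size}"
        )
    picked = rng.choice(eligible, size=need, replace=False)

    truth = SimTruth(noise_rate=epsilon, seed=seed)
    infects = np.zeros((n_phages, matrix.n_strains), dtype=np.uint8)
    for p in range(n_phages):
        raw_id = f"P{p + 1}"
        if mode == "receptor":
            r = int(picked[p])
            truth.receptor_of[raw_id] = matrix.entity_ids[r]
            infects[p] = matrix.values[r]
        elif mode == "defense":
            d = int(picked[p])
            truth.defense_of[raw_id] = matrix.entity_ids[d]
            infects[p] = 1 - matrix.values[d]
        else:
            r, d = int(picked[2 * p]), int(picked[2 * p + 1])
            truth.receptor_of[raw_id] = matrix.entity_ids[r]
            truth.defense_of[raw_id] = matrix.entity_ids[d]
            infects[p] = matrix.values[r] & (1 - matrix.values[d])
    if epsilon > 0:
        flips = rng.random(infects.shape) < epsilon
        infects = infects ^ flips.astype(np.uint8)

    hr = HostRangeMatrix(
        phage_ids=[f"P{p + 1}{namespace}" for p in range(n_phages)],
        strain_ids=list(matrix.strain_ids),
        infects=infects,
        namespace=namespace,
        raw_phage_ids=[f"P{p + 1}" for p in range(n_phages)],
    )
    return hr, truth


# ---------------------------------------------------------------------------
# phage genomes
# ---------------------------------------------------------------------------


def _mutate(template: str, p_sub: float, rng: np.random.Generator) -> str:
    chars = list(template)
    for i in range(len(chars)):
        if rng.random() < p_sub:
            choices = _AA.replace(chars[i], "")
            chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def simulate_phage_genomes(
    hr: HostRangeMatrix,
    truth: SimTruth,
    families_per_phage: int = 3,
    protein_length: int = 120,
    p_sub: float = 0.03,
    seed: int = 0,
) -> tuple[list[GeneFamily], list[ProteinRecord]]:
    """Synthetic phage gene families and protein sequences.

    Each phage carries ``families_per_phage`` private families plus one
    marker family shared by all phages with the same receptor gene (or a
    private marker when no receptor truth exists). Family members derive
    from a random template protein with per-site substitution probability
    ``p_sub``, keeping within-family identity above and between-family
    identity below the 80% clustering cutoff.
    """
    rng = np.random.default_rng(seed)
    families: list[GeneFamily] = []
    records: list[ProteinRecord] = []
    fam_no = 0

    def new_family(member_phages: list[str], tag: str) -> None:
        nonlocal fam_no
        fam_no += 1
        template = "".join(_AA[int(i)] for i in rng.integers(len(_AA), size=protein_length))
        members: set[tuple[str, str]] = set()
        for phage in member_phages:
            gene_id = f"{phage}_{tag}"
            seq = _mutate(template, p_sub, rng)
            records.append(ProteinRecord(gene_id=gene_id, phage_id=phage, sequence=seq))
            members.add((gene_id, phage))
        families.append(GeneFamily(family_id=f"SIMF{fam_no}", members=members))

    by_receptor: dict[str, list[str]] = {}
    for raw in hr.raw_phage_ids:
        receptor = truth.receptor_of.get(raw)
        by_receptor.setdefault(receptor if receptor else f"_none_{raw}", []).append(raw)
    for receptor in sorted(by_receptor):
        new_family(sorted(by_receptor[receptor]), tag="marker")
    for raw in hr.raw_phage_ids:
        for k in range(families_per_phage):
            new_family([raw], tag=f"core{k + 1}")
    return families, records


# ---------------------------------------------------------------------------
# bundle writer (CLI `simulate`)
# ---------------------------------------------------------------------------


def write_bundle(
    outdir: str | Path,
    n_strains: int = 60,
    n_genes: int = 200,
    n_phages: int = 5,
    mode: str = "receptor",
    epsilon: float = 0.0,
    gain_rate: float = 0.1,
    loss_rate: float = 0.1,
    families_per_phage: int = 3,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a complete synthetic input bundle to a directory."""
    from .io_formats import write_presence_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(n_strains, seed=seed)
    matrix, _events = simulate_neutral_genes(
        tree, n_genes, gain_rate=gain_rate, loss_rate=loss_rate, seed=seed + 1
    )
    hr, truth = simulate_host_range(
        matrix, tree, n_phages, mode=mode, epsilon=epsilon, seed=seed + 2
    )
    families, records = simulate_phage_genomes(hr, truth, families_per_phage, seed=seed + 3)

    paths = {
        "tree": outdir / "tree.nwk",
        "gpa": outdir / "gpa.Rtab",
        "host_range": outdir / "host_range.tsv",
        "proteins": outdir / "phage_proteins.faa",
        "phage_map": outdir / "phage_map.tsv",
        "truth": outdir / "truth.json",
    }
    with open(paths["tree"], "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")
    write_presence_matrix(matrix, paths["gpa"])
    with open(paths["host_range"], "w", encoding="utf-8") as fh:
        fh.write("phage\t" + "\t".join(hr.strain_ids) + "\n")
        for i, raw in enumerate(hr.raw_phage_ids):
            fh.write(raw + "\t" + "\t".join(map(str, hr.infects[i])) + "\n")
    with open(paths["proteins"], "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n{rec.sequence}\n")
    with open(paths["phage_map"], "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.gene_id}\t{rec.phage_id}\n")
    truth.to_json(paths["truth"])
    return paths
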