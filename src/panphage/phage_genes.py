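"""Phage gene family construction from protein sequences.

Candidate gene pairs come either from a precomputed tabular similarity
hit file (best e-value per unordered pair below a cutoff, default 0.1) or,
for small datasets, from exhaustive enumeration. For candidate pairs the
global percent identity is computed with a Needleman-Wunsch alignment
(BLOSUM62, affine gaps, end gaps penalized); pairs at >= 80% identity form
the edges of a graph that is partitioned into families by the shared
Markov-clustering core with inflation 2. Every gene, including isolated
ones, belongs to exactly one family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ProteinRecord, ValidationError, read_hit_table
from .matrix_builder import GeneFamily
from .network import mcl_cluster

logger = logging.getLogger(__name__)


@dataclass
class AlignmentParams:
    """Global alignment settings: substitution matrix and affine gap costs."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_identity(
    a: str, b: str, params: AlignmentParams | None = None
) -> float:
    """Percent identity of the optimal global alignment of two proteins.

    Identity = 100 * identical aligned positions / alignment length
    including gap columns; the aligner's traceback is deterministic, and
    identity is symmetric in the two sequences.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentParams()
    aln = _aligner(params).align(a, b)[0]
    counts = aln.counts()
    length = aln.shape[1]
    return 100.0 * counts.identities / length


def candidate_pairs(
    records: Sequence[ProteinRecord],
    hits: str | Path | pd.DataFrame | None = None,
    evalue_cutoff: float = 0.1,
    max_all_pairs: int = 2000,
) -> set[tuple[str, str]]:
    """Unordered gene pairs worth aligning.

    With a hit table: pairs whose best e-value (over both hit directions)
    is below the cutoff, self-hits excluded. Without one: all pairs, which
    is only permitted up to ``max_all_pairs`` genes.
    """
    ids = [r.gene_id for r in records]
    known = set(ids)
    if hits is None:
        if len(ids) > max_all_pairs:
            raise ValueError(
                f"all-pairs mode limited to {max_all_pairs} genes "
                f"({len(ids)} given); provide a hit table"
            )
        return {
            (a, b) if a < b else (b, a)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
        }
    if not isinstance(hits, pd.DataFrame):
        hits = read_hit_table(hits)
    best: dict[tuple[str, str], float] = {}
    for q, s, e in zip(hits["query"], hits["subject"], hits["evalue"]):
        q, s = str(q), str(s)
        if q not in known or s not in known:
            missing = q if q not in known else s
            raise ValidationError(f"hit table references unknown gene id {missing!r}")
        if q == s:
            continue
        key = (q, s) if q < s else (s, q)
        e = float(e)
        if key not in best or e < best[key]:
            best[key] = e
    return {pair for pair, e in best.items() if e < evalue_cutoff}


def compute_identities(
    records: Sequence[ProteinRecord],
    pairs: set[tuple[str, str]],
    params: AlignmentParams | None = None,
) -> dict[tuple[str, str], float]:
    """Global percent identity for every candidate pair."""
    params = params or AlignmentParams()
    seq = {r.gene_id: r.sequence for r in records}
    return {
        (a, b): global_identity(seq[a], seq[b], params) for a, b in sorted(pairs)
    }


def cluster_phage_genes(
    records: Sequence[ProteinRecord],
    identities: Mapping[tuple[str, str], float],
    identity_cutoff: float = 80.0,
    inflation: float = 2.0,
) -> list[GeneFamily]:
    """Cluster genes into families from pairwise identities.

    Edges are pairs with identity >= cutoff (the threshold is sharp: 79.9
    does not connect); clustering uses the shared MCL core. Family ids are
    deterministic: sorted by size descending, then by lexicographically
    smallest member.
    """
    phage_of = {r.gene_id: r.phage_id for r in records}
    g = nx.Graph()
    g.add_nodes_from(phage_of)
    for (a, b), ident in identities.items():
        if ident >= identity_cutoff:
            g.add_edge(a, b, weight=1.0)
    clusters = mcl_cluster(g, inflation=inflation)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    families = [
        GeneFamily(
            family_id=f"PGF{k}",
            members={(gene, phage_of[gene]) for gene in members},
        )
        for k, members in enumerate(clusters, start=1)
    ]
    total = sum(len(f.members) for f in families)
    if total != len(phage_of):
        raise AssertionError("families do not partition the gene set")
    return families


def family_presence(
    families: Sequence[GeneFamily], records: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """Binary family x phage table: 1 iff the phage carries >= 1 member."""
    phages = sorted({r.phage_id for r in records})
    data = {
        fam.family_id: [1 if p in fam.phages else 0 for p in phages]
        for fam in families
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=phages)


def write_families(families: Sequence[GeneFamily], path: str | Path) -> None:
    """Write family membership as family_id / gene_id / phage_id TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family_id\tgene_id\tphage_id\n")
        for fam in families:
            for gene, phage in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{gene}\t{phage}\n")
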