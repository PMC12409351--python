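"""End-to-end convenience wrapper: matrix in, association results out."""

from __future__ import annotations

from .ancestral import extract_events, reconstruct_fitch, resolve_polytomies
from .association import AnalysisConfig, AssociationResult, test_all_pairs
from .io_formats import Phylogeny, PresenceMatrix
from .matrix_builder import filter_entities


def run_association_analysis(
    matrix: PresenceMatrix,
    tree: Phylogeny,
    cfg: AnalysisConfig | None = None,
    min_present: int = 1,
    max_present: int | None = None,
) -> list[AssociationResult]:
    """Run the full association analysis on a combined presence matrix.

    Filters uninformative entities, resolves polytomies, reconstructs
    ancestral states by parsimony, extracts gain/loss events and tests all
    eligible pairs against the simulated neutral null.
    """
    cfg = cfg or AnalysisConfig()
    matrix = filter_entities(matrix, min_present=min_present, max_present=max_present)
    btree = resolve_polytomies(tree)
    states = reconstruct_fitch(matrix, btree)
    events = extract_events(states, btree)
    return test_all_pairs(events, matrix.entity_category, btree, cfg)
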