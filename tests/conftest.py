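from __future__ import annotations

import dendropy
import numpy as np
import pytest

from panphage.io_formats import (
    CATEGORY_BACTERIAL_GENE,
    Phylogeny,
    PresenceMatrix,
)


def tree_from_newick(newick: str) -> Phylogeny:
    t = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    return Phylogeny.from_dendropy(t)


def star_tree(lengths: list[float]) -> Phylogeny:
    """Rooted star: one root, one terminal branch per length."""
    n = len(lengths)
    return Phylogeny(
        parent=[-1] + [0] * n,
        blen=[0.0] + list(lengths),
        names=[None] + [f"L{i + 1}" for i in range(n)],
    )


def gene_matrix(rows: dict[str, list[int]], strains: list[str]) -> PresenceMatrix:
    return PresenceMatrix(
        entity_ids=list(rows),
        strain_ids=strains,
        values=np.array(list(rows.values()), dtype=np.uint8),
        entity_category={g: CATEGORY_BACTERIAL_GENE for g in rows},
    )


@pytest.fixture
def balanced4() -> Phylogeny:
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def tree5() -> Phylogeny:
    return tree_from_newick("((A:1,B:1):1,((C:1,D:1):1,E:1):0.5);")
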