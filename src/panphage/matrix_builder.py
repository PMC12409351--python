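"""Construction of the pangenome-phage interaction matrices.

Three encodings append phage information to the bacterial gene
presence/absence matrix as pseudo-gene rows:

* plus: a phage row is 1 for every strain the phage can infect — detects
  bacterial genes whose *presence* enables infection (receptors);
* minus: a phage row is 1 for every strain the phage can NOT infect —
  detects genes whose presence prevents infection (defense systems);
* plus-genes: a phage gene family row is 1 for every strain infected by at
  least one phage carrying a member of the family — links bacterial genes
  to particular phage genes.

The same builders accept any binary phage x strain matrix, so adsorption
(or adsorb-but-not-infect) matrices are handled by re-labelling the input,
not by different code. Bacterial gene rows pass through unchanged, and the
strain order of the bacterial matrix is the canonical axis: host-range
columns are permuted to match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import (
    CATEGORY_PHAGE,
    CATEGORY_PHAGE_GENE,
    HostRangeMatrix,
    PresenceMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class GeneFamily:
    """A family of homologous phage genes: members are (gene_id, phage_id)."""

    family_id: str
    members: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"family {self.family_id!r} has no members")

    @property
    def phages(self) -> set[str]:
        return {p for _, p in self.members}


def _check_join(gpa: PresenceMatrix, hr: HostRangeMatrix) -> HostRangeMatrix:
    hr = hr.reorder_strains(gpa.strain_ids)
    collisions = set(gpa.entity_ids) & set(hr.phage_ids)
    if collisions:
        raise ValidationError(
            f"phage ids collide with gene ids after namespacing: {sorted(collisions)[:5]}"
        )
    return hr


def _append_rows(
    gpa: PresenceMatrix,
    row_ids: list[str],
    rows: np.ndarray,
    category: str,
) -> PresenceMatrix:
    categories = dict(gpa.entity_category)
    for rid in row_ids:
        categories[rid] = category
    return PresenceMatrix(
        entity_ids=list(gpa.entity_ids) + row_ids,
        strain_ids=list(gpa.strain_ids),
        values=np.vstack([gpa.values, rows.astype(np.uint8)]),
        entity_category=categories,
        annotations=dict(gpa.annotations),
    )


def build_gpa_plus_phage(gpa: PresenceMatrix, hr: HostRangeMatrix) -> PresenceMatrix:
    """Append one row per phage: 1 iff the phage infects the strain."""
    hr = _check_join(gpa, hr)
    for i, p in enumerate(hr.phage_ids):
        if hr.infects[i].sum() == 0:
            logger.warning("phage %r infects no strain: all-zero row retained", p)
    return _append_rows(gpa, list(hr.phage_ids), hr.infects, CATEGORY_PHAGE)


def build_gpa_minus_phage(gpa: PresenceMatrix, hr: HostRangeMatrix) -> PresenceMatrix:
    """Append one row per phage: 1 iff the phage does NOT infect the strain."""
    hr = _check_join(gpa, hr)
    return _append_rows(gpa, list(hr.phage_ids), 1 - hr.infects, CATEGORY_PHAGE)


def build_gpa_plus_phage_genes(
    gpa: PresenceMatrix, hr: HostRangeMatrix, families: list[GeneFamily]
) -> PresenceMatrix:
    """Append one row per phage gene family.

    A family is present in a strain iff some phage carrying a member of the
    family can infect that strain (boolean OR of the carriers' infection
    rows).
    """
    hr = _check_join(gpa, hr)
    raw_index = {p: i for i, p in enumerate(hr.raw_phage_ids)}
    rows = np.zeros((len(families), len(gpa.strain_ids)), dtype=np.uint8)
    ids: list[str] = []
    for k, fam in enumerate(families):
        ids.append(fam.family_id)
        for phage in sorted(fam.phages):
            if phage not in raw_index:
                raise ValidationError(
                    f"family {fam.family_id!r} references phage {phage!r} "
                    "absent from the host range matrix"
                )
            rows[k] |= hr.infects[raw_index[phage]]
    return _append_rows(gpa, ids, rows, CATEGORY_PHAGE_GENE)


def filter_entities(
    m: PresenceMatrix, min_present: int = 1, max_present: int | None = None
) -> PresenceMatrix:
    """Keep entities present in min_present..max_present strains.

    The defaults (1, n_strains - 1) drop constant rows, which carry no
    gain/loss events; removals are logged per category so absent phages in
    the results are explainable.
    """
    n = m.n_strains
    if max_present is None:
        max_present = n - 1
    if not 0 <= min_present <= max_present <= n:
        raise ValueError("need 0 <= min_present <= max_present <= n_strains")
    k = m.values.sum(axis=1)
    keep = (k >= min_present) & (k <= max_present)
    removed: dict[str, list[str]] = {}
    for i in np.flatnonzero(~keep):
        removed.setdefault(m.entity_category[m.entity_ids[i]], []).append(m.entity_ids[i])
    for cat, ids in sorted(removed.items()):
        logger.info(
            "filter_entities removed %d %s entities (constant or out of range): %s%s",
            len(ids), cat, ", ".join(ids[:10]), "..." if len(ids) > 10 else "",
        )
    idx = np.flatnonzero(keep)
    kept_ids = [m.entity_ids[i] for i in idx]
    return PresenceMatrix(
        entity_ids=kept_ids,
        strain_ids=list(m.strain_ids),
        values=m.values[idx],
        entity_category={e: m.entity_category[e] for e in kept_ids},
        annotations={e: a for e, a in m.annotations.items() if e in set(kept_ids)},
    )
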