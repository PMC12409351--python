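"""Readers, writers and the typed in-memory containers of the pipeline.

Every external file format touched by the tool (presence/absence tables,
host-range matrices, Newick trees, protein FASTA, hit tables, result
tables) is parsed here with strict validation, so that downstream modules
only ever see validated objects: a :class:`PresenceMatrix`, a
:class:`HostRangeMatrix`, a :class:`Phylogeny` or lists of
:class:`ProteinRecord`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: entity categories carried by every row of a PresenceMatrix
CATEGORY_BACTERIAL_GENE = "bacterial_gene"
CATEGORY_PHAGE = "phage"
CATEGORY_PHAGE_GENE = "phage_gene"
CATEGORIES = (CATEGORY_BACTERIAL_GENE, CATEGORY_PHAGE, CATEGORY_PHAGE_GENE)

#: default suffix appended to phage identifiers to keep them disjoint from
#: gene identifiers after the matrices are joined
DEFAULT_PHAGE_NAMESPACE = "_Phag"

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (duplicates, incompleteness...)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PresenceMatrix:
    """Binary entity x strain matrix; the unifying data structure.

    Rows are "entities": bacterial genes, phages (their infection pattern
    encoded like a gene) or phage gene families. ``values`` is a uint8
    array of shape ``(len(entity_ids), len(strain_ids))``.
    """

    entity_ids: list[str]
    strain_ids: list[str]
    values: np.ndarray
    entity_category: dict[str, str]
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.validate()

    def validate(self) -> None:
        if len(set(self.entity_ids)) != len(self.entity_ids):
            dup = _first_duplicate(self.entity_ids)
            raise ValidationError(f"duplicate entity id: {dup!r}")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            dup = _first_duplicate(self.strain_ids)
            raise ValidationError(f"duplicate strain id: {dup!r}")
        if self.values.shape != (len(self.entity_ids), len(self.strain_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.strain_ids)} strains"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary value at entity {self.entity_ids[i]!r}, "
                f"strain {self.strain_ids[j]!r}"
            )
        missing = [e for e in self.entity_ids if e not in self.entity_category]
        if missing:
            raise ValidationError(f"entities without category: {missing[:5]}")

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.entity_ids.index(entity_id)]

    def reorder_strains(self, strain_order: Sequence[str]) -> "PresenceMatrix":
        """Return a copy with columns permuted to ``strain_order``."""
        if set(strain_order) != set(self.strain_ids):
            missing = sorted(set(strain_order) ^ set(self.strain_ids))
            raise ValidationError(f"strain sets differ: {missing}")
        idx = [self.strain_ids.index(s) for s in strain_order]
        return PresenceMatrix(
            entity_ids=list(self.entity_ids),
            strain_ids=list(strain_order),
            values=self.values[:, idx],
            entity_category=dict(self.entity_category),
            annotations=dict(self.annotations),
        )


@dataclass
class HostRangeMatrix:
    """Complete binary phages x strains infection (or adsorption) matrix.

    ``phage_ids`` carry the namespace suffix (default ``_Phag``) so they can
    never collide with gene identifiers; ``raw_phage_ids`` preserve the ids
    as given in the input file (and as used in phage protein FASTA files).
    """

    phage_ids: list[str]
    strain_ids: list[str]
    infects: np.ndarray
    namespace: str = DEFAULT_PHAGE_NAMESPACE
    raw_phage_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.infects = np.asarray(self.infects, dtype=np.uint8)
        if not self.raw_phage_ids:
            ns = self.namespace
            self.raw_phage_ids = [
                p[: -len(ns)] if ns and p.endswith(ns) else p for p in self.phage_ids
            ]
        if len(set(self.phage_ids)) != len(self.phage_ids):
            raise ValidationError("duplicate phage ids")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValidationError("duplicate strain ids")
        if self.infects.shape != (len(self.phage_ids), len(self.strain_ids)):
            raise ValidationError("host range shape mismatch")
        if not np.isin(self.infects, (0, 1)).all():
            raise ValidationError("host range matrix must be binary (0/1)")

    @property
    def n_phages(self) -> int:
        return len(self.phage_ids)

    def namespaced(self, raw_id: str) -> str:
        try:
            return self.phage_ids[self.raw_phage_ids.index(raw_id)]
        except ValueError:
            raise ValidationError(f"unknown phage id: {raw_id!r}") from None

    def reorder_strains(self, strain_order: Sequence[str]) -> "HostRangeMatrix":
        if set(strain_order) != set(self.strain_ids):
            missing = sorted(set(strain_order) ^ set(self.strain_ids))
            raise ValidationError(
                f"host range strains do not match: unmatched ids {missing}"
            )
        idx = [self.strain_ids.index(s) for s in strain_order]
        return HostRangeMatrix(
            phage_ids=list(self.phage_ids),
            strain_ids=list(strain_order),
            infects=self.infects[:, idx],
            namespace=self.namespace,
            raw_phage_ids=list(self.raw_phage_ids),
        )


class Phylogeny:
    """Rooted phylogeny over the strain set, stored as flat arrays.

    Nodes are indexed in preorder (``parent[i] < i``, root is node 0), which
    makes both the bottom-up and top-down passes of ancestral reconstruction
    simple array loops. A *branch* is identified by the node below it, so
    branch ids are node ids of non-root nodes; ``blen[i]`` is the length of
    the branch above node ``i`` (0 for the root).
    """

    def __init__(
        self,
        parent: Sequence[int],
        blen: Sequence[float],
        names: Sequence[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.names = list(names)
        n = self.parent.size
        if n == 0 or self.parent[0] != -1 or (self.parent[1:] >= np.arange(1, n)).any():
            raise ValidationError("nodes must be in preorder with root first")
        if not np.isfinite(self.blen).all() or (self.blen < 0).any():
            raise ValidationError("branch lengths must be finite and >= 0")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self.is_leaf = np.array([len(c) == 0 for c in self.children])
        labels = [self.names[i] for i in np.flatnonzero(self.is_leaf)]
        if None in labels:
            raise ValidationError("every leaf must be labelled")
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate leaf label: {_first_duplicate(labels)!r}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_leaf)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.names[i] for i in self.leaf_indices]

    @property
    def branch_ids(self) -> list[str]:
        """Names of the nodes below each non-root branch (order: node index)."""
        return [self.node_name(i) for i in range(1, self.n_nodes)]

    def node_name(self, i: int) -> str:
        name = self.names[i]
        return name if name is not None else f"N{i}"

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def total_length(self) -> float:
        return float(self.blen.sum())

    # -- conversions --------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        parent: list[int] = []
        blen: list[float] = []
        names: list[str | None] = []
        index: dict[int, int] = {}
        missing_lengths = 0
        for node in tree.preorder_node_iter():
            i = len(parent)
            index[id(node)] = i
            parent.append(-1 if node.parent_node is None else index[id(node.parent_node)])
            length = node.edge.length
            if length is None:
                if node.parent_node is not None:
                    missing_lengths += 1
                length = 0.0
            blen.append(float(length))
            if node.is_leaf():
                names.append(node.taxon.label if node.taxon else node.label)
            else:
                names.append(None)
        if missing_lengths:
            logger.warning(
                "%d branches without length set to 0", missing_lengths
            )
        return cls(parent, blen, names)

    def to_newick(self) -> str:
        def rec(i: int) -> str:
            if self.is_leaf[i]:
                label = self.names[i]
                return f"{label}:{self.blen[i]:g}"
            inner = ",".join(rec(c) for c in self.children[i])
            return f"({inner}):{self.blen[i]:g}"

        if self.is_leaf[0]:  # degenerate single-node tree
            return f"{self.names[0]};"
        inner = ",".join(rec(c) for c in self.children[0])
        return f"({inner});"

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick")


@dataclass(frozen=True)
class ProteinRecord:
    """One phage protein sequence with its phage of origin."""

    gene_id: str
    phage_id: str
    sequence: str


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _sep_for(path: str | Path, dialect: str) -> str:
    if dialect == "rtab":
        return "\t"
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_gpa(
    path: str | Path,
    dialect: str = "rtab",
    orientation: str = "entities_as_rows",
) -> PresenceMatrix:
    """Read a gene presence/absence table into a :class:`PresenceMatrix`.

    ``rtab`` is the tab-separated genes-as-rows layout emitted by common
    pangenome tools (first header cell names the gene column); ``generic``
    accepts CSV or TSV with an ``orientation`` flag. All entities are
    categorized as bacterial genes; row/column order is preserved.
    """
    if dialect not in ("rtab", "generic"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if orientation not in ("entities_as_rows", "strains_as_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    df = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0, dtype=str)
    if orientation == "strains_as_rows":
        df = df.T
    entity_ids = [str(e) for e in df.index]
    strain_ids = [str(s) for s in df.columns]
    values = _parse_binary(df, entity_ids, strain_ids, kind="gene")
    return PresenceMatrix(
        entity_ids=entity_ids,
        strain_ids=strain_ids,
        values=values,
        entity_category={e: CATEGORY_BACTERIAL_GENE for e in entity_ids},
    )


def _parse_binary(
    df: pd.DataFrame, row_ids: list[str], col_ids: list[str], kind: str
) -> np.ndarray:
    raw = df.to_numpy(dtype=object)
    values = np.zeros(raw.shape, dtype=np.uint8)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise FormatError(
                    f"missing cell for {kind} {row_ids[i]!r}, column {col_ids[j]!r}: "
                    "the matrix must be complete"
                )
            text = str(cell).strip()
            if text not in ("0", "1"):
                raise FormatError(
                    f"non-binary value {text!r} for {kind} {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                )
            values[i, j] = int(text)
    return values


def read_host_range(
    path: str | Path, namespace: str = DEFAULT_PHAGE_NAMESPACE
) -> HostRangeMatrix:
    """Read a complete phages x strains 0/1 matrix (TSV or CSV).

    Phage ids are suffixed with ``namespace`` so they cannot collide with
    bacterial gene ids once the matrices are joined. Phages infecting no
    strain are accepted with a warning.
    """
    df = pd.read_csv(path, sep=_sep_for(path, "generic"), index_col=0, dtype=str)
    raw_ids = [str(p) for p in df.index]
    strain_ids = [str(s) for s in df.columns]
    values = _parse_binary(df, raw_ids, strain_ids, kind="phage")
    for i, p in enumerate(raw_ids):
        if values[i].sum() == 0:
            logger.warning("phage %r infects no strain in the host range matrix", p)
    return HostRangeMatrix(
        phage_ids=[p + namespace for p in raw_ids],
        strain_ids=strain_ids,
        infects=values,
        namespace=namespace,
        raw_phage_ids=raw_ids,
    )


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree; support values are ignored.

    Branches without a length are set to 0 with a warning (zero-length
    branches get zero weight in the association null, so cladogram-like
    inputs cannot host simulated events on those edges).
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicates are caught by our validator
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    return Phylogeny.from_dendropy(tree)


def read_phage_map(path: str | Path) -> dict[str, str]:
    """Read a two-column gene_id -> phage_id TSV mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"phage map {path} must have two tab-separated columns")
    return dict(zip(df[0], df[1]))


def read_phage_proteins(
    fasta_paths: Iterable[str | Path],
    phage_map: Mapping[str, str] | str | Path | None = None,
    host_range: HostRangeMatrix | None = None,
) -> list[ProteinRecord]:
    """Read phage protein FASTA files into :class:`ProteinRecord` objects.

    The phage of origin is taken from ``phage_map`` (a mapping or a
    two-column TSV path) when given, otherwise from the file stem
    (one-file-per-phage convention). Trailing ``*`` stop codons are
    stripped; any other non-amino-acid character is an error. When a
    ``host_range`` is given, every resolved phage id must occur in it.
    """
    if isinstance(phage_map, (str, Path)):
        phage_map = read_phage_map(phage_map)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for fp in fasta_paths:
        stem = Path(fp).stem
        for rec in SeqIO.parse(str(fp), "fasta"):
            gene_id = rec.id
            if gene_id in seen:
                raise ValidationError(f"duplicate gene id {gene_id!r} across FASTA files")
            seen.add(gene_id)
            seq = str(rec.seq).upper().rstrip("*")
            if not seq:
                raise ValidationError(f"empty sequence for gene {gene_id!r}")
            bad = set(seq) - _VALID_AA
            if bad:
                raise FormatError(
                    f"invalid residue(s) {sorted(bad)} in gene {gene_id!r}"
                )
            if phage_map is not None:
                if gene_id not in phage_map:
                    raise ValidationError(
                        f"gene {gene_id!r} has no phage in the mapping file"
                    )
                phage_id = phage_map[gene_id]
            else:
                phage_id = stem
            if host_range is not None and phage_id not in host_range.raw_phage_ids:
                raise ValidationError(
                    f"gene {gene_id!r} maps to phage {phage_id!r} absent from the "
                    "host range matrix"
                )
            records.append(ProteinRecord(gene_id=gene_id, phage_id=phage_id, sequence=seq))
    return records


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular similarity-search hit file.

    Columns follow the conventional tabular output of local search tools:
    query, subject, pident, length, mismatch, gapopen, qstart, qend,
    sstart, send, evalue, bitscore.
    """
    cols = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot parse hit table {path}: {exc}") from exc
    if df.shape[1] != 12:
        raise FormatError(f"hit table {path} must have 12 tab-separated columns")
    if df["evalue"].isna().any():
        line = int(df.index[df["evalue"].isna()][0]) + 1
        raise FormatError(f"malformed hit table row at line {line}")
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

PAIR_TABLE_COLUMNS = [
    "entity_a", "entity_b", "category_a", "category_b",
    "score_type", "observed_score", "p_value", "q_value", "significant",
]


def write_presence_matrix(m: PresenceMatrix, path: str | Path) -> None:
    """Write a PresenceMatrix in Rtab layout plus a category sidecar TSV."""
    df = pd.DataFrame(m.values, index=m.entity_ids, columns=m.strain_ids)
    df.index.name = "Gene"
    df.to_csv(path, sep="\t")
    sidecar = Path(str(path) + ".categories.tsv")
    with open(sidecar, "w", encoding="utf-8") as fh:
        fh.write("entity_id\tcategory\n")
        for e in m.entity_ids:
            fh.write(f"{e}\t{m.entity_category[e]}\n")


def read_presence_matrix(path: str | Path) -> PresenceMatrix:
    """Read back a matrix written by :func:`write_presence_matrix`."""
    m = read_gpa(path, dialect="rtab")
    sidecar = Path(str(path) + ".categories.tsv")
    if sidecar.exists():
        cat = pd.read_csv(sidecar, sep="\t", dtype=str)
        m.entity_category.update(dict(zip(cat["entity_id"], cat["category"])))
    return m


def write_pair_table(results, path: str | Path) -> None:
    """Write association results as a deterministic TSV.

    Rows are sorted by q ascending, then lexicographically by
    (entity_a, entity_b, score_type), so equal inputs give bit-identical
    files.
    """
    rows = sorted(
        results, key=lambda r: (r.q_value, r.entity_a, r.entity_b, r.score_type)
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PAIR_TABLE_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                f"{r.entity_a}\t{r.entity_b}\t{r.category_a}\t{r.category_b}\t"
                f"{r.score_type}\t{r.observed_score}\t{r.p_value!r}\t"
                f"{r.q_value!r}\t{int(r.significant)}\n"
            )


def read_pair_table(path: str | Path):
    """Round-trip reader for :func:`write_pair_table` output."""
    from .association import AssociationResult

    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in df.iterrows():
        out.append(
            AssociationResult(
                entity_a=row["entity_a"],
                entity_b=row["entity_b"],
                category_a=row["category_a"],
                category_b=row["category_b"],
                score_type=row["score_type"],
                observed_score=int(row["observed_score"]),
                p_value=float(row["p_value"]),
                q_value=float(row["q_value"]),
                significant=bool(int(row["significant"])),
            )
        )
    return out


def _first_duplicate(items: Sequence) -> object:
    seen: set = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
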