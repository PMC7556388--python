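"""Geneset collections and their alignment to an expression feature space.

A geneset is a named set of feature identifiers (a pathway, a GO group,
any predefined gene collection).  Aligning a collection against the
columns of an expression matrix yields a binary membership matrix
``G ∈ {0,1}^{g×p}`` whose row ``i`` marks which features belong to
geneset ``i``.  Identifiers are matched verbatim; any probe-to-gene
mapping is applied upstream via :func:`apply_feature_map`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GmtParseError(ValueError):
    """Raised for malformed GMT input."""


@dataclass
class GenesetCollection:
    """Ordered collection of named genesets.

    Each entry is ``(name, description, members)`` where *members* is a
    set of feature identifiers.  Names are unique within a collection and
    every members set is non-empty.
    """

    entries: list[tuple[str, str, set[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def validate(self) -> None:
        names = self.names
        if len(set(names)) != len(names):
            seen, dups = set(), set()
            for n in names:
                (dups if n in seen else seen).add(n)
            raise ValueError(f"duplicate geneset names: {sorted(dups)}")
        for name, _, members in self.entries:
            if not members:
                raise ValueError(f"geneset {name!r} has no members")


@dataclass
class MembershipMatrix:
    """Binary geneset-membership indicator aligned to a feature list.

    ``matrix`` is ``g × p`` with entries in {0, 1}; ``feature_ids`` gives
    the column order (it must match the expression matrix exactly) and
    ``sizes[i]`` is the row sum ``‖g_i‖₀``.
    """

    matrix: np.ndarray
    geneset_names: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("membership matrix must be 2-D")
        if self.matrix.shape != (len(self.geneset_names), len(self.feature_ids)):
            raise ValueError("membership matrix shape does not match names/features")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("membership matrix entries must be 0 or 1")
        if (self.matrix.sum(axis=1) < 1).any():
            raise ValueError("every geneset row must have at least one member")

    @property
    def sizes(self) -> np.ndarray:
        """Row sums ``‖g_i‖₀`` (number of member features per geneset)."""
        return self.matrix.sum(axis=1).astype(np.int64)

    @property
    def n_genesets(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    def support(self, i: int) -> np.ndarray:
        """Column indices of the features in geneset ``i``."""
        return np.flatnonzero(self.matrix[i])


def read_gmt(path) -> GenesetCollection:
    """Read a GMT file (one geneset per line: name, description, members).

    Member order is discarded and duplicate member ids within a line are
    collapsed.  Lines with fewer than three tab-separated fields raise
    :class:`GmtParseError` naming the line number; duplicate geneset
    names raise :class:`ValueError`.
    """
    entries: list[tuple[str, str, set[str]]] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, members), got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            members = {m for m in fields[2:] if m}
            if not members:
                raise GmtParseError(f"{path}: line {lineno}: geneset {name!r} has no members")
            if name in seen:
                raise ValueError(f"{path}: duplicate geneset name {name!r} at line {lineno}")
            seen.add(name)
            entries.append((name, description, members))
    return GenesetCollection(entries)


def write_gmt(collection: GenesetCollection, path) -> None:
    """Write a collection in GMT format (members sorted for determinism)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for name, description, members in collection.entries:
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def apply_feature_map(collection: GenesetCollection, mapping: pd.DataFrame) -> GenesetCollection:
    """Expand geneset members from gene symbols to platform feature ids.

    ``mapping`` has two columns, feature id then gene symbol.  Each
    geneset member (a gene symbol) is replaced by all feature ids mapping
    to it; members with no mapped feature are dropped.
    """
    if mapping.shape[1] < 2:
        raise ValueError("feature map needs two columns: feature_id, gene_symbol")
    by_gene: dict[str, set[str]] = {}
    for fid, gene in zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)):
        by_gene.setdefault(gene, set()).add(fid)
    out: list[tuple[str, str, set[str]]] = []
    for name, desc, members in collection.entries:
        expanded: set[str] = set()
        for m in members:
            expanded |= by_gene.get(m, set())
        if expanded:
            out.append((name, desc, expanded))
    return GenesetCollection(out)


def build_membership(
    collection: GenesetCollection,
    feature_ids: list[str],
    min_overlap: int = 1,
) -> tuple[MembershipMatrix, pd.DataFrame]:
    """Align a geneset collection to an ordered feature list.

    Returns the membership matrix together with a report of dropped
    genesets (those whose intersection with ``feature_ids`` is smaller
    than ``min_overlap``) as a DataFrame with columns
    ``name, original_size, overlap_size``.

    Features that belong to no geneset are kept as all-zero columns: only
    the discovery phase can capture them.
    """
    if len(feature_ids) == 0:
        raise ValueError("feature_ids must be non-empty")
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError("feature_ids must be unique")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    collection.validate()

    index = {f: j for j, f in enumerate(feature_ids)}
    p = len(feature_ids)
    rows, names = [], []
    dropped: list[tuple[str, int, int]] = []
    for name, _, members in collection.entries:
        cols = [index[m] for m in members if m in index]
        if len(cols) < min_overlap:
            dropped.append((name, len(members), len(cols)))
            continue
        row = np.zeros(p, dtype=np.int8)
        row[cols] = 1
        rows.append(row)
        names.append(name)
    report = pd.DataFrame(dropped, columns=["name", "original_size", "overlap_size"])
    if not rows:
        raise ValueError("no usable genesets: every geneset fell below min_overlap")
    G = MembershipMatrix(np.vstack(rows), names, list(feature_ids))
    return G, report
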