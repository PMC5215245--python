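"""Taxonomy trees and rank normalization.

Loads a rooted taxonomy either from the NCBI dump dialect (``nodes.dmp`` /
``names.dmp``, fields separated by ``\\t|\\t``) or from a compact 4-column TSV
(``taxid  parent  rank  name``), and supports the lineage operations the
benchmarking protocol needs: ancestor-at-rank projection, lowest common
ancestor, and normalization of arbitrary read assignments to a fixed rank
(family or genus).

All lookups are offline: names resolve by exact, case-insensitive match on
scientific names.  Ambiguous names resolve to the shallowest matching node
with a warning (or raise in strict mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .exceptions import InputError, StructureError, UnknownTaxonError

logger = logging.getLogger(__name__)

#: Controlled rank vocabulary, coarsest to finest. "no rank" is allowed anywhere.
RANKS = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Assignment status labels.
CLASSIFIED = "classified"
UNCLASSIFIED = "unclassified"
DISCARDED = "discarded"
STATUSES = (CLASSIFIED, UNCLASSIFIED, DISCARDED)


@dataclass(frozen=True)
class TaxNode:
    """One node of a taxonomy tree.

    The root is the unique node with ``parent == taxid``.
    """

    taxid: int
    parent: int
    rank: str
    name: str


class TaxonomyTree:
    """Rooted taxonomy supporting ancestor-at-rank and LCA queries.

    Parameters
    ----------
    nodes
        Mapping taxid -> :class:`TaxNode`.  Validated on construction:
        every parent must exist, exactly one node is its own parent (the
        root), and every node must reach the root (no cycles).
    merged
        Optional mapping of retired taxid -> current taxid (the
        ``merged.dmp`` content); applied transparently on lookup.
    """

    def __init__(self, nodes: Mapping[int, TaxNode], merged: Mapping[int, int] | None = None):
        if not nodes:
            raise InputError("taxonomy has no nodes")
        self.nodes: dict[int, TaxNode] = dict(nodes)
        self.merged: dict[int, int] = dict(merged or {})

        roots = [n.taxid for n in self.nodes.values() if n.parent == n.taxid]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        self.root: int = roots[0]

        for node in self.nodes.values():
            if node.parent not in self.nodes:
                raise StructureError(
                    f"taxid {node.taxid} has dangling parent {node.parent}"
                )

        # Depth computation doubles as the cycle check: a node that never
        # reaches root on its parent path sits on a cycle.
        self._depth: dict[int, int] = {self.root: 0}
        for taxid in self.nodes:
            self._resolve_depth(taxid)

        self.name_index: dict[str, list[int]] = {}
        for node in self.nodes.values():
            self.name_index.setdefault(node.name.lower(), []).append(node.taxid)

    def _resolve_depth(self, taxid: int) -> int:
        path = []
        cur = taxid
        while cur not in self._depth:
            path.append(cur)
            cur = self.nodes[cur].parent
            if cur in path:
                raise StructureError(f"cycle detected at taxid {cur}")
        base = self._depth[cur]
        for i, t in enumerate(reversed(path), start=1):
            self._depth[t] = base + i
        return self._depth[taxid]

    # -- basic queries -----------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes or taxid in self.merged

    def __len__(self) -> int:
        return len(self.nodes)

    def get(self, taxid: int) -> TaxNode:
        taxid = self.merged.get(taxid, taxid)
        try:
            return self.nodes[taxid]
        except KeyError:
            raise UnknownTaxonError(taxid) from None

    def depth(self, taxid: int) -> int:
        return self._depth[self.get(taxid).taxid]

    def lineage(self, taxid: int) -> list[int]:
        """Path from *taxid* (inclusive) up to the root (inclusive)."""
        node = self.get(taxid)
        out = [node.taxid]
        while node.taxid != self.root:
            node = self.nodes[node.parent]
            out.append(node.taxid)
        return out

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """First node of rank *rank* on the root path of *taxid*, inclusive.

        Returns ``None`` when no ancestor carries the rank (e.g. asking for
        the family of the root, or of a node attached above family level).
        """
        for t in self.lineage(taxid):
            if self.nodes[t].rank == rank:
                return t
        return None

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor: deepest node on every member's root path."""
        taxids = list(taxids)
        if not taxids:
            raise InputError("LCA of an empty set is undefined")
        common: set[int] | None = None
        for t in taxids:
            path = set(self.lineage(t))
            common = path if common is None else common & path
        assert common  # root is always shared
        return max(common, key=lambda t: self._depth[t])

    def resolve_name(self, name: str, strict: bool = False) -> int:
        """Resolve a scientific name to a taxid (exact, case-insensitive).

        Ambiguous names resolve to the shallowest matching node with a
        warning; in strict mode any ambiguity or miss raises
        :class:`UnknownTaxonError`.
        """
        hits = self.name_index.get(name.strip().lower(), [])
        if not hits:
            raise UnknownTaxonError(name)
        if len(hits) > 1:
            if strict:
                raise UnknownTaxonError(f"ambiguous name {name!r}: taxids {sorted(hits)}")
            chosen = min(hits, key=lambda t: (self._depth[t], t))
            logger.warning(
                "name %r is ambiguous (%d nodes); resolving to shallowest taxid %d",
                name, len(hits), chosen,
            )
            return chosen
        return hits[0]

    # -- serialization -----------------------------------------------------

    def to_table(self) -> pd.DataFrame:
        rows = [
            (n.taxid, n.parent, n.rank, n.name)
            for n in sorted(self.nodes.values(), key=lambda n: n.taxid)
        ]
        return pd.DataFrame(rows, columns=["taxid", "parent", "rank", "name"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


# -- loaders ---------------------------------------------------------------


def _load_compact_tsv(path: Path) -> dict[int, TaxNode]:
    df = pd.read_csv(path, sep="\t", dtype={"taxid": int, "parent": int, "rank": str, "name": str})
    required = {"taxid", "parent", "rank", "name"}
    if not required.issubset(df.columns):
        raise InputError(f"compact taxonomy TSV must have columns {sorted(required)}")
    return {
        int(r.taxid): TaxNode(int(r.taxid), int(r.parent), str(r.rank), str(r.name))
        for r in df.itertuples()
    }


def _split_dmp(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]


def _load_dmp(nodes_path: Path, names_path: Path | None) -> dict[int, TaxNode]:
    names: dict[int, str] = {}
    if names_path is not None:
        for line in Path(names_path).read_text().splitlines():
            if not line.strip():
                continue
            fields = _split_dmp(line)
            # names.dmp: taxid | name | unique name | name class
            if len(fields) >= 4 and fields[3] == "scientific name":
                names[int(fields[0])] = fields[1]
            elif len(fields) < 4 and int(fields[0]) not in names:
                names[int(fields[0])] = fields[1]
    nodes: dict[int, TaxNode] = {}
    for line in Path(nodes_path).read_text().splitlines():
        if not line.strip():
            continue
        fields = _split_dmp(line)
        if len(fields) < 3:
            raise InputError(f"malformed nodes.dmp line: {line!r}")
        taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        nodes[taxid] = TaxNode(taxid, parent, rank, names.get(taxid, str(taxid)))
    return nodes


def _load_merged(path: Path) -> dict[int, int]:
    merged = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = _split_dmp(line)
        merged[int(fields[0])] = int(fields[1])
    return merged


def load_taxonomy(
    nodes_source: str | Path,
    names_source: str | Path | None = None,
    merged_source: str | Path | None = None,
) -> TaxonomyTree:
    """Load a taxonomy from NCBI dump files or a compact TSV.

    The format is auto-detected from the first line of *nodes_source*:
    ``\\t|\\t``-separated fields select the dump dialect, otherwise the file
    must be a 4-column TSV with header ``taxid  parent  rank  name``.
    """
    nodes_path = Path(nodes_source)
    try:
        with open(nodes_path) as fh:
            first = fh.readline()
    except OSError as exc:
        raise InputError(f"cannot read taxonomy from {nodes_path}: {exc}") from exc
    if not first.strip():
        raise InputError(f"empty taxonomy file: {nodes_path}")

    if "\t|\t" in first:
        nodes = _load_dmp(nodes_path, Path(names_source) if names_source else None)
    else:
        nodes = _load_compact_tsv(nodes_path)
    merged = _load_merged(Path(merged_source)) if merged_source else None
    return TaxonomyTree(nodes, merged=merged)


# -- assignment normalization ---------------------------------------------


def normalize_assignments(
    tree: TaxonomyTree,
    raw: pd.DataFrame,
    rank: str,
    strict: bool = False,
) -> pd.DataFrame:
    """Project an assignment table onto a fixed rank.

    *raw* must have columns ``read_id``, ``status``, ``taxid``; for
    classified rows ``taxid`` may be an integer taxid or a scientific name.
    Classified entries are replaced by their ancestor at *rank*; entries
    whose lineage carries no node of that rank (calls coarser than the rank)
    become unclassified-at-rank.  Unclassified and discarded rows pass
    through.  Row count and read ids are preserved.
    """
    out_status: list[str] = []
    out_taxid: list[object] = []
    for row in raw.itertuples():
        status = row.status
        if status != CLASSIFIED:
            out_status.append(status)
            out_taxid.append(pd.NA)
            continue
        taxon = row.taxid
        try:
            if isinstance(taxon, str) and not str(taxon).lstrip("-").isdigit():
                taxid = tree.resolve_name(taxon, strict=strict)
            else:
                taxid = tree.get(int(taxon)).taxid
        except UnknownTaxonError:
            if strict:
                raise
            logger.warning("read %s: unresolvable taxon %r, marking unclassified", row.read_id, taxon)
            out_status.append(UNCLASSIFIED)
            out_taxid.append(pd.NA)
            continue
        anc = tree.ancestor_at_rank(taxid, rank)
        if anc is None:
            out_status.append(UNCLASSIFIED)
            out_taxid.append(pd.NA)
        else:
            out_status.append(CLASSIFIED)
            out_taxid.append(anc)
    return pd.DataFrame(
        {"read_id": raw["read_id"].to_numpy(), "status": out_status, "taxid": out_taxid}
    )
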