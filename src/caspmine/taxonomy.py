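"""NCBI-taxdump loading and lineage-based group labels.

Group labels follow the survey's convention for bacterial groups: the
phylum, except for Proteobacteria where the class is used instead
(Alphaproteobacteria, Betaproteobacteria, ...).  Order-level labels are
available through the ``rank`` parameter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaxonNode:
    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str


class TaxonTable:
    """Taxid-indexed taxonomy with lineage resolution."""

    def __init__(self, nodes: dict[int, TaxonNode]):
        self.nodes = nodes
        self._validate()

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.taxid == n.parent_taxid]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0].taxid
        for n in self.nodes.values():
            if n.parent_taxid not in self.nodes:
                raise ValueError(f"orphan parent {n.parent_taxid} of taxid {n.taxid}")
        # cycle check: every lineage must terminate at the root
        for taxid in self.nodes:
            self.lineage(taxid)

    def lineage(self, taxid: int) -> list[TaxonNode]:
        """Path from the node up to (and including) the root."""
        if taxid not in self.nodes:
            raise KeyError(f"unknown taxid {taxid}")
        path = []
        seen = set()
        node = self.nodes[taxid]
        while True:
            if node.taxid in seen:
                raise ValueError(f"cyclic parent links at taxid {node.taxid}")
            seen.add(node.taxid)
            path.append(node)
            if node.taxid == node.parent_taxid:
                return path
            node = self.nodes[node.parent_taxid]

    def ancestor_at_rank(self, taxid: int, rank: str) -> TaxonNode | None:
        for node in self.lineage(taxid):
            if node.rank == rank:
                return node
        return None

    def superkingdom(self, taxid: int) -> str:
        node = self.ancestor_at_rank(taxid, "superkingdom")
        return node.scientific_name if node else "unknown"


def _parse_dmp(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t|\t")]
            fields[-1] = fields[-1].rstrip("\t|")
            rows.append(fields)
    return rows


def load_taxdump(nodes_file: str | Path, names_file: str | Path) -> TaxonTable:
    """Load nodes.dmp / names.dmp (pipe-tab dialect); scientific names only."""
    names: dict[int, str] = {}
    for fields in _parse_dmp(names_file):
        taxid, name, _unique, name_class = (fields + ["", "", "", ""])[:4]
        if name_class.strip().rstrip("|").strip() == "scientific name":
            names[int(taxid)] = name
    nodes: dict[int, TaxonNode] = {}
    for fields in _parse_dmp(nodes_file):
        taxid = int(fields[0])
        if taxid in nodes:
            raise ValueError(f"duplicate taxid {taxid} in nodes file")
        nodes[taxid] = TaxonNode(
            taxid=taxid,
            parent_taxid=int(fields[1]),
            rank=fields[2],
            scientific_name=names.get(taxid, f"taxid:{taxid}"),
        )
    return TaxonTable(nodes)


def group_label(taxid: int, table: TaxonTable, rank: str = "phylum") -> str:
    """Survey grouping label for a taxid.

    With the default ``rank='phylum'``: the phylum name, except that
    Proteobacteria are resolved to their class.  With another rank (e.g.
    ``'order'``) the ancestor at that rank.  Unresolvable taxids label as
    'unknown' with a logged warning.
    """
    try:
        lineage = table.lineage(taxid)
    except KeyError:
        logger.warning("taxid %s not in taxonomy; labelled 'unknown'", taxid)
        return "unknown"
    by_rank = {n.rank: n.scientific_name for n in lineage}
    if rank == "phylum":
        phylum = by_rank.get("phylum")
        if phylum is None:
            return "unknown"
        if phylum == "Proteobacteria":
            return by_rank.get("class", phylum)
        return phylum
    name = by_rank.get(rank)
    return name if name is not None else "unknown"


def write_taxdump(
    table: TaxonTable, nodes_file: str | Path, names_file: str | Path
) -> None:
    """Write a taxon table back out in the taxdump dmp dialect."""
    with open(nodes_file, "w") as fh:
        for n in sorted(table.nodes.values(), key=lambda n: n.taxid):
            fh.write(f"{n.taxid}\t|\t{n.parent_taxid}\t|\t{n.rank}\t|\n")
    with open(names_file, "w") as fh:
        for n in sorted(table.nodes.values(), key=lambda n: n.taxid):
            fh.write(f"{n.taxid}\t|\t{n.scientific_name}\t|\t\t|\tscientific name\t|\n")
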