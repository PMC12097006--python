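"""Minimal NCBI taxdump access: parent pointers, ranks, names, lineages.

Reads the standard ``nodes.dmp`` / ``names.dmp`` pair (fields separated
by ``\\t|\\t``, lines terminated by ``\\t|``).  Name resolution tries
scientific names first, then synonyms/equivalent names.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class Lineage:
    """Root-to-leaf path of (rank, name, taxid) triples for one taxid."""

    taxid: int
    ranked_names: list[tuple[str, str, int]]  # (rank, name, taxid), root first

    def names(self) -> list[str]:
        return [n for _, n, _ in self.ranked_names]

    def rank_name(self, rank: str) -> str | None:
        for r, n, _ in self.ranked_names:
            if r == rank:
                return n
        return None


def _split_dmp(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\n").rstrip("\t|").split("\t|\t")]


class TaxDb:
    """In-memory taxdump: taxid -> (parent, rank, scientific name)."""

    def __init__(self, nodes_path, names_path):
        self.parent: dict[int, int] = {}
        self.rank: dict[int, str] = {}
        self.name: dict[int, str] = {}
        self._sci_index: dict[str, int] = {}
        self._syn_index: dict[str, int] = {}
        with open(nodes_path) as fh:
            for line in fh:
                fields = _split_dmp(line)
                taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
                self.parent[taxid] = parent
                self.rank[taxid] = rank
        with open(names_path) as fh:
            for line in fh:
                fields = _split_dmp(line)
                taxid, name_txt, name_class = int(fields[0]), fields[1], fields[3]
                if name_class == "scientific name":
                    self.name[taxid] = name_txt
                    self._sci_index[name_txt.lower()] = taxid
                elif name_class in ("synonym", "equivalent name", "genbank synonym"):
                    self._syn_index.setdefault(name_txt.lower(), taxid)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.parent

    def resolve_name(self, organism: str) -> int | None:
        """Taxid for an organism name, or None when unresolvable."""
        key = organism.strip().lower()
        return self._sci_index.get(key, self._syn_index.get(key))

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """Nearest ancestor (inclusive) with the given rank."""
        node = taxid
        seen: set[int] = set()
        while node not in seen:
            seen.add(node)
            if self.rank.get(node) == rank:
                return node
            parent = self.parent.get(node)
            if parent is None or parent == node:
                return None
            node = parent
        return None

    def lineage(self, taxid: int) -> Lineage:
        """Walk parent pointers to the root; raises on unknown taxids."""
        if taxid not in self.parent:
            raise KeyError(f"unknown taxid: {taxid}")
        path: list[tuple[str, str, int]] = []
        node = taxid
        seen: set[int] = set()
        while node not in seen:
            seen.add(node)
            path.append((self.rank.get(node, "no rank"),
                         self.name.get(node, str(node)), node))
            parent = self.parent.get(node)
            if parent is None or parent == node:
                break
            node = parent
        path.reverse()
        return Lineage(taxid=taxid, ranked_names=path)
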