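"""Phyletic classification of peptide families.

Each family is assigned an evolutionary origin: the last common ancestor
(LCA) of the terminal taxa it occurs in, on a rooted clade tree.  The
default tree follows the Conchifera/Aculifera hypothesis for Mollusca
embedded in the standard metazoan backbone
(Eumetazoa > Bilateria > Protostomia > Lophotrochozoa > Mollusca >
{Conchifera, Aculifera} > class-level taxa), so origins are reported as
eumetazoan, bilaterian, protostomian, lophotrochozoan, molluscan, or
class-level.  Per-taxon "minimum complement" counts (the number of families
with at least one member detected in a taxon) are tabulated from the
presence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: Default clade tree: nested mapping; leaves are empty mappings.
DEFAULT_CLADE_TREE: dict = {
    "Eumetazoa": {
        "Cnidaria": {},
        "Bilateria": {
            "Deuterostomia": {
                "Chordata": {},
                "Echinodermata": {},
            },
            "Protostomia": {
                "Ecdysozoa": {
                    "Arthropoda": {},
                    "Nematoda": {},
                },
                "Lophotrochozoa": {
                    "Annelida": {},
                    "Brachiopoda": {},
                    "Ectoprocta": {},
                    "Entoprocta": {},
                    "Gastrotricha": {},
                    "Nemertea": {},
                    "Phoronida": {},
                    "Platyhelminthes": {},
                    "Rotifera": {},
                    "Mollusca": {
                        "Conchifera": {
                            "Gastropoda": {},
                            "Bivalvia": {},
                            "Cephalopoda": {},
                            "Scaphopoda": {},
                            "Monoplacophora": {},
                        },
                        "Aculifera": {
                            "Polyplacophora": {},
                            "Neomeniomorpha": {},
                            "Chaetodermomorpha": {},
                        },
                    },
                },
            },
        },
    }
}


class CladeTree:
    """Rooted tree of named clades; leaves are terminal taxa."""

    def __init__(self, nested: Mapping[str, Mapping]) -> None:
        if len(nested) != 1:
            raise ValueError("clade tree must have exactly one root")
        self.parent: dict[str, str | None] = {}
        self.children: dict[str, list[str]] = {}
        self.root = next(iter(nested))

        def walk(name: str, sub: Mapping, parent: str | None) -> None:
            if name in self.parent:
                raise ValueError(f"duplicate clade name {name!r}")
            self.parent[name] = parent
            self.children[name] = list(sub)
            for child, csub in sub.items():
                walk(child, csub, name)

        walk(self.root, nested[self.root], None)

    @classmethod
    def default(cls) -> "CladeTree":
        return cls(DEFAULT_CLADE_TREE)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CladeTree":
        with open(path) as fh:
            nested = yaml.safe_load(fh)
        return cls(nested)

    def to_yaml(self, path: str | Path) -> None:
        def rebuild(name: str) -> dict:
            return {c: rebuild(c) for c in self.children[name]}

        with open(path, "w") as fh:
            yaml.safe_dump({self.root: rebuild(self.root)}, fh, sort_keys=False)

    @property
    def leaves(self) -> list[str]:
        return [n for n, c in self.children.items() if not c]

    def ancestors(self, name: str) -> list[str]:
        """Path from ``name`` up to the root, inclusive."""
        if name not in self.parent:
            raise ValueError(f"unknown taxon or clade {name!r}")
        path = [name]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path

    def to_newick(self) -> str:
        def render(name: str) -> str:
            kids = self.children[name]
            if not kids:
                return name
            return "(" + ",".join(render(k) for k in kids) + ")" + name

        return render(self.root) + ";"


def assign_origin(taxa_present: Iterable[str], tree: CladeTree) -> str:
    """Name of the lowest clade ancestral to every taxon in the set."""
    taxa = list(taxa_present)
    if not taxa:
        raise ValueError("taxa_present must be non-empty")
    leaves = set(tree.leaves)
    for t in taxa:
        if t not in leaves:
            raise ValueError(f"unknown terminal taxon {t!r}")
    # intersect root-ward paths; the LCA is the deepest shared clade
    paths = [tree.ancestors(t) for t in taxa]
    shared = set(paths[0])
    for p in paths[1:]:
        shared &= set(p)
    for clade in paths[0]:  # ordered leaf -> root, first shared is lowest
        if clade in shared:
            return clade
    raise RuntimeError("tree has no common root")  # pragma: no cover


@dataclass
class FamilyAssignment:
    """One peptide family with its members, phyletic distribution, origin."""

    family_id: str
    members: list[str]
    taxa_present: set[str]
    origin: str = ""

    def classify(self, tree: CladeTree) -> "FamilyAssignment":
        self.origin = assign_origin(self.taxa_present, tree)
        return self


def complement_matrix(
    families: Sequence[FamilyAssignment],
    taxa: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Family-by-taxon presence matrix and per-taxon complement counts.

    ``matrix[family, taxon]`` is True when at least one member of the family
    carries that taxon; the per-taxon count (column sum) is the taxon's
    minimum peptide-family complement.
    """
    matrix = pd.DataFrame(
        False, index=[f.family_id for f in families], columns=list(taxa), dtype=bool
    )
    for f in families:
        for t in f.taxa_present:
            if t in matrix.columns:
                matrix.loc[f.family_id, t] = True
    counts = matrix.sum(axis=0)
    counts.name = "n_families"
    return matrix, counts
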