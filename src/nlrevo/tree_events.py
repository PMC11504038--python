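"""Gene-tree event calling: duplications and horizontal transfers.

The rules operate on a rooted gene tree whose leaves are labelled with both a
gene identifier and a species identifier.  A *duplication* is scored wherever
genes of one species form a maximal monophyletic group of two or more leaves.
A *horizontal transfer* is scored when the diversity of one species is nested
inside that of another: walking rootward from a maximal single-species clade,
each of the next ``context_depth`` enclosing clades must add leaves of one and
the same other species (the donor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Mapping, Optional, Sequence

import dendropy

__all__ = [
    "GeneTree",
    "DuplicationEvent",
    "HGTEvent",
    "maximal_species_clades",
    "call_duplications",
    "call_hgt",
    "hgt_matrix",
]


class GeneTree:
    """A rooted gene tree with an optional gene -> species mapping.

    Wraps a :class:`dendropy.Tree`.  Leaf labels are gene identifiers and must
    be unique; internal node labels, when numeric, are read as support values
    on a 0-100 scale.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        species_map: Optional[Mapping[str, str]] = None,
        explicitly_unrooted: bool = False,
    ) -> None:
        self.tree = tree
        self.species_map = dict(species_map) if species_map is not None else None
        self.explicitly_unrooted = explicitly_unrooted
        labels = self.leaf_ids
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels in gene tree: {dupes}")

    # -- basic accessors ---------------------------------------------------
    @property
    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label if lf.taxon else (lf.label or "")
                for lf in self.tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self.tree.leaf_nodes())

    def species_of(self, gene_id: str) -> str:
        if self.species_map is None:
            raise ValueError("gene tree has no species map")
        try:
            return self.species_map[gene_id]
        except KeyError:
            raise ValueError(f"leaf {gene_id!r} has no species label") from None

    def with_species(self, species_map: Mapping[str, str]) -> "GeneTree":
        return GeneTree(self.tree, species_map, self.explicitly_unrooted)

    def as_newick(self) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip() + "\n"

    def midpoint_root(self) -> "GeneTree":
        clone = self.tree.clone(depth=1)
        clone.reroot_at_midpoint(update_bipartitions=False)
        return GeneTree(clone, self.species_map, explicitly_unrooted=False)

    @classmethod
    def from_newick(cls, newick: str,
                    species_map: Optional[Mapping[str, str]] = None) -> "GeneTree":
        from .io_formats import parse_newick  # local import: io depends on us
        gt = parse_newick(newick)
        return cls(gt.tree, species_map, gt.explicitly_unrooted)


@dataclass(frozen=True)
class DuplicationEvent:
    species_id: str
    clade_leaf_ids: frozenset[str]
    n_events: int

    def __post_init__(self) -> None:
        if len(self.clade_leaf_ids) < 2:
            raise ValueError("duplication clade must contain >= 2 genes")
        if self.n_events < 1:
            raise ValueError("n_events must be positive")


@dataclass(frozen=True)
class HGTEvent:
    donor_species: str
    recipient_species: str
    recipient_clade_leaf_ids: frozenset[str]
    context_depth: int

    def __post_init__(self) -> None:
        if self.donor_species == self.recipient_species:
            raise ValueError("HGT donor and recipient species must differ")


def _support_of(node: dendropy.Node) -> Optional[float]:
    if node.label is None:
        return None
    try:
        return float(node.label)
    except ValueError:
        return None


def _leaf_label(leaf: dendropy.Node) -> str:
    return leaf.taxon.label if leaf.taxon else (leaf.label or "")


def _prepared(tree: GeneTree) -> dendropy.Tree:
    """Annotate every node with its leaf-gene set and species set."""
    if tree.species_map is None:
        raise ValueError("event calling requires a gene -> species map")
    t = tree.tree
    if tree.explicitly_unrooted:
        warnings.warn(
            "gene tree was supplied explicitly unrooted; midpoint-rooting it "
            "for event calling", stacklevel=3)
        tree = tree.midpoint_root()
        t = tree.tree
    for node in t.postorder_node_iter():
        if node.is_leaf():
            gid = _leaf_label(node)
            node._genes = frozenset([gid])
            node._species = frozenset([tree.species_of(gid)])
        else:
            node._genes = frozenset().union(*(c._genes for c in node.child_nodes()))
            node._species = frozenset().union(*(c._species for c in node.child_nodes()))
    return t


def maximal_species_clades(tree: GeneTree) -> list[tuple[str, frozenset[str]]]:
    """Maximal single-species clades, singletons included.

    Every leaf belongs to exactly one returned clade; a clade is returned when
    all its leaves share one species and its parent clade (if any) does not.
    """
    t = _prepared(tree)
    out: list[tuple[str, frozenset[str]]] = []
    for node in t.preorder_node_iter():
        if len(node._species) == 1:
            parent = node.parent_node
            if parent is None or len(parent._species) > 1:
                (sp,) = node._species
                out.append((sp, node._genes))
    return out


def call_duplications(
    tree: GeneTree,
    mode: Literal["node_count", "per_clade"] = "node_count",
) -> list[DuplicationEvent]:
    """Score duplications from maximal single-species clades of size >= 2.

    ``node_count`` scores each coalescence inside the clade (clade of *n*
    genes = *n*-1 events); ``per_clade`` scores the whole clade as one event.
    """
    if mode not in ("node_count", "per_clade"):
        raise ValueError(f"unknown duplication mode {mode!r}")
    events = []
    for sp, genes in maximal_species_clades(tree):
        if len(genes) < 2:
            continue
        n = len(genes) - 1 if mode == "node_count" else 1
        events.append(DuplicationEvent(sp, frozenset(genes), n))
    return events


def call_hgt(
    tree: GeneTree,
    context_depth: int = 2,
    min_support: float = 0.0,
    min_clade_size: int = 1,
) -> list[HGTEvent]:
    """Call directed transfers from species nesting patterns.

    For each maximal single-species clade (recipient species A), the next
    ``context_depth`` enclosing clades must each add leaves belonging to one
    single other species B; B is then the donor.  A mixed context, or hitting
    the root early, yields no call.  When internal supports are present,
    context nodes below ``min_support`` suppress the call.
    """
    if context_depth < 1:
        raise ValueError("context_depth must be >= 1")
    t = _prepared(tree)
    events: list[HGTEvent] = []
    for node in t.preorder_node_iter():
        if len(node._species) != 1:
            continue
        parent = node.parent_node
        if parent is not None and len(parent._species) == 1:
            continue  # not maximal
        (recipient,) = node._species
        if len(node._genes) < min_clade_size:
            continue
        donor: Optional[str] = None
        cur = node
        ok = True
        for _ in range(context_depth):
            par = cur.parent_node
            if par is None:
                ok = False
                break
            added_species = frozenset().union(
                *(c._species for c in par.child_nodes() if c is not cur))
            if len(added_species) != 1:
                ok = False
                break
            (sp,) = added_species
            if sp == recipient or (donor is not None and sp != donor):
                ok = False
                break
            donor = sp
            sup = _support_of(par)
            if sup is not None and min_support > 0 and sup < min_support:
                ok = False
                break
            cur = par
        if ok and donor is not None:
            events.append(HGTEvent(donor, recipient, frozenset(node._genes),
                                   context_depth))
    return events


def hgt_matrix(
    events: Iterable[HGTEvent],
    species: Sequence[str],
):
    """Donor-by-recipient transfer-count matrix (pandas DataFrame).

    Rows are donors, columns recipients; the grand total equals the number of
    events and the diagonal is structurally zero.
    """
    import numpy as np
    import pandas as pd

    species = list(species)
    idx = {s: i for i, s in enumerate(species)}
    mat = np.zeros((len(species), len(species)), dtype=int)
    for ev in events:
        if ev.donor_species not in idx or ev.recipient_species not in idx:
            raise ValueError(
                f"event species {ev.donor_species!r}->{ev.recipient_species!r} "
                "not in the species list")
        mat[idx[ev.donor_species], idx[ev.recipient_species]] += 1
    return pd.DataFrame(mat, index=species, columns=species)
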