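"""NLR candidate screening and domain-architecture classification.

NLR (nucleotide-binding leucine-rich repeat) proteins are gated on the
NB-ARC domain and classified by their N-terminal domain into TNL (TIR),
RNL (RPW8), CNL (Rx_N, the four-helix bundle annotated in place of the
classical coiled-coil) or plain NL (neither).  Candidate sets from an HMM
search and a BLAST homology search are merged, then filtered by where the
candidates fall in a reference phylogeny containing known plant R proteins
and non-plant NB-ARC homologs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import DomainHit
from .tree_events import GeneTree, _leaf_label

__all__ = [
    "DomainArchitecture",
    "NLRClass",
    "ReferenceLabel",
    "merge_candidates",
    "filter_by_phylogeny",
    "classify_architecture",
    "drop_redundant_isoforms",
]


class NLRClass(str, Enum):
    TNL = "TNL"
    CNL = "CNL"
    RNL = "RNL"
    NL = "NL"
    NOT_NLR = "NOT_NLR"


# Canonical domain names and the aliases (incl. Pfam accessions) they match.
_ALIASES = {
    "NB-ARC": {"NB-ARC", "NBARC", "NB_ARC", "NBS", "PF00931"},
    "TIR": {"TIR", "TIR_2", "PF01582", "PF13676"},
    "RPW8": {"RPW8", "PF05659"},
    "Rx_N": {"RX_N", "RX-N", "RXN", "PF18052"},
}


def _canonical(name: str) -> Optional[str]:
    key = name.strip().upper().split(".")[0]
    for canon, aliases in _ALIASES.items():
        if key in {a.upper() for a in aliases}:
            return canon
    if key.startswith("LRR") or key.startswith("PF12799") or key.startswith("PF13855"):
        return "LRR"
    return None


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered domain hits on one protein plus derived presence flags."""

    protein_id: str
    domains: tuple[DomainHit, ...]
    has_nbarc: bool
    has_tir: bool
    has_rpw8: bool
    has_rxn: bool
    has_lrr: bool

    @classmethod
    def from_hits(cls, protein_id: str,
                  hits: Iterable[DomainHit]) -> "DomainArchitecture":
        mine = sorted((h for h in hits if h.protein_id == protein_id),
                      key=lambda h: (h.env_start, h.env_end))
        canon = {_canonical(h.domain_name) for h in mine}
        return cls(
            protein_id=protein_id,
            domains=tuple(mine),
            has_nbarc="NB-ARC" in canon,
            has_tir="TIR" in canon,
            has_rpw8="RPW8" in canon,
            has_rxn="Rx_N" in canon,
            has_lrr="LRR" in canon,
        )

    @property
    def n_terminal_domains(self) -> frozenset[str]:
        """Which of the three class-defining N-terminal domains are present."""
        out = set()
        if self.has_tir:
            out.add("TIR")
        if self.has_rpw8:
            out.add("RPW8")
        if self.has_rxn:
            out.add("Rx_N")
        return frozenset(out)

    @property
    def is_multi_nterminal(self) -> bool:
        return len(self.n_terminal_domains) > 1


@dataclass(frozen=True)
class ReferenceLabel:
    leaf_id: str
    label: str  # candidate | plant_R | non_plant | outgroup

    def __post_init__(self) -> None:
        if self.label not in ("candidate", "plant_R", "non_plant", "outgroup"):
            raise ValueError(f"unknown reference label {self.label!r}")


def merge_candidates(hmm_ids: Iterable[str], blast_ids: Iterable[str]) -> set[str]:
    """Union of the HMM-search and BLAST-search candidate id sets."""
    return set(hmm_ids) | set(blast_ids)


def classify_architecture(arch: DomainArchitecture) -> NLRClass:
    """Assign exactly one NLR class from domain presence.

    NB-ARC gates NLR status; among NB-ARC proteins the N-terminal domain
    decides the class with precedence TIR > RPW8 > Rx_N, and proteins with
    none of the three (with or without LRRs) are NL.  LRR presence never
    changes the class.
    """
    if not arch.has_nbarc:
        return NLRClass.NOT_NLR
    if arch.has_tir:
        return NLRClass.TNL
    if arch.has_rpw8:
        return NLRClass.RNL
    if arch.has_rxn:
        return NLRClass.CNL
    return NLRClass.NL


def filter_by_phylogeny(
    tree: GeneTree,
    labels: Sequence[ReferenceLabel],
    mode: str = "strict",
) -> set[str]:
    """Retain candidates that group with plant R proteins, not non-plant ones.

    strict (default): a candidate is kept iff the smallest clade containing
    it and at least one reference leaf (plant_R or non_plant) contains no
    non_plant reference.  permissive: kept iff some enclosing clade up to the
    root consists solely of candidates and plant_R leaves (at least one of
    the latter).
    """
    if mode not in ("strict", "permissive"):
        raise ValueError(f"unknown filter mode {mode!r}")
    label_of = {l.leaf_id: l.label for l in labels}
    t = tree.tree
    for lf in t.leaf_node_iter():
        gid = _leaf_label(lf)
        if gid not in label_of:
            raise ValueError(f"leaf {gid!r} has no reference label")
    n_ref = sum(1 for v in label_of.values() if v in ("plant_R", "non_plant"))
    if n_ref == 0:
        raise ValueError("tree contains no plant_R or non_plant reference leaves")

    # per-node counts of each label among descendant leaves
    for node in t.postorder_node_iter():
        if node.is_leaf():
            lab = label_of[_leaf_label(node)]
            node._counts = {lab: 1}
        else:
            counts: dict[str, int] = {}
            for c in node.child_nodes():
                for k, v in c._counts.items():
                    counts[k] = counts.get(k, 0) + v
            node._counts = counts

    retained: set[str] = set()
    for lf in t.leaf_node_iter():
        gid = _leaf_label(lf)
        if label_of[gid] != "candidate":
            continue
        if mode == "strict":
            node = lf
            while node is not None:
                c = node._counts
                if c.get("plant_R", 0) + c.get("non_plant", 0) >= 1:
                    if c.get("non_plant", 0) == 0:
                        retained.add(gid)
                    break
                node = node.parent_node
        else:  # permissive
            node = lf.parent_node
            while node is not None:
                c = node._counts
                pure = (c.get("non_plant", 0) == 0 and c.get("outgroup", 0) == 0
                        and c.get("plant_R", 0) >= 1)
                if pure:
                    retained.add(gid)
                    break
                node = node.parent_node
    return retained


def drop_redundant_isoforms(
    records: Iterable[tuple[str, str, float]],
) -> set[str]:
    """Keep one protein per locus: the longest isoform, ties broken by the
    lexicographically smallest protein id.  Removes alternative-splicing
    redundancy when several protein models share a locus."""
    best: dict[str, tuple[float, str]] = {}
    for protein_id, locus_id, length in records:
        if length < 0:
            raise ValueError(f"negative length for {protein_id!r}")
        # rank: longer wins; at equal length the smaller id wins
        cand = (-float(length), protein_id)
        if locus_id not in best or cand < best[locus_id]:
            best[locus_id] = cand
    return {pid for _, pid in best.values()}
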