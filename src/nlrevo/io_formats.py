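"""Readers and writers for the file formats the toolkit consumes.

Supported inputs: hmmscan ``--domtblout`` tables and a plain five-column TSV
for protein-domain hits, 12-column tabular BLAST output, newick trees, and
CSV tables of per-event recombination-method p-values.  Output tables are
plain CSV (UTF-8, ``\\n`` line endings, ``.`` decimal separator).
"""

from __future__ import annotations

import csv
import dataclasses
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence, Union

import dendropy

from .tree_events import GeneTree

__all__ = [
    "DomainHit",
    "BlastHit",
    "RecombMethodTable",
    "RECOMB_METHODS",
    "read_domain_table",
    "read_blast_hits",
    "read_newick_tree",
    "parse_newick",
    "write_newick_tree",
    "read_recomb_pvalue_table",
    "write_table",
    "read_table",
]

#: The seven recombination-detection methods whose p-values the consensus
#: rule combines.
RECOMB_METHODS = ("RDP", "GENECONV", "Chimaera", "MaxChi", "BootScan",
                  "SiScan", "3Seq")


@dataclass(frozen=True)
class DomainHit:
    """One domain annotation on a protein (1-based inclusive envelope)."""

    protein_id: str
    domain_name: str
    env_start: int
    env_end: int
    e_value: float

    def __post_init__(self) -> None:
        if self.env_start < 1:
            raise ValueError("env_start must be >= 1")
        if self.env_end < self.env_start:
            raise ValueError("env_end must be >= env_start")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


@dataclass(frozen=True)
class BlastHit:
    query_id: str
    subject_id: str
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")


@dataclass(frozen=True)
class RecombMethodTable:
    """Per-candidate-event p-values from up to seven named methods."""

    event_id: str
    method_pvalues: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, p in self.method_pvalues.items():
            if name not in RECOMB_METHODS:
                raise ValueError(f"unknown recombination method {name!r}")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value for {name} outside [0, 1]: {p}")


def _parse_error(path: Union[str, Path], lineno: int, msg: str) -> ValueError:
    return ValueError(f"{path}:{lineno}: {msg}")


def read_domain_table(
    path: Union[str, Path],
    dialect: str = "generic_tsv",
    max_evalue: float = 10.0,
) -> list[DomainHit]:
    """Read domain hits with ``e_value <= max_evalue``, in file order.

    ``hmmscan_domtbl`` parses hmmscan ``--domtblout`` output, taking the
    per-domain independent E-value and the envelope coordinates; the profile
    name is the domain and the query name the protein.  ``generic_tsv``
    expects tab-separated ``protein_id, domain_name, env_start, env_end,
    e_value`` (an optional header whose first field is ``protein_id`` is
    skipped).  Lines starting with ``#`` are comments.
    """
    hits: list[DomainHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if dialect == "hmmscan_domtbl":
                f = line.split()
                if len(f) < 23:
                    raise _parse_error(path, lineno,
                                       f"expected >= 23 columns, got {len(f)}")
                pid, dom, ev, s, e = f[3], f[0], f[12], f[19], f[20]
            elif dialect == "generic_tsv":
                f = line.split("\t")
                if f and f[0] == "protein_id":
                    continue  # header row
                if len(f) != 5:
                    raise _parse_error(path, lineno,
                                       f"expected 5 tab-separated columns, got {len(f)}")
                pid, dom, s, e, ev = f
            else:
                raise ValueError(f"unknown domain-table dialect {dialect!r}")
            try:
                hit = DomainHit(pid, dom, int(s), int(e), float(ev))
            except ValueError as exc:
                raise _parse_error(path, lineno, str(exc)) from exc
            if hit.e_value <= max_evalue:
                hits.append(hit)
    return hits


def read_blast_hits(path: Union[str, Path], max_evalue: float = 1e-3) -> set[str]:
    """Distinct query ids with at least one tabular-BLAST hit at or below
    ``max_evalue`` (12-column outfmt-6 layout; E-value in column 11)."""
    if max_evalue <= 0:
        raise ValueError("max_evalue must be > 0")
    queries: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise _parse_error(path, lineno,
                                   f"expected 12 columns, got {len(f)}")
            try:
                ev = float(f[10])
            except ValueError as exc:
                raise _parse_error(path, lineno, f"bad E-value {f[10]!r}") from exc
            if ev < 0:
                raise _parse_error(path, lineno, "negative E-value")
            if ev <= max_evalue:
                queries.add(f[0])
    return queries


def parse_newick(text: str) -> GeneTree:
    """Parse one newick string into a rooted :class:`GeneTree`.

    Leaf labels are kept verbatim; numeric internal labels serve as support
    values; branch lengths are retained.  The tree is treated as rooted
    exactly as written unless the string carries an explicit ``[&U]`` flag.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise ValueError("newick string must end with ';'")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        msg = str(exc)
        if "Multiple occurrences of the same taxa" in msg or "Duplicate" in msg:
            raise ValueError(f"duplicate leaf labels in newick tree: {msg}") from exc
        raise ValueError(f"newick parse error: {msg}") from exc
    unrooted = "[&U]" in stripped.upper().replace(" ", "")
    return GeneTree(tree, explicitly_unrooted=unrooted)


def read_newick_tree(path: Union[str, Path]) -> GeneTree:
    """Read a single newick tree from a file."""
    with open(path, encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick_tree(tree: GeneTree, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_newick())


def read_recomb_pvalue_table(path: Union[str, Path]) -> list[RecombMethodTable]:
    """Read a CSV of per-event method p-values.

    The first column is ``event_id``; any further columns named after one of
    the seven methods carry p-values.  Empty cells mean the method was not
    run for that event.
    """
    tables: list[RecombMethodTable] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "event_id" not in reader.fieldnames:
            raise ValueError(f"{path}: missing 'event_id' column")
        method_cols = [c for c in reader.fieldnames if c in RECOMB_METHODS]
        for row in reader:
            pvals = {m: float(row[m]) for m in method_cols
                     if row[m] not in (None, "", "NA", "nan")}
            tables.append(RecombMethodTable(row["event_id"], pvals))
    return tables


Record = Union[Mapping[str, Any], Any]


def _record_items(rec: Record) -> list[tuple[str, Any]]:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        return [(f.name, getattr(rec, f.name)) for f in dataclasses.fields(rec)]
    if isinstance(rec, Mapping):
        return list(rec.items())
    raise TypeError(f"unsupported record type {type(rec).__name__}")


def write_table(records: Sequence[Record], path: Union[str, Path],
                fieldnames: Optional[Sequence[str]] = None) -> None:
    """Write uniform records (dataclasses or mappings) as a CSV table.

    Field order follows the first record (or ``fieldnames``); records whose
    fields differ raise an error.  An empty sequence yields a header-only
    file when ``fieldnames`` is given, otherwise an empty file.
    """
    rows = [dict(_record_items(r)) for r in records]
    if fieldnames is None:
        fieldnames = list(rows[0].keys()) if rows else []
    for i, row in enumerate(rows):
        if list(row.keys()) != list(fieldnames):
            raise ValueError(f"record {i} fields {list(row)} do not match "
                             f"header {list(fieldnames)}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(fieldnames),
                                lineterminator="\n")
        writer.writeheader()
        writer.writerows(rows)


def read_table(path: Union[str, Path]) -> list[dict[str, str]]:
    """Read back a CSV written by :func:`write_table` (string-valued)."""
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))
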