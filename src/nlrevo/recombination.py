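"""Recombination detection: a maximum chi-square scan and the multi-method
consensus rule.

The built-in detector is a pairwise maximum chi-square (MaxChi) scan: along
the alignment's polymorphic columns (restricted to sites where neither
sequence of the pair has a gap or N), a fixed-width window is slid and at
each candidate point the 2x2 chi-square contrasting the pair's
match/mismatch counts in the left versus right half-window is computed; the
maximum is the test statistic and its significance comes from permuting
site order.  Calls from
up to seven external methods are combined by requiring a minimum number of
methods below a p-value threshold (defaults: four methods, p < 1e-6).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .io_formats import RECOMB_METHODS, RecombMethodTable

__all__ = [
    "Alignment",
    "RecombTestResult",
    "ConsensusCall",
    "read_alignment",
    "polymorphic_columns",
    "maxchi_test",
    "consensus_call",
]

_VALID = set("ACGTN-")


@dataclass(frozen=True)
class Alignment:
    """A nucleotide multiple alignment over {A, C, G, T, -, N}."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 sequences")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows are not equal length")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - _VALID
            if bad:
                raise ValueError(f"sequence {sid!r} has invalid characters {bad}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence id {seq_id!r} not in alignment") from None


def read_alignment(path: Union[str, Path]) -> Alignment:
    """Read a FASTA alignment."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class RecombTestResult:
    pair: tuple[str, str]
    max_chi2: float
    breakpoint_site: Optional[int]  # 1-based index into the polymorphic-site list
    breakpoint_column: Optional[int]  # 1-based alignment column of that site
    p_value: float
    n_permutations: int
    seed: int


def polymorphic_columns(aln: Alignment) -> np.ndarray:
    """0-based alignment columns with >= 2 distinct states among the
    non-gap, non-N characters of all rows."""
    mat = np.array([np.frombuffer(r.upper().encode(), dtype="S1")
                    for r in aln.rows])
    n_states = sum((mat == b).any(axis=0).astype(int)
                   for b in (b"A", b"C", b"G", b"T"))
    return np.nonzero(n_states >= 2)[0]


def _chi2_profile(mismatch: np.ndarray, half_window: int) -> np.ndarray:
    """2x2 chi-square at every candidate point of one (or many) site orders.

    ``mismatch`` is a 0/1 array (..., n_sites); returns (..., n_points) with
    one value per boundary placed after sites ``half_window .. n-half_window``.
    No continuity correction; degenerate tables (all-match or all-mismatch
    margins) score 0.
    """
    hw = half_window
    n = mismatch.shape[-1]
    zeros = np.zeros(mismatch.shape[:-1] + (1,), dtype=np.int64)
    cum = np.concatenate([zeros, np.cumsum(mismatch, axis=-1, dtype=np.int64)],
                         axis=-1)
    ks = np.arange(hw, n - hw + 1)
    m_left = cum[..., ks] - cum[..., ks - hw]
    m_right = cum[..., ks + hw] - cum[..., ks]
    a, b = m_left, hw - m_left
    c, d = m_right, hw - m_right
    col1, col2 = a + c, b + d
    num = 2.0 * hw * (a * d - b * c) ** 2
    den = (hw * hw * col1 * col2).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return chi


def maxchi_test(
    aln: Alignment,
    pair: tuple[str, str],
    half_window: int = 25,
    n_permutations: int = 500,
    seed: int = 0,
) -> RecombTestResult:
    """Pairwise MaxChi scan with a site-order permutation null.

    The site list is the alignment's polymorphic columns, further dropping
    sites where either sequence of the pair carries a gap or N.  The
    reported p-value is the add-one permutation estimate
    ``(1 + #{permuted max >= observed max}) / (n_permutations + 1)``; with
    fewer than ``2 * half_window`` usable sites, or a constant match/mismatch
    signal, there is no detectable breakpoint and the p-value is 1.
    """
    if half_window < 2:
        raise ValueError("half_window must be >= 2")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    s1 = np.frombuffer(aln.row(pair[0]).upper().encode(), dtype="S1")
    s2 = np.frombuffer(aln.row(pair[1]).upper().encode(), dtype="S1")
    poly = polymorphic_columns(aln)
    pair_ok = ~(np.isin(s1, [b"-", b"N"]) | np.isin(s2, [b"-", b"N"]))
    cols = poly[pair_ok[poly]]
    mismatch = (s1[cols] != s2[cols]).astype(np.int64)
    n = mismatch.size
    if n < 2 * half_window or mismatch.sum() in (0, n):
        return RecombTestResult(pair, 0.0, None, None, 1.0, n_permutations, seed)

    profile = _chi2_profile(mismatch, half_window)
    best = int(np.argmax(profile))
    max_chi2 = float(profile[best])
    # boundary after polymorphic site (half_window + best): 1-based index of
    # the last site of the left half
    bp_site = half_window + best
    bp_col = int(cols[bp_site - 1]) + 1

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.broadcast_to(mismatch, (n_permutations, n)), axis=1)
    null_max = _chi2_profile(perm, half_window).max(axis=1)
    p = (1.0 + int(np.sum(null_max >= max_chi2))) / (n_permutations + 1.0)
    return RecombTestResult(pair, max_chi2, bp_site, bp_col, p,
                            n_permutations, seed)


@dataclass(frozen=True)
class ConsensusCall:
    event_id: str
    n_supporting: int
    significant: bool


def consensus_call(
    table: RecombMethodTable,
    min_methods: int = 4,
    alpha: float = 1e-6,
) -> ConsensusCall:
    """Combine per-method p-values: an event is significant when at least
    ``min_methods`` methods report p strictly below ``alpha``.  Methods with
    no p-value count as non-supporting."""
    if not (1 <= min_methods <= len(RECOMB_METHODS)):
        raise ValueError("min_methods must be in 1..7")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    for name, p in table.method_pvalues.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value for {name} outside [0, 1]: {p}")
    n = sum(1 for p in table.method_pvalues.values() if p < alpha)
    return ConsensusCall(table.event_id, n, n >= min_methods)
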