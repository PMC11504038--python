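"""Positive-selection summaries from codon-model likelihoods and BEB sites.

Takes the per-group log-likelihoods of the M7 (beta) and M8 (beta plus a
positive-selection class) codon models and the Bayes-empirical-Bayes site
posteriors computed upstream, performs the M7-vs-M8 likelihood-ratio test
(chi-square, 2 degrees of freedom, so the upper tail is exp(-stat/2)), and
labels a group positively selected when the test is significant and at least
one site passes the posterior cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "GroupLikelihoods",
    "BEBSite",
    "SelectionCall",
    "lrt_m7m8",
    "classify_selection_groups",
    "summarize_selection",
    "read_likelihoods_tsv",
    "read_beb_tsv",
]


@dataclass(frozen=True)
class GroupLikelihoods:
    group_id: str
    lnL_m7: float
    lnL_m8: float


@dataclass(frozen=True)
class BEBSite:
    group_id: str
    site_index: int  # 1-based codon position
    posterior: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior <= 1.0):
            raise ValueError("posterior must be in [0, 1]")
        if self.site_index < 1:
            raise ValueError("site_index is 1-based")


@dataclass(frozen=True)
class SelectionCall:
    group_id: str
    lrt_stat: float
    p_value: float
    n_beb_sites: int
    verdict: str  # positive | negative


def lrt_m7m8(g: GroupLikelihoods) -> tuple[float, float]:
    """Likelihood-ratio statistic and p-value for M8 over M7.

    stat = max(0, 2*(lnL_M8 - lnL_M7)); negative differences (optimizer
    noise) clamp to 0.  With 2 degrees of freedom the chi-square upper tail
    has the closed form exp(-stat / 2).
    """
    if not (math.isfinite(g.lnL_m7) and math.isfinite(g.lnL_m8)):
        raise ValueError(f"non-finite log-likelihood for group {g.group_id!r}")
    stat = max(0.0, 2.0 * (g.lnL_m8 - g.lnL_m7))
    return stat, math.exp(-stat / 2.0)


def classify_selection_groups(
    lik: Sequence[GroupLikelihoods],
    sites: Sequence[BEBSite] = (),
    alpha: float = 0.05,
    min_posterior: float = 0.95,
) -> list[SelectionCall]:
    """One call per group: positive iff LRT p < alpha and >= 1 BEB site at
    or above the posterior cutoff."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if not (0.0 <= min_posterior <= 1.0):
        raise ValueError("min_posterior must be in [0, 1]")
    known = {g.group_id for g in lik}
    for s in sites:
        if s.group_id not in known:
            raise ValueError(f"BEB site references unknown group {s.group_id!r}")
    site_counts: dict[str, int] = {g.group_id: 0 for g in lik}
    for s in sites:
        if s.posterior >= min_posterior:
            site_counts[s.group_id] += 1
    calls = []
    for g in lik:
        stat, p = lrt_m7m8(g)
        n = site_counts[g.group_id]
        verdict = "positive" if (p < alpha and n >= 1) else "negative"
        calls.append(SelectionCall(g.group_id, stat, p, n, verdict))
    return calls


def summarize_selection(calls: Iterable[SelectionCall]) -> str:
    """``k/n`` summary: groups called positive over groups tested."""
    calls = list(calls)
    k = sum(1 for c in calls if c.verdict == "positive")
    return f"{k}/{len(calls)}"


def read_likelihoods_tsv(path: Union[str, Path]) -> list[GroupLikelihoods]:
    """TSV with header ``group_id  lnL_m7  lnL_m8``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    need = {"group_id", "lnL_m7", "lnL_m8"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return [GroupLikelihoods(str(r.group_id), float(r.lnL_m7), float(r.lnL_m8))
            for r in df.itertuples(index=False)]


def read_beb_tsv(path: Union[str, Path]) -> list[BEBSite]:
    """TSV with header ``group_id  site  posterior``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    need = {"group_id", "site", "posterior"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return [BEBSite(str(r.group_id), int(r.site), float(r.posterior))
            for r in df.itertuples(index=False)]
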