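"""Per-species class-count tables and count-versus-event correlations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .nlr_identify import NLRClass

__all__ = ["SpeciesCounts", "CorrelationResult", "counts_table",
           "correlate_counts_events", "plot_counts_vs_events"]


@dataclass(frozen=True)
class SpeciesCounts:
    species_id: str
    n_tnl: int
    n_cnl: int
    n_rnl: int
    n_nl: int

    @property
    def n_total(self) -> int:
        return self.n_tnl + self.n_cnl + self.n_rnl + self.n_nl


@dataclass(frozen=True)
class CorrelationResult:
    x_name: str
    y_name: str
    r: float
    p_value: float
    n: int
    method: str

    def is_significant(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def counts_table(
    assignments: Sequence[tuple[str, str, Union[str, NLRClass]]],
) -> list[SpeciesCounts]:
    """Tally per-species TNL/CNL/RNL/NL counts.

    ``assignments`` rows are (protein_id, species_id, class); rows must be
    pre-filtered to true NLRs (a NOT_NLR row is an error).  One row per
    species, in first-appearance order; the grand total equals the input
    length.
    """
    order: list[str] = []
    tally: dict[str, dict[str, int]] = {}
    for protein_id, species_id, cls in assignments:
        cls = NLRClass(cls)
        if cls is NLRClass.NOT_NLR:
            raise ValueError(
                f"{protein_id}: NOT_NLR rows are not allowed in counts_table")
        if species_id not in tally:
            order.append(species_id)
            tally[species_id] = {c.value: 0 for c in
                                 (NLRClass.TNL, NLRClass.CNL,
                                  NLRClass.RNL, NLRClass.NL)}
        tally[species_id][cls.value] += 1
    return [SpeciesCounts(s, tally[s]["TNL"], tally[s]["CNL"],
                          tally[s]["RNL"], tally[s]["NL"]) for s in order]


def correlate_counts_events(
    counts: Mapping[str, float],
    events: Mapping[str, float],
    method: str = "pearson",
    x_name: str = "nlr_count",
    y_name: str = "event_count",
) -> CorrelationResult:
    """Correlate per-species gene counts with per-species event counts.

    Both mappings must cover the same species (>= 3).  Pearson is the
    default; Spearman applies the same t-transform to rank correlations.
    """
    if set(counts) != set(events):
        raise ValueError("counts and events cover different species sets")
    species = sorted(counts)
    if len(species) < 3:
        raise ValueError("need >= 3 paired species observations")
    x = np.asarray([counts[s] for s in species], dtype=float)
    y = np.asarray([events[s] for s in species], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(x_name, y_name, float(res.statistic),
                             float(res.pvalue), len(species), method)


def plot_counts_vs_events(
    counts: Mapping[str, float],
    events: Mapping[str, float],
    result: Optional[CorrelationResult] = None,
    ax=None,
    xlabel: str = "NLR gene count",
    ylabel: str = "event count",
):
    """Scatter of per-species counts vs events with an annotation box."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(4, 4))
    species = sorted(counts)
    x = [counts[s] for s in species]
    y = [events[s] for s in species]
    ax.scatter(x, y)
    for s, xi, yi in zip(species, x, y):
        ax.annotate(s, (xi, yi), fontsize=7)
    if result is not None:
        ax.set_title(f"{result.method} r = {result.r:.2f}, "
                     f"p = {result.p_value:.3g} (n = {result.n})")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax
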