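"""Co-occurrence and correlation analyses for bivalent (dual-marked) genes.

A bivalent chromatin state is the co-localization of an activating and a
repressive histone modification (here typically H3K18ac and H3K27me3) on
the same genes.  Two complementary genome-scale signatures are computed:

* co-occurrence — the fraction of a gene universe marked by both
  modifications;
* correlation attribution — the Pearson correlation of per-gene densities
  between the two marks over the universe, re-computed after removing a
  candidate subset; a drop in r attributes the correlation to that subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .enrichment import EnrichmentResult
from .errors import ComputationError, InputError
from .signal_density import density_series

import pandas as pd


@dataclass(frozen=True)
class CoOccurrence:
    mark_a: str
    mark_b: str
    universe_id: str
    n_universe: int
    n_both: int
    genes: frozenset[str]

    @property
    def fraction(self) -> float:
        return self.n_both / self.n_universe

    @property
    def percent(self) -> int:
        """Fraction as the nearest integer percent (36.53% reports as 37)."""
        return int(round(100.0 * self.fraction))


@dataclass(frozen=True)
class CorrelationReport:
    mark_a: str
    mark_b: str
    set_id: str
    n: int
    pearson_r: float
    t_statistic: float
    p_value: float


def co_occurrence(
    marked_a: Iterable[str],
    marked_b: Iterable[str],
    universe: Iterable[str],
    mark_a: str = "mark_a",
    mark_b: str = "mark_b",
    universe_id: str = "universe",
) -> CoOccurrence:
    """Count genes of the universe marked by both modifications."""
    universe = frozenset(universe)
    if not universe:
        raise InputError("co_occurrence: empty universe")
    marked_a = frozenset(marked_a)
    marked_b = frozenset(marked_b)
    if not marked_a <= universe or not marked_b <= universe:
        raise InputError("co_occurrence: marked sets must be subsets of the universe")
    both = marked_a & marked_b
    return CoOccurrence(
        mark_a=mark_a,
        mark_b=mark_b,
        universe_id=universe_id,
        n_universe=len(universe),
        n_both=len(both),
        genes=both,
    )


def density_correlation(
    signals: pd.DataFrame,
    mark_a: str,
    mark_b: str,
    gene_set: Sequence[str],
    set_id: str = "set",
) -> CorrelationReport:
    """Pearson correlation of per-gene densities between two marks.

    t = r * sqrt((n - 2) / (1 - r^2)); the two-sided p-value comes from the
    t distribution with n - 2 degrees of freedom.  Densities (not raw
    sums) are used to remove gene-length confounding.
    """
    genes = sorted(set(gene_set))
    if len(genes) < 3:
        raise InputError("density_correlation: need at least 3 genes")
    x = density_series(signals, mark_a, genes).to_numpy()
    y = density_series(signals, mark_b, genes).to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ComputationError(
            "density_correlation: zero variance in a density vector (r undefined)"
        )
    r, p = stats.pearsonr(x, y)
    n = len(genes)
    denom = 1.0 - r * r
    t = np.inf * np.sign(r) if denom == 0 else r * np.sqrt((n - 2) / denom)
    return CorrelationReport(
        mark_a=mark_a,
        mark_b=mark_b,
        set_id=set_id,
        n=n,
        pearson_r=float(r),
        t_statistic=float(t),
        p_value=float(p),
    )


def correlation_attribution(
    signals: pd.DataFrame,
    mark_a: str,
    mark_b: str,
    universe: Iterable[str],
    subset: Iterable[str],
) -> tuple[CorrelationReport, CorrelationReport]:
    """Correlation over the universe and over universe minus subset.

    A drop (r_full > r_without) indicates the subset contributes to the
    cross-mark correlation.
    """
    universe = frozenset(universe)
    subset = frozenset(subset)
    if not subset <= universe:
        raise InputError("correlation_attribution: subset must lie inside the universe")
    remaining = universe - subset
    if len(remaining) < 3:
        raise InputError("correlation_attribution: fewer than 3 genes left after removal")
    full = density_correlation(signals, mark_a, mark_b, sorted(universe), set_id="universe")
    without = density_correlation(
        signals, mark_a, mark_b, sorted(remaining), set_id="universe_minus_subset"
    )
    return full, without


def dual_enriched_sets(
    results_a: Iterable[EnrichmentResult],
    results_b: Iterable[EnrichmentResult],
) -> list[str]:
    """Set ids called enriched for both marks."""
    a = {r.set_id: r for r in results_a}
    b = {r.set_id: r for r in results_b}
    if set(a) != set(b):
        raise InputError("dual_enriched_sets: results cover different set universes")
    return sorted(
        sid
        for sid in a
        if a[sid].direction == "enriched" and b[sid].direction == "enriched"
    )
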