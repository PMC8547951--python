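"""Per (gene-set, mark) enrichment and depletion calls.

The effect size is a density fold change (set density over background
density); significance comes from Fisher's exact test on marked-gene
counts (set vs rest of universe) with Benjamini-Hochberg FDR control over
the whole set x mark family.  A set is called enriched when
FC >= fc_threshold and q <= q_threshold, depleted when FC <= 1/fc_threshold
and q <= q_threshold, otherwise none.

A gene is "marked" for a modification when its per-gene density is at or
above a configurable quantile of the density distribution over the
reference universe (default 0.75).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GenomeAnnotation, MetabolicAnnotation
from .errors import ComputationError, InputError
from .signal_density import SetDensity, set_density

logger = logging.getLogger(__name__)

DEFAULT_MARK_QUANTILE = 0.75
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_Q_THRESHOLD = 0.01


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment call for one (gene set, mark) pair."""

    set_id: str
    mark_name: str
    density: float
    background_density: float
    p_value: float
    q_value: float
    direction: str  # enriched | depleted | none
    marked_in_set: int
    unmarked_in_set: int
    marked_out: int
    unmarked_out: int
    n_genes: int

    @property
    def fold_change(self) -> float:
        return self.density / self.background_density

    @property
    def log2fc(self) -> float:
        return math.log2(self.fold_change)


def mark_gene(
    signals: pd.DataFrame,
    mark: str,
    quantile: float = DEFAULT_MARK_QUANTILE,
    universe: Iterable[str] | None = None,
) -> frozenset[str]:
    """Gene ids whose density for ``mark`` reaches the universe quantile.

    The threshold is the empirical quantile (linear interpolation) of the
    per-gene densities over the universe; genes at or above it are marked.
    """
    sub = signals[signals["mark"] == mark]
    if universe is not None:
        universe = set(universe)
        sub = sub[sub["gene_id"].isin(universe)]
    if sub.empty:
        raise InputError(f"mark_gene: empty universe for mark {mark!r}")
    threshold = float(np.quantile(sub["density"].to_numpy(), quantile))
    return frozenset(sub.loc[sub["density"] >= threshold, "gene_id"])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed one (relative
    tie tolerance 1e-7).  Any zero margin is a degenerate table with p = 1.
    """
    for name, x in zip("abcd", (a, b, c, d)):
        if x < 0 or int(x) != x:
            raise InputError(f"fisher_exact_2x2: {name} must be a nonnegative integer")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a + b, c + d, a + c, b + d) == 0:
        logger.debug("fisher_exact_2x2: zero margin in (%d,%d,%d,%d); p=1", a, b, c, d)
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order.

    q_(i) = min_{j>=i}(p_(j) * m / j), capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("bh_fdr: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_enrichment(
    signals: pd.DataFrame,
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    marks: Sequence[str] | None = None,
    quantile: float = DEFAULT_MARK_QUANTILE,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    use_raw_p: bool = False,
    alpha: float = 0.05,
    per_mark_fdr: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment/depletion calls for every set x mark pair.

    The background density is the pooled density over ``universe``; the
    2x2 table counts marked genes inside and outside each set.  q-values
    are BH-adjusted jointly across the whole set x mark matrix unless
    ``per_mark_fdr``.  With ``use_raw_p`` the significance gate is
    p < alpha instead of q <= q_threshold (the q-values are still
    reported).
    """
    universe = frozenset(universe)
    if not universe:
        raise InputError("call_enrichment: empty universe")
    set_members = {sid: frozenset(m) for sid, m in sets.items()}
    for sid, members in set_members.items():
        if not members <= universe:
            stray = sorted(members - universe)
            raise InputError(f"set {sid!r} not a subset of the universe: {stray[:5]}")
    if marks is None:
        marks = sorted(signals["mark"].unique())

    rows = []  # (set_id, mark, density, background, p, a, b, c, d, n)
    for mark in marks:
        background = set_density(signals, universe, "background", mark)
        if background.density <= 0:
            raise ComputationError(f"background density is 0 for mark {mark!r}")
        marked = mark_gene(signals, mark, quantile=quantile, universe=universe)
        for sid in sorted(set_members):
            members = set_members[sid]
            sd = set_density(signals, members, sid, mark)
            a = len(members & marked)
            b = len(members) - a
            c = len(marked - members)
            d = len(universe) - len(members) - c
            p = fisher_exact_2x2(a, b, c, d)
            rows.append(
                (sid, mark, sd.density, background.density, p, a, b, c, d, sd.n_genes)
            )

    if per_mark_fdr:
        q_all = np.empty(len(rows))
        for mark in marks:
            idx = [i for i, r in enumerate(rows) if r[1] == mark]
            q_all[idx] = bh_fdr([rows[i][4] for i in idx])
    else:
        q_all = bh_fdr([r[4] for r in rows])

    results = []
    for (sid, mark, dens, bg, p, a, b, c, d, n), q in zip(rows, q_all):
        fc = dens / bg
        significant = (p < alpha) if use_raw_p else (q <= q_threshold)
        if significant and fc >= fc_threshold:
            direction = "enriched"
        elif significant and fc > 0 and fc <= 1.0 / fc_threshold:
            direction = "depleted"
        else:
            direction = "none"
        results.append(
            EnrichmentResult(
                set_id=sid,
                mark_name=mark,
                density=dens,
                background_density=bg,
                p_value=p,
                q_value=float(q),
                direction=direction,
                marked_in_set=a,
                unmarked_in_set=b,
                marked_out=c,
                unmarked_out=d,
                n_genes=n,
            )
        )
    return results


def enrichment_matrix(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Sets x marks matrix of log2 fold changes; NA where direction is none."""
    results = list(results)
    sets = sorted({r.set_id for r in results})
    marks = sorted({r.mark_name for r in results})
    mat = pd.DataFrame(np.nan, index=sets, columns=marks)
    mat.index.name = "set_id"
    for r in results:
        if r.direction != "none":
            mat.loc[r.set_id, r.mark_name] = r.log2fc
    return mat


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Long-format results table (one row per set x mark)."""
    rows = [
        {
            "set_id": r.set_id,
            "mark": r.mark_name,
            "n_genes": r.n_genes,
            "density": r.density,
            "background_density": r.background_density,
            "fold_change": r.fold_change,
            "log2fc": r.log2fc,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "direction": r.direction,
            "marked_in_set": r.marked_in_set,
            "unmarked_in_set": r.unmarked_in_set,
            "marked_out": r.marked_out,
            "unmarked_out": r.unmarked_out,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def filter_pathways(
    annotation: MetabolicAnnotation,
    min_genes: int = 10,
    domain: str | None = "specialized",
) -> dict[str, frozenset[str]]:
    """Pathway gene sets of a domain with at least ``min_genes`` members.

    ``domain=None`` disables the domain filter.  The membership bound is
    inclusive: a pathway with exactly ``min_genes`` genes qualifies.
    """
    if domain is not None and domain not in annotation.domains:
        raise InputError(f"unknown domain {domain!r}; known: {annotation.domains}")
    out = {}
    for pid in annotation.pathway_ids:
        if domain is not None and domain not in annotation.pathway_to_domains[pid]:
            continue
        genes = annotation.genes_in_pathway(pid)
        if len(genes) >= min_genes:
            out[pid] = genes
    return out


def domain_sets(annotation: MetabolicAnnotation) -> dict[str, frozenset[str]]:
    """Domain-level gene sets, restricted to unique-domain genes."""
    return {
        d: annotation.genes_in_domain(d, unique_only=True) for d in annotation.domains
    }
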