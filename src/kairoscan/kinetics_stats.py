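"""Expression-kinetics and metabolite statistics.

Fold changes of target-gene expression are computed with the comparative
Cq method: per replicate, dCq = Cq_target - Cq_reference; the fold change
between treated and mock samples at one time point is 2^-(mean dCq_treated
- mean dCq_mock), with a pooled-variance t-test on the replicate dCq
values.  Earliest-induction calls scan an ordered time grid for the first
time point that is both significant and above a minimal fold change.

The three-way factorial ANOVA (genotype x treatment x duration) is fitted
by least squares on a balanced design with sequential (Type I) sums of
squares; in a balanced design these coincide with every other
sums-of-squares type, which is why unbalanced input is refused rather than
silently re-interpreted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .core_io import ConcentrationTable, CqTable
from .errors import ComputationError, InputError

logger = logging.getLogger(__name__)

ANOVA_TERMS = ["G", "T", "D", "GxT", "GxD", "TxD", "GxTxD", "residual"]
_TERM_MAP = {
    "C(genotype)": "G",
    "C(treatment)": "T",
    "C(time)": "D",
    "C(genotype):C(treatment)": "GxT",
    "C(genotype):C(time)": "GxD",
    "C(treatment):C(time)": "TxD",
    "C(genotype):C(treatment):C(time)": "GxTxD",
    "Residual": "residual",
}


@dataclass(frozen=True)
class ExpressionFC:
    """Treated-vs-mock induction of one target at one (genotype, time)."""

    target: str
    genotype: str
    time: int
    fold_change: float
    p_value: float
    n: int


@dataclass(frozen=True)
class InductionCall:
    target: str
    genotype: str
    earliest_time: int | None
    alpha: float
    min_fc: float


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    sx, sy = np.var(x, ddof=1), np.var(y, ddof=1)
    if sx == 0 and sy == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def ddcq_fold_change(
    cq_table: CqTable,
    target: str,
    reference_gene: str,
    genotype: str,
    time: int,
) -> ExpressionFC:
    """ddCq fold change of ``target`` vs its untreated control at one time.

    Requires expression records for both the target and the reference gene
    under both treatments with matching replicate ids; fold changes are
    immune to any constant Cq offset (plate effects).
    """

    def _dcq(treatment: str) -> np.ndarray:
        tgt = cq_table.select(
            assay="expression",
            target_gene=target,
            genotype=genotype,
            time=time,
            treatment=treatment,
        )
        ref = cq_table.select(
            assay="expression",
            target_gene=reference_gene,
            genotype=genotype,
            time=time,
            treatment=treatment,
        )
        if ref.empty:
            raise InputError(
                f"no reference records for {reference_gene!r} "
                f"({genotype}, t={time}, {treatment})"
            )
        if tgt.empty:
            raise InputError(
                f"no target records for {target!r} ({genotype}, t={time}, {treatment})"
            )
        merged = tgt.merge(
            ref[["replicate", "cq"]], on="replicate", suffixes=("", "_ref")
        )
        if len(merged) < 2:
            raise InputError(
                f"need >= 2 paired replicates for {target!r} "
                f"({genotype}, t={time}, {treatment})"
            )
        return (merged["cq"] - merged["cq_ref"]).to_numpy()

    dcq_treated = _dcq("treated")
    dcq_mock = _dcq("mock")
    ddcq = float(np.mean(dcq_treated) - np.mean(dcq_mock))
    _, p = _pooled_t(dcq_treated, dcq_mock)
    return ExpressionFC(
        target=target,
        genotype=genotype,
        time=time,
        fold_change=2.0 ** (-ddcq),
        p_value=p,
        n=min(len(dcq_treated), len(dcq_mock)),
    )


def expression_kinetics(
    cq_table: CqTable,
    reference_gene: str,
    targets: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fold-change table over every (target, genotype, time) in the Cq data."""
    expr = cq_table.select(assay="expression")
    if targets is None:
        targets = sorted(set(expr["target_gene"]) - {reference_gene})
    rows = []
    for target in targets:
        sub = expr[expr["target_gene"] == target]
        for genotype in sorted(sub["genotype"].unique()):
            for time in sorted(sub.loc[sub["genotype"] == genotype, "time"].unique()):
                fc = ddcq_fold_change(cq_table, target, reference_gene, genotype, int(time))
                rows.append(
                    {
                        "target": fc.target,
                        "genotype": fc.genotype,
                        "time": fc.time,
                        "fold_change": fc.fold_change,
                        "p_value": fc.p_value,
                        "n": fc.n,
                    }
                )
    return pd.DataFrame(rows)


def earliest_induction(
    expression_fcs: Iterable[ExpressionFC],
    alpha: float = 0.05,
    min_fc: float = 1.0,
) -> InductionCall:
    """Earliest time with p <= alpha and fold_change > min_fc, else None.

    The input series must belong to a single (target, genotype); times are
    scanned in increasing order.  Monotone in alpha: relaxing alpha never
    yields a later call.
    """
    fcs = sorted(expression_fcs, key=lambda f: f.time)
    if not fcs:
        raise InputError("earliest_induction: empty fold-change series")
    keys = {(f.target, f.genotype) for f in fcs}
    if len(keys) > 1:
        raise InputError(f"earliest_induction: mixed series {sorted(keys)}")
    target, genotype = next(iter(keys))
    earliest = None
    for f in fcs:
        if f.p_value <= alpha and f.fold_change > min_fc:
            earliest = f.time
            break
    return InductionCall(
        target=target,
        genotype=genotype,
        earliest_time=earliest,
        alpha=alpha,
        min_fc=min_fc,
    )


def expression_response_table(
    cq_table: CqTable,
    target: str,
    reference_gene: str,
    scale: str = "linear",
) -> pd.DataFrame:
    """Per-replicate responses of one target for the three-way ANOVA.

    ``scale="linear"`` returns relative expression 2^-dCq (the default
    reading of per-replicate raw transcript abundance); ``scale="dcq"``
    returns the reference-normalized Cq difference itself.
    """
    if scale not in ("linear", "dcq"):
        raise InputError(f"unknown response scale {scale!r}")
    tgt = cq_table.select(assay="expression", target_gene=target)
    ref = cq_table.select(assay="expression", target_gene=reference_gene)
    if tgt.empty or ref.empty:
        raise InputError(
            f"expression records missing for {target!r} or {reference_gene!r}"
        )
    merged = tgt.merge(
        ref[["genotype", "treatment", "time", "replicate", "cq"]],
        on=["genotype", "treatment", "time", "replicate"],
        suffixes=("", "_ref"),
    )
    dcq = (merged["cq"] - merged["cq_ref"]).to_numpy()
    response = dcq if scale == "dcq" else np.power(2.0, -dcq)
    return pd.DataFrame(
        {
            "genotype": merged["genotype"],
            "treatment": merged["treatment"],
            "time": merged["time"],
            "response": response,
        }
    )


def _check_balanced(df: pd.DataFrame) -> None:
    counts = df.groupby(["genotype", "treatment", "time"], sort=True).size()
    n_cells = (
        df["genotype"].nunique() * df["treatment"].nunique() * df["time"].nunique()
    )
    if len(counts) != n_cells or counts.nunique() != 1:
        raise InputError(
            "anova3: design is not balanced/fully crossed — every "
            "(genotype, treatment, time) cell needs the same replicate count; "
            "balance or subsample the data first"
        )
    if counts.iloc[0] < 2:
        raise InputError("anova3: need >= 2 replicates per cell")


def anova3(observations: pd.DataFrame, response: str = "response") -> pd.DataFrame:
    """Three-way fixed-effects factorial ANOVA on a balanced design.

    ``observations`` has columns genotype, treatment, time and the
    response.  Returns a table indexed by term (G, T, D, GxT, GxD, TxD,
    GxTxD, residual) with df, sum_sq, mean_sq, F and p.  Sums of squares
    are sequential (Type I) in that term order; in a balanced design they
    are orthogonal, hence order-invariant.  A constant response yields
    zero sums of squares and NA F statistics.
    """
    required = {"genotype", "treatment", "time", response}
    missing = required - set(observations.columns)
    if missing:
        raise InputError(f"anova3: missing columns {sorted(missing)}")
    df = observations.copy()
    _check_balanced(df)
    df = df.rename(columns={response: "_resp"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        model = ols("_resp ~ C(genotype) * C(treatment) * C(time)", data=df).fit()
        table = anova_lm(model, typ=1)
    table = table.rename(index=_TERM_MAP)
    table = table.loc[ANOVA_TERMS]
    out = pd.DataFrame(
        {
            "df": table["df"].astype(float),
            "sum_sq": table["sum_sq"].astype(float),
            "mean_sq": table["sum_sq"] / table["df"],
            "F": table["F"].astype(float),
            "p": table["PR(>F)"].astype(float),
        }
    )
    out.index.name = "term"
    # numerical dust from a perfectly fit model can make F meaningless
    if out.loc["residual", "sum_sq"] < 0:
        raise ComputationError("anova3: negative residual sum of squares")
    resp = df["_resp"].to_numpy(dtype=float)
    degenerate_resp = np.var(resp) <= 1e-14 * max(1.0, float(np.mean(resp)) ** 2)
    if out.loc["residual", "mean_sq"] == 0 or degenerate_resp:
        # constant response or saturated fit: F ratios are 0/0 and undefined
        out.loc[out.index != "residual", ["F", "p"]] = np.nan
    return out


def metabolite_stats(
    conc_table: ConcentrationTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(genotype, time) treated-vs-mock t-tests plus the three-way ANOVA.

    Returns (per_time, anova).  ``per_time`` has one row per (genotype,
    time) with the mean treated/mock concentration ratio and a pooled
    two-tailed t-test p-value; ``anova`` is :func:`anova3` on the raw
    concentrations.
    """
    df = conc_table.df
    rows = []
    for (genotype, time), sub in df.groupby(["genotype", "time"], sort=True):
        treated = sub.loc[sub["treatment"] == "treated", "concentration"].to_numpy()
        mock = sub.loc[sub["treatment"] == "mock", "concentration"].to_numpy()
        if len(treated) < 2 or len(mock) < 2:
            raise InputError(
                f"metabolite_stats: need >= 2 replicates per group at "
                f"({genotype}, t={time})"
            )
        t, p = _pooled_t(treated, mock)
        mock_mean = float(np.mean(mock))
        ratio = float(np.mean(treated)) / mock_mean if mock_mean > 0 else np.nan
        rows.append(
            {
                "genotype": genotype,
                "time": int(time),
                "ratio": ratio,
                "t": t,
                "p_value": p,
                "n_treated": len(treated),
                "n_mock": len(mock),
            }
        )
    per_time = pd.DataFrame(rows)
    anova = anova3(df.rename(columns={"concentration": "response"}))
    return per_time, anova


def accumulation_onset(
    per_time: pd.DataFrame, genotype: str, alpha: float = 0.05
) -> int | None:
    """Earliest time with p <= alpha and treated/mock ratio > 1.

    The metabolite analogue of :func:`earliest_induction`, applied to the
    per-time table of :func:`metabolite_stats`.
    """
    sub = per_time[per_time["genotype"] == genotype].sort_values("time")
    if sub.empty:
        raise InputError(f"accumulation_onset: no rows for genotype {genotype!r}")
    hits = sub[(sub["p_value"] <= alpha) & (sub["ratio"] > 1.0)]
    return int(hits["time"].iloc[0]) if len(hits) else None
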