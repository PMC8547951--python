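"""ddCq fold changes, induction calls and the three-way factorial ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

import kairoscan as ks
from kairoscan.core_io import CqTable
from kairoscan.errors import InputError
from kairoscan.kinetics_stats import (
    ExpressionFC,
    accumulation_onset,
    earliest_induction,
    expression_response_table,
)
from conftest import minimal_assay_kwargs


def _cq_records(ddcq=0.0, base=24.0, ref=18.0, reps=3, offset=0.0):
    """Treated/mock expression records with an exact planted ddCq."""
    rows = []
    for treatment in ("treated", "mock"):
        shift = ddcq if treatment == "treated" else 0.0
        for r in range(1, reps + 1):
            rows.append(
                dict(target_gene="TGT", sample="s", genotype="Col-0",
                     treatment=treatment, time=30, replicate=r,
                     assay="expression", antibody="", cq=base + shift + offset)
            )
            rows.append(
                dict(target_gene="ACT2", sample="s", genotype="Col-0",
                     treatment=treatment, time=30, replicate=r,
                     assay="expression", antibody="", cq=ref + offset)
            )
    return CqTable.from_records(rows)


# --- ddCq ------------------------------------------------------------------


def test_ddcq_zero_gives_unit_fold_change():
    fc = ks.ddcq_fold_change(_cq_records(ddcq=0.0), "TGT", "ACT2", "Col-0", 30)
    assert fc.fold_change == pytest.approx(1.0)


def test_ddcq_minus_two_gives_fourfold():
    fc = ks.ddcq_fold_change(_cq_records(ddcq=-2.0), "TGT", "ACT2", "Col-0", 30)
    assert fc.fold_change == pytest.approx(4.0)


def test_ddcq_plate_offset_immunity():
    a = ks.ddcq_fold_change(_cq_records(ddcq=-1.3), "TGT", "ACT2", "Col-0", 30)
    b = ks.ddcq_fold_change(
        _cq_records(ddcq=-1.3, offset=2.71), "TGT", "ACT2", "Col-0", 30
    )
    assert a.fold_change == pytest.approx(b.fold_change, rel=1e-12)


def test_ddcq_missing_reference_is_error():
    rows = _cq_records().df
    rows = rows[rows["target_gene"] != "ACT2"]
    with pytest.raises(InputError, match="reference"):
        ks.ddcq_fold_change(CqTable(rows), "TGT", "ACT2", "Col-0", 30)


def test_zero_noise_recovery_matches_truth_exactly():
    cfg = ks.SimConfig(
        seed=11, cq_noise_sd=0.0,
        **{**minimal_assay_kwargs(),
           "expression_fc": {("TGT", "Col-0", 30): 6.5, ("TGT", "Col-0", 180): 0.5}},
    )
    ds_cq = ks.simulate_cq(cfg)
    for time in (30, 180):
        fc = ks.ddcq_fold_change(ds_cq, "TGT", "ACT2", "Col-0", time)
        assert fc.fold_change == pytest.approx(
            cfg.expression_fc[("TGT", "Col-0", time)], abs=1e-9
        )


# --- earliest induction ----------------------------------------------------


def _series(ps, fcs, times=(5, 30, 60, 180, 360)):
    return [
        ExpressionFC("TGT", "Col-0", t, fc, p, 6)
        for t, p, fc in zip(times, ps, fcs)
    ]


def test_earliest_induction_picks_first_qualifying_time():
    s = _series([0.5, 0.2, 0.3, 0.01, 0.01], [1.0, 1.2, 1.3, 3.0, 5.0])
    assert earliest_induction(s).earliest_time == 180


def test_earliest_induction_none_when_nothing_qualifies():
    s = _series([0.5, 0.2, 0.3, 0.2, 0.6], [1.0, 1.2, 1.3, 3.0, 5.0])
    assert earliest_induction(s).earliest_time is None


def test_earliest_induction_requires_fold_change_gate():
    s = _series([0.01, 0.01, 0.5, 0.5, 0.5], [0.5, 3.0, 1.0, 1.0, 1.0])
    # t=5 is significant but repressed; first induction is t=30
    assert earliest_induction(s).earliest_time == 30


def test_earliest_induction_monotone_in_alpha(rng):
    for _ in range(50):
        s = _series(rng.uniform(0, 1, 5), rng.uniform(0.5, 4.0, 5))
        loose = earliest_induction(s, alpha=0.2).earliest_time
        strict = earliest_induction(s, alpha=0.05).earliest_time
        if strict is not None:
            assert loose is not None and loose <= strict


def test_earliest_induction_recovers_planted_onset():
    """Induction planted from t=30 (FC 4), Cq noise 0.1, n=6: called at 30
    in >= 90% of 200 generator seeds."""
    times = (5, 30, 60, 180, 360)
    ok = 0
    for seed in range(200):
        cfg = ks.SimConfig(
            seed=seed, cq_noise_sd=0.1, replicates=6,
            **{**minimal_assay_kwargs(),
               "expression_fc": {("TGT", "Col-0", t): (4.0 if t >= 30 else 1.0)
                                 for t in times}},
        )
        cq = ks.simulate_cq(cfg)
        series = [ks.ddcq_fold_change(cq, "TGT", "ACT2", "Col-0", t) for t in times]
        ok += earliest_induction(series).earliest_time == 30
    assert ok >= 0.90 * 200


# --- three-way ANOVA -------------------------------------------------------


def _design(rng=None, effect=None, reps=3):
    rows = []
    for g, t, d in itertools.product(("wt", "mut"), ("treated", "mock"), (5, 30, 60)):
        for r in range(reps):
            if effect == "treatment":
                y = 3.0 if t == "treated" else 1.0
            elif effect == "constant":
                y = 2.0
            else:
                y = float(rng.normal())
            rows.append({"genotype": g, "treatment": t, "time": d, "response": y})
    return pd.DataFrame(rows)


def test_anova_pure_treatment_effect_isolates_one_term():
    table = ks.anova3(_design(effect="treatment"))
    assert table.loc["T", "sum_sq"] > 0
    for term in ("G", "D", "GxT", "GxD", "TxD", "GxTxD"):
        assert table.loc[term, "sum_sq"] == pytest.approx(0.0, abs=1e-18)


def test_anova_constant_response_reports_na():
    table = ks.anova3(_design(effect="constant"))
    assert np.allclose(table["sum_sq"], 0.0, atol=1e-18)
    assert np.isnan(table.loc["G", "F"])


def test_anova_df_partition(rng):
    table = ks.anova3(_design(rng))
    assert table["df"].sum() == 36 - 1


def test_anova_unbalanced_is_refused(rng):
    df = _design(rng)
    with pytest.raises(InputError, match="balanced"):
        ks.anova3(df.iloc[:-1])


def test_anova_order_invariance_via_factor_relabeling(rng):
    """In a balanced design Type I sums of squares are orthogonal: swapping
    the roles of two factors swaps their rows without changing any value."""
    df = _design(rng)
    swapped = df.rename(columns={"genotype": "treatment", "treatment": "genotype"})
    a = ks.anova3(df)
    b = ks.anova3(swapped)
    assert a.loc["G", "sum_sq"] == pytest.approx(b.loc["T", "sum_sq"])
    assert a.loc["T", "sum_sq"] == pytest.approx(b.loc["G", "sum_sq"])
    assert a.loc["GxD", "sum_sq"] == pytest.approx(b.loc["TxD", "sum_sq"])
    assert a.loc["GxTxD", "sum_sq"] == pytest.approx(b.loc["GxTxD", "sum_sq"])
    assert a.loc["residual", "sum_sq"] == pytest.approx(b.loc["residual", "sum_sq"])


def test_expression_response_table_feeds_anova():
    cfg = ks.SimConfig(
        seed=5, cq_noise_sd=0.1,
        **{**minimal_assay_kwargs(),
           "expression_fc": {("TGT", g, t): 2.0
                             for g in ("Col-0", "clf28")
                             for t in (5, 30)}},
    )
    cq = ks.simulate_cq(cfg)
    obs = expression_response_table(cq, "TGT", "ACT2")
    table = ks.anova3(obs)
    assert table.loc["T", "p"] < 1e-6  # planted treatment effect dominates


# --- metabolite stats ------------------------------------------------------


def test_metabolite_identical_groups_give_p_one():
    rows = []
    for (g, t), conc in {("Col-0", 5): 10.0, ("Col-0", 30): 12.0}.items():
        for treatment in ("treated", "mock"):
            for r in range(1, 4):
                rows.append({"genotype": g, "treatment": treatment, "time": t,
                             "replicate": r, "concentration": conc + r})
    per_time, anova = ks.metabolite_stats(ks.ConcentrationTable(pd.DataFrame(rows)))
    assert np.allclose(per_time["p_value"], 1.0)
    assert anova.loc["T", "sum_sq"] == pytest.approx(0.0, abs=1e-18)


def test_metabolite_accumulation_onset_recovered():
    """3x accumulation planted from t=180: the onset call lands at 180 and
    never earlier in >= 90% of 200 generator seeds."""
    times = (5, 30, 60, 180, 360)
    ok = 0
    for seed in range(200):
        cfg = ks.SimConfig(
            seed=seed,
            **{**minimal_assay_kwargs(),
               "conc_fc": {("Col-0", t): (3.0 if t >= 180 else 1.0) for t in times}},
        )
        conc = ks.simulate_concentrations(cfg)
        per_time, _ = ks.metabolite_stats(conc)
        ok += accumulation_onset(per_time, "Col-0") == 180
    assert ok >= 0.90 * 200
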