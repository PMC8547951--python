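"""Marked-gene calls, Fisher exact test, BH FDR and enrichment calls."""

import math

import numpy as np
import pandas as pd
import pytest

import kairoscan as ks
from kairoscan.core_io import MetabolicAnnotation
from kairoscan.enrichment import results_frame
from kairoscan.errors import ComputationError, InputError


def _signals(densities, mark="M"):
    rows = [
        {
            "gene_id": g,
            "mark": mark,
            "signal_sum": d,
            "window_len": 1,
            "density": d,
        }
        for g, d in densities.items()
    ]
    return pd.DataFrame(rows)


# --- mark_gene -------------------------------------------------------------


def test_mark_gene_uses_linear_interpolated_quantile():
    sig = _signals({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
    # 0.75 empirical quantile of [1,2,3,4] is 3.25 -> only the gene at 4
    assert ks.mark_gene(sig, "M", quantile=0.75) == {"d"}


def test_mark_gene_quantile_zero_marks_everything():
    sig = _signals({"a": 1.0, "b": 2.0})
    assert ks.mark_gene(sig, "M", quantile=0.0) == {"a", "b"}


def test_mark_gene_degenerate_ties_all_marked():
    sig = _signals({g: 2.5 for g in "abcd"})
    assert ks.mark_gene(sig, "M", quantile=0.75) == set("abcd")


def test_mark_gene_empty_universe_is_error():
    sig = _signals({"a": 1.0})
    with pytest.raises(InputError):
        ks.mark_gene(sig, "M", universe=["zzz"])


# --- Fisher exact ----------------------------------------------------------


def test_fisher_balanced_table_is_one():
    assert ks.fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)


def test_fisher_extreme_table_enumeration_value():
    # margins (10,10,10,10): only the two extreme tables qualify;
    # p = 2 / C(20,10)
    expected = 2.0 / math.comb(20, 10)
    assert ks.fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(expected, rel=1e-9)


def test_fisher_small_table_matches_enumeration():
    # margins (3,3,3,3): tables a=0..3 with probs C(3,a)C(3,3-a)/C(6,3)
    denom = math.comb(6, 3)
    probs = [math.comb(3, a) * math.comb(3, 3 - a) / denom for a in range(4)]
    p_obs = probs[2]  # observed table (2,1,1,2)
    expected = sum(p for p in probs if p <= p_obs * (1 + 1e-7))
    assert ks.fisher_exact_2x2(2, 1, 1, 2) == pytest.approx(expected, rel=1e-9)


def test_fisher_zero_margin_degenerates_to_one():
    assert ks.fisher_exact_2x2(0, 0, 3, 5) == 1.0
    assert ks.fisher_exact_2x2(2, 0, 3, 0) == 1.0


def test_fisher_transpose_symmetry(rng):
    for _ in range(25):
        a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
        p = ks.fisher_exact_2x2(a, b, c, d)
        assert ks.fisher_exact_2x2(c, d, a, b) == pytest.approx(p, rel=1e-12)
        assert ks.fisher_exact_2x2(a, c, b, d) == pytest.approx(p, rel=1e-12)


def test_fisher_rejects_negative_or_fractional():
    with pytest.raises(InputError):
        ks.fisher_exact_2x2(-1, 2, 3, 4)
    with pytest.raises(InputError):
        ks.fisher_exact_2x2(1.5, 2, 3, 4)


# --- BH FDR ----------------------------------------------------------------


def test_bh_step_up_closed_form_example():
    q = ks.bh_fdr([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


def test_bh_single_value_identity():
    np.testing.assert_allclose(ks.bh_fdr([0.3]), [0.3])


def test_bh_properties(rng):
    p = rng.uniform(size=40)
    q = ks.bh_fdr(p)
    assert np.all(q >= p - 1e-15)
    assert np.all(q <= 1.0)
    # monotone on sorted input
    qs = ks.bh_fdr(np.sort(p))
    assert np.all(np.diff(qs) >= -1e-15)
    # permutation equivariance
    perm = rng.permutation(len(p))
    np.testing.assert_allclose(ks.bh_fdr(p[perm]), q[perm])


def test_bh_rejects_out_of_range():
    with pytest.raises(InputError):
        ks.bh_fdr([0.5, 1.2])


# --- call_enrichment -------------------------------------------------------


def _two_group_signals(marks=("M",)):
    # 10 high-density genes (the candidate set) among 40
    entries = {}
    for i in range(30):
        entries[f"lo{i}"] = 1.0
    for i in range(10):
        entries[f"hi{i}"] = 4.0
    frames = [_signals(entries, mark=m) for m in marks]
    return pd.concat(frames, ignore_index=True)


def test_call_enrichment_fold_change_boundary_is_inclusive():
    sig = _two_group_signals()
    universe = set(sig["gene_id"])
    sets = {"S": frozenset(f"hi{i}" for i in range(10))}
    [res] = ks.call_enrichment(sig, sets, universe, fc_threshold=1.5)
    assert res.direction == "enriched"
    # exactly at the threshold still qualifies ("at least")
    [res_at] = ks.call_enrichment(sig, sets, universe, fc_threshold=res.fold_change)
    assert res_at.direction == "enriched"
    [res_above] = ks.call_enrichment(
        sig, sets, universe, fc_threshold=res.fold_change * (1 + 1e-9)
    )
    assert res_above.direction == "none"


def test_call_enrichment_depletion_is_symmetric():
    sig = _two_group_signals()
    universe = set(sig["gene_id"])
    sets = {"LOW": frozenset(f"lo{i}" for i in range(10))}
    [res] = ks.call_enrichment(sig, sets, universe, fc_threshold=1.2)
    assert res.fold_change < 1
    if res.q_value <= 0.01 and res.fold_change <= 1 / 1.2:
        assert res.direction == "depleted"


def test_call_enrichment_counts_partition_universe():
    sig = _two_group_signals()
    universe = set(sig["gene_id"])
    sets = {"S": frozenset(f"hi{i}" for i in range(10))}
    [res] = ks.call_enrichment(sig, sets, universe)
    assert res.marked_in_set + res.unmarked_in_set == res.n_genes == 10
    total = (
        res.marked_in_set + res.unmarked_in_set + res.marked_out + res.unmarked_out
    )
    assert total == len(universe)


def test_call_enrichment_set_outside_universe_is_error():
    sig = _two_group_signals()
    universe = set(sig["gene_id"]) - {"hi0"}
    with pytest.raises(InputError, match="subset"):
        ks.call_enrichment(sig, {"S": {"hi0"}}, universe)


def test_call_enrichment_zero_background_is_error():
    sig = _signals({"a": 0.0, "b": 0.0, "c": 0.0})
    with pytest.raises(ComputationError):
        ks.call_enrichment(sig, {"S": {"a"}}, {"a", "b", "c"})


def test_raw_p_mode_reproduces_legend_rule():
    sig = _two_group_signals()
    universe = set(sig["gene_id"])
    sets = {"S": frozenset(f"hi{i}" for i in range(10))}
    [res] = ks.call_enrichment(sig, sets, universe, use_raw_p=True, alpha=0.05)
    assert res.p_value < 0.05 and res.direction == "enriched"


# --- matrix + results frame ------------------------------------------------


def test_enrichment_matrix_gray_cells_and_log2():
    sig = _two_group_signals(marks=("A", "B"))
    universe = set(sig["gene_id"])
    sets = {
        "S": frozenset(f"hi{i}" for i in range(10)),
        "NULLISH": frozenset(list(universe)[:10]),
    }
    results = ks.call_enrichment(sig, sets, universe)
    mat = ks.enrichment_matrix(results)
    for r in results:
        cell = mat.loc[r.set_id, r.mark_name]
        if r.direction == "none":
            assert np.isnan(cell)
        else:
            assert cell == pytest.approx(math.log2(r.fold_change))
    frame = results_frame(results)
    assert set(frame["set_id"]) == set(sets)


# --- pathway / domain filtering --------------------------------------------


def _annotation():
    rows = []
    for i in range(10):
        rows.append((f"g{i}", "P-BIG", "specialized"))
    for i in range(9):
        rows.append((f"h{i}", "P-SMALL", "specialized"))
    rows.append(("x0", "P-OTHER", "hormone"))
    for i in range(10):
        rows.append((f"y{i}", "P-HORM", "hormone"))
    return MetabolicAnnotation.from_records(rows)


def test_filter_pathways_boundary_inclusive():
    ann = _annotation()
    sets = ks.filter_pathways(ann, min_genes=10, domain="specialized")
    assert set(sets) == {"P-BIG"}  # 9-gene pathway excluded, 10-gene included


def test_filter_pathways_domain_off_considers_all():
    ann = _annotation()
    sets = ks.filter_pathways(ann, min_genes=10, domain=None)
    assert set(sets) == {"P-BIG", "P-HORM"}


def test_filter_pathways_unknown_domain_is_error():
    with pytest.raises(InputError):
        ks.filter_pathways(_annotation(), domain="nope")


def test_domain_level_ignores_multi_domain_genes():
    """Adding a multi-domain gene changes no domain-level enrichment result."""
    base_rows = [(f"g{i}", "P1", "specialized") for i in range(10)]
    base_rows += [(f"h{i}", "P2", "hormone") for i in range(10)]
    ann1 = MetabolicAnnotation.from_records(base_rows)
    ann2 = MetabolicAnnotation.from_records(
        base_rows + [("multi", "P1", "specialized"), ("multi", "P2", "hormone")]
    )
    densities = {f"g{i}": 3.0 + i * 0.01 for i in range(10)}
    densities.update({f"h{i}": 1.0 + i * 0.01 for i in range(10)})
    densities["multi"] = 99.0  # extreme value; must not matter
    sig = _signals(densities)
    out = []
    for ann in (ann1, ann2):
        sets = ks.domain_sets(ann)
        assert "multi" not in set().union(*sets.values())
        universe = frozenset().union(*sets.values())
        res = ks.call_enrichment(sig, sets, universe)
        out.append(results_frame(res).sort_values(["set_id", "mark"]).reset_index(drop=True))
    pd.testing.assert_frame_equal(out[0], out[1])
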