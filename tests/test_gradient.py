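"""Unit and property tests for the gradient SIP detection machinery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from sedsip.gradient import (
    FilterParams,
    WindowSpec,
    aggregate_group_calls,
    compare_groups_wilcoxon,
    detect_labelled_asvs,
    detect_substrate_responders,
    filter_taxa,
    normalize_relative_abundance,
    select_window,
    LabelSummary,
)
from sedsip.synth import SynthTaxon, simulate_microcosm_timeseries

from conftest import make_table


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "column, expected",
    [
        ([10, 30, 60], [0.1, 0.3, 0.6]),
        ([0, 0, 5], [0.0, 0.0, 1.0]),
        ([7, 11, 2], [0.35, 0.55, 0.10]),
    ],
)
def test_normalize_column_proportions(column, expected):
    table = make_table(np.array(column)[:, None], [{"sample_id": "s1"}])
    rel = normalize_relative_abundance(table)
    assert rel.mode == "relative"
    np.testing.assert_allclose(rel.data["s1"].to_numpy(), expected)


def test_normalize_rejects_all_zero_sample():
    table = make_table([[0, 1], [0, 2]], [{"sample_id": "empty"}, {"sample_id": "ok"}])
    with pytest.raises(ValueError, match="empty"):
        normalize_relative_abundance(table)


# ---------------------------------------------------------------------------
# window selection
# ---------------------------------------------------------------------------


def _density_table(densities, treatment="C13", timepoint=4):
    meta = [
        {"sample_id": f"f{i}", "treatment": treatment, "timepoint_days": timepoint,
         "density": d}
        for i, d in enumerate(densities)
    ]
    vals = np.full((1, len(densities)), 1.0 / 1)  # single ASV, relative mode
    t = make_table(vals, meta, mode="relative")
    return t


def test_select_window_membership_and_min_fraction_error():
    t = _density_table([1.720, 1.726, 1.731, 1.744])
    win2 = WindowSpec("w", 1.725, 1.741, min_fractions=2)
    sel = select_window(t, win2, "C13", 4)
    assert sel.sample_ids == ["f1", "f2"]
    win3 = WindowSpec("w", 1.725, 1.741, min_fractions=3)
    with pytest.raises(ValueError, match="2 fraction"):
        select_window(t, win3, "C13", 4)


def test_select_window_bounds_inclusive():
    t = _density_table([1.725, 1.741])
    win = WindowSpec("w", 1.725, 1.741, min_fractions=1, max_fractions=5)
    assert select_window(t, win, "C13", 4).n_samples == 2


def test_select_window_keeps_closest_to_midpoint():
    densities = [1.726, 1.728, 1.731, 1.733, 1.736, 1.740]
    t = _density_table(densities)
    win = WindowSpec("w", 1.725, 1.741, min_fractions=3, max_fractions=5)
    sel = select_window(t, win, "C13", 4)
    # midpoint 1.733; the farthest fraction (1.726) is dropped
    kept = sorted(float(sel.meta.loc[s, "density"]) for s in sel.sample_ids)
    assert kept == [1.728, 1.731, 1.733, 1.736, 1.740]


def test_select_window_missing_density_errors():
    t = _density_table([1.730, float("nan"), 1.735])
    win = WindowSpec("w", 1.725, 1.741, min_fractions=1)
    with pytest.raises(ValueError, match="density"):
        select_window(t, win, "C13", 4)


# ---------------------------------------------------------------------------
# taxon filters
# ---------------------------------------------------------------------------


def _two_group_tables(treat_vals, ctrl_vals):
    nt = np.asarray(treat_vals, dtype=float)
    nc = np.asarray(ctrl_vals, dtype=float)
    t = make_table(nt, [{"sample_id": f"t{i}"} for i in range(nt.shape[1])],
                   mode="relative")
    c = make_table(nc, [{"sample_id": f"c{i}", "treatment": "C12"}
                        for i in range(nc.shape[1])], mode="relative")
    return t, c


def test_filter_removes_uniformly_rare_asv():
    t, c = _two_group_tables([[0.0005] * 4], [[0.0005] * 4])
    assert filter_taxa(t, c, FilterParams()) == []


def test_filter_keeps_one_group_median_pass():
    t, c = _two_group_tables([[0.05] * 4], [[0.0] * 4])
    assert filter_taxa(t, c, FilterParams()) == ["asv1"]


def test_filter_prevalence_ceiling_rule():
    # 8 samples, prevalence 0.1 -> ceil(0.8) = 1 sample suffices, but the
    # median rule must also pass in one group
    treat = [[0.05, 0.05, 0.05, 0.0]]
    ctrl = [[0.0, 0.0, 0.0, 0.0]]
    t, c = _two_group_tables(treat, ctrl)
    assert filter_taxa(t, c, FilterParams()) == ["asv1"]
    # present above cutoff in 1 sample only: prevalence passes, median fails
    treat2 = [[0.05, 0.0, 0.0, 0.0]]
    t2, c2 = _two_group_tables(treat2, ctrl)
    assert filter_taxa(t2, c2, FilterParams()) == []


def test_filter_mismatched_asv_ids_error():
    t, _ = _two_group_tables([[0.1] * 4], [[0.1] * 4])
    _, c = _two_group_tables([[0.1] * 4], [[0.1] * 4])
    c.data.index = ["other"]
    with pytest.raises(ValueError, match="mismatched"):
        filter_taxa(t, c, FilterParams())


# ---------------------------------------------------------------------------
# rank test
# ---------------------------------------------------------------------------


def exact_two_sided_p(x, y):
    """Brute-force enumeration of the rank-sum null over all assignments."""
    pool = np.concatenate([x, y])
    ranks = rankdata(pool)
    n1 = len(x)
    mu = n1 * len(y) / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dist = []
    for idx in itertools.combinations(range(len(pool)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        dist.append(u)
    dist = np.array(dist)
    return float(np.mean(np.abs(dist - mu) >= abs(u_obs - mu) - 1e-12))


def test_wilcoxon_exact_examples():
    # perfect separation at 4 vs 4 (one tied pair inside the control group)
    res = compare_groups_wilcoxon([0.10, 0.12, 0.15, 0.11],
                                  [0.01, 0.02, 0.01, 0.03])
    assert res.u_statistic == 16
    assert res.p_value == pytest.approx(2 / 70, abs=1e-12)
    assert res.direction == "up" and res.significant
    # perfect separation at 5 vs 5
    res = compare_groups_wilcoxon([0.5, 0.6, 0.7, 0.8, 0.9],
                                  [0.0, 0.1, 0.2, 0.3, 0.4])
    assert res.p_value == pytest.approx(2 / 252, abs=1e-15)


def test_wilcoxon_identical_and_degenerate_inputs():
    res = compare_groups_wilcoxon([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
    assert res.p_value == 1.0 and not res.significant
    res = compare_groups_wilcoxon([0.2] * 3, [0.2] * 3)
    assert res.p_value == 1.0 and res.direction == "none"
    with pytest.raises(ValueError, match=">= 3"):
        compare_groups_wilcoxon([0.1, 0.2], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        compare_groups_wilcoxon([0.1, 0.2, 1.5], [0.1, 0.2, 0.3])


def test_wilcoxon_normal_flavour_reaches_significance_at_triplicates():
    # extreme 3 vs 3 configuration: z = 4.5/sqrt(5.25), two-sided p = 0.0495
    res = compare_groups_wilcoxon([0.10, 0.12, 0.15], [0.01, 0.02, 0.03],
                                  method="normal")
    assert res.p_value == pytest.approx(0.0495, abs=5e-5)
    assert res.significant
    # the exact flavour cannot reach 0.05 at 3 vs 3
    res_exact = compare_groups_wilcoxon([0.10, 0.12, 0.15], [0.01, 0.02, 0.03])
    assert res_exact.p_value == pytest.approx(0.1, abs=1e-12)
    assert not res_exact.significant


@pytest.mark.parametrize("n1,n2", [(3, 3), (3, 4), (4, 4), (3, 6), (4, 5),
                                   (5, 5), (3, 9), (4, 8), (5, 7), (6, 6)])
def test_wilcoxon_matches_enumeration_oracle(n1, n2):
    """Exact p equals brute-force enumeration for untied samples, n <= 12."""
    rng = np.random.default_rng(12345 + 100 * n1 + n2)
    for _ in range(20):
        pool = rng.permutation(np.linspace(0.01, 0.9, n1 + n2))
        x, y = pool[:n1], pool[n1:]
        res = compare_groups_wilcoxon(x, y)
        assert res.method_used == "exact"
        assert res.p_value == pytest.approx(exact_two_sided_p(x, y), abs=1e-12)


@given(st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8, unique=True),
       st.lists(st.floats(0.0, 1.0), min_size=3, max_size=8, unique=True))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_wilcoxon_symmetry_under_group_swap(x, y):
    a = compare_groups_wilcoxon(x, y)
    b = compare_groups_wilcoxon(y, x)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
    flip = {"up": "down", "down": "up", "none": "none"}
    assert b.direction == flip[a.direction]


def test_wilcoxon_paired_mode_requires_equal_n():
    with pytest.raises(ValueError, match="equal"):
        compare_groups_wilcoxon([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3],
                                paired=True)
    res = compare_groups_wilcoxon([0.3, 0.4, 0.5, 0.6], [0.1, 0.2, 0.3, 0.35],
                                  paired=True)
    assert res.method_used == "signed-rank"
    assert 0 < res.p_value <= 1


# ---------------------------------------------------------------------------
# detection workflows
# ---------------------------------------------------------------------------


def _labelled_toy_table(sig_days, all_days=(4, 10, 13, 24), seed=0):
    """One planted ASV clearly enriched on ``sig_days``, flat background."""
    rng = np.random.default_rng(seed)
    densities = [1.727, 1.731, 1.735, 1.739]
    meta, cols = [], []
    for tr in ("C13", "C12"):
        for tp in all_days:
            for d in densities:
                meta.append({"sample_id": f"{tr}_d{tp}_{d:.3f}",
                             "gradient_id": f"{tr}_d{tp}",
                             "treatment": tr, "timepoint_days": tp,
                             "density": d})
                enriched = tr == "C13" and tp in sig_days
                hot = rng.integers(1800, 2400) if enriched else rng.integers(5, 30)
                rest = 10000 - hot
                cols.append([hot, rest * 0.6, rest * 0.4])
    return make_table(np.array(cols).T, meta, asv_ids=["hot", "bg1", "bg2"])


def test_detect_labelled_at_three_of_four_timepoints():
    table = _labelled_toy_table(sig_days=(4, 10, 13))
    res = detect_labelled_asvs(table, windows=[WindowSpec("w1", 1.725, 1.741)])
    by_id = {s.asv_id: s for s in res.summaries}
    assert by_id["hot"].labelled
    assert by_id["hot"].timepoints_significant == 3
    assert by_id["hot"].timepoints_tested == 4
    assert not by_id["bg1"].labelled and not by_id["bg2"].labelled
    # audit trail covers every tested combination that passed filters
    assert any(c.asv_id == "hot" and c.significant for c in res.calls)


def test_detect_labelled_below_min_timepoints_not_called():
    table = _labelled_toy_table(sig_days=(4, 10))
    res = detect_labelled_asvs(table, windows=[WindowSpec("w1", 1.725, 1.741)])
    by_id = {s.asv_id: s for s in res.summaries}
    assert not by_id["hot"].labelled
    assert by_id["hot"].timepoints_significant == 2


def test_detect_labelled_skips_timepoint_missing_treatment():
    table = _labelled_toy_table(sig_days=(4, 10, 13))
    # drop all C12 samples of day 24: the day is excluded from the denominator
    keep = [s for s in table.sample_ids if not s.startswith("C12_d24")]
    table = table.subset_samples(keep)
    res = detect_labelled_asvs(table, windows=[WindowSpec("w1", 1.725, 1.741)])
    assert all(s.timepoints_tested == 3 for s in res.summaries)


def test_detect_labelled_alpha_and_min_timepoint_monotonicity():
    table = _labelled_toy_table(sig_days=(4, 10, 13), seed=3)
    win = [WindowSpec("w1", 1.725, 1.741)]
    strict = set(detect_labelled_asvs(table, windows=win, alpha=0.01).labelled_asvs)
    loose = set(detect_labelled_asvs(table, windows=win, alpha=0.05).labelled_asvs)
    assert strict <= loose
    few = set(detect_labelled_asvs(table, windows=win, min_timepoints=4).labelled_asvs)
    many = set(detect_labelled_asvs(table, windows=win, min_timepoints=3).labelled_asvs)
    assert few <= many


def test_detect_responders_and_null_self_comparison():
    taxa = [SynthTaxon(asv_id="resp", base_abundance=0.02,
                       response_profile={10: 10.0, 13: 10.0, 24: 10.0}),
            SynthTaxon(asv_id="once", base_abundance=0.02,
                       response_profile={31: 10.0})]
    taxa += [SynthTaxon(asv_id=f"bg{i}", base_abundance=0.96 / 20)
             for i in range(20)]
    table, truth = simulate_microcosm_timeseries(taxa, substrate="DNA", seed=7)
    res = detect_substrate_responders(table, substrate="DNA")
    assert "resp" in res.labelled_asvs
    by_id = {s.asv_id: s for s in res.summaries}
    assert by_id["resp"].timepoints_significant == 3
    # enriched at a single time point only: excluded by the >=2 rule
    assert "once" not in res.labelled_asvs
    assert by_id["once"].timepoints_significant == 1
    # self-comparison of the control arm finds nothing
    null = detect_substrate_responders(table, substrate="no_substrate")
    assert null.labelled_asvs == []


# ---------------------------------------------------------------------------
# group aggregation
# ---------------------------------------------------------------------------


def _summaries(labelled_ids, groups):
    return [LabelSummary(a, 3, 4, True, groups.get(a, "")) for a in labelled_ids]


def test_aggregate_group_calls_counts_groups():
    groups = {f"a{i}": f"g{i % 4}" for i in range(12)}
    out = aggregate_group_calls(_summaries(list(groups), groups), groups)
    assert len(out) == 4
    assert out["n_labelled_asvs"].sum() == 12

    assert len(aggregate_group_calls([], {})) == 0

    one = {"x1": "g", "x2": "g", "x3": "g"}
    out = aggregate_group_calls(_summaries(list(one), one), one)
    assert len(out) == 1 and int(out.loc[0, "n_labelled_asvs"]) == 3


def test_aggregate_group_calls_missing_mapping_errors():
    with pytest.raises(ValueError, match="orphan"):
        aggregate_group_calls(_summaries(["orphan"], {}), {})
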