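"""Contrast counting, fit metrics, resampling, significance, grid selection."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from speechrecal import (
    ContrastSummary,
    FitMetrics,
    PerceptualModel,
    RuleParams,
    ci_median_difference,
    compute_contrasts,
    fit_metrics,
    resample_groups,
    run_grid,
    select_best,
    wilcoxon_signed_rank,
)
from speechrecal.evaluation import GridPointResult
from speechrecal.experiment import CATEGORIES, STIM_TYPES, ExperimentResult
from speechrecal.rules import ListenerState


def make_result(seq):
    """Build an ExperimentResult from (stim_type, percept) pairs."""
    codes = np.array([STIM_TYPES.index(s) for s, _ in seq], dtype=np.int8)
    perc = np.array([CATEGORIES.index(p) for _, p in seq], dtype=np.int8)
    n = len(seq)
    state = ListenerState.initial(PerceptualModel.default(), RuleParams.none())
    return ExperimentResult(
        listener_id=0,
        seed=None,
        rule_params=RuleParams.none(),
        stim_codes=codes,
        s_V=np.full(n, np.nan),
        s_A=np.zeros(n),
        posteriors=np.full((n, 3), 1 / 3),
        percept_codes=perc,
        final_state=state,
    )


# ---------------------------------------------------------------------------
# conditional contrasts
# ---------------------------------------------------------------------------

def test_contrasts_on_hand_counted_sequence():
    """Eight-trial fixture with manually enumerated conditional cells."""
    seq = [
        ("AV_McGurk", "ada"),  # fused
        ("A_aba", "ada"),      # after fused McGurk -> 'ada'
        ("A_aba", "aba"),      # after control (A_aba) -> not 'ada'
        ("A_ada", "ada"),      # correctly perceived /ada/
        ("A_aba", "ada"),      # after correct /ada/ -> 'ada'
        ("AV_McGurk", "aga"),  # NOT fused
        ("A_aba", "aba"),      # after non-fused McGurk: in neither cell
        ("A_aba", "ada"),      # after control (A_aba) -> 'ada'
    ]
    cs = compute_contrasts(make_result(seq))
    assert cs.p_ada_mc == pytest.approx(100.0)       # 1/1
    assert cs.p_ada_oth_mc == pytest.approx(50.0)    # trials 3, 8
    assert cs.p_ada_ada == pytest.approx(100.0)      # trial 5
    assert cs.p_ada_oth_ada == pytest.approx(50.0)   # trials 3, 8
    assert cs.p_ada_all == pytest.approx(60.0)       # 3 of 5 A_aba trials
    assert cs.c_stim[0] == pytest.approx(40.0)       # 2/5 'aba'
    assert cs.c_stim[1] == pytest.approx(100.0)
    assert cs.c_stim[4] == pytest.approx(50.0)       # 1/2 fused
    assert math.isnan(cs.c_stim[2])                  # stimulus type never shown


def test_contrast_empty_cells_are_flagged_not_zero_filled():
    seq = [("A_aba", "aba"), ("A_aba", "aba"), ("AV_McGurk", "aga"), ("A_aba", "aba")]
    cs = compute_contrasts(make_result(seq))
    assert math.isnan(cs.p_ada_mc)  # no fused McGurk predecessor exists
    assert cs.p_ada_oth_mc == pytest.approx(0.0)


def test_contrast_first_trial_excluded_from_conditional_cells():
    # a lone A_aba at position 1 counts only toward c_stim / p_ada_all
    seq = [("A_aba", "ada"), ("AV_McGurk", "ada"), ("A_aba", "ada")]
    cs = compute_contrasts(make_result(seq))
    assert cs.p_ada_mc == pytest.approx(100.0)
    assert math.isnan(cs.p_ada_oth_mc)
    assert cs.p_ada_all == pytest.approx(100.0)


def test_every_aba_after_fused_mcgurk_perceived_ada_gives_100():
    seq = [("AV_McGurk", "ada"), ("A_aba", "ada")] * 4
    cs = compute_contrasts(make_result(seq))
    assert cs.p_ada_mc == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# fit metrics
# ---------------------------------------------------------------------------

def test_fit_metrics_zero_at_printed_targets():
    fm = fit_metrics(29.0, 16.0, (80, 83, 98, 98, 87, 98))
    assert fm.delta_mc == 0.0
    assert fm.delta_overall == 0.0
    assert fm.combined == 0.0


def test_fit_metrics_direct_arithmetic():
    fm = fit_metrics(31.0, 18.0)
    assert fm.delta_mc == pytest.approx(2.0)
    assert math.isnan(fm.delta_overall)
    fm = fit_metrics(29.0, 16.0, (81, 84, 99, 99, 88, 99))
    assert fm.delta_overall == pytest.approx(1.0)
    assert fm.combined == pytest.approx(6.0)


def test_fit_metrics_undefined_inputs_propagate():
    fm = fit_metrics(math.nan, 16.0)
    assert math.isnan(fm.delta_mc) and math.isnan(fm.combined)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank vs exhaustive sign enumeration
# ---------------------------------------------------------------------------

def _enumeration_p(d):
    d = np.asarray(d, float)
    d = d[d != 0]
    r = stats.rankdata(np.abs(d))
    w = r[d > 0].sum()
    null = np.array(
        [np.dot(signs, r) for signs in itertools.product((0.0, 1.0), repeat=d.size)]
    )
    p_le = np.mean(null <= w + 1e-9)
    p_ge = np.mean(null >= w - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


def test_wilcoxon_matches_enumeration_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(3, 11))
        d = rng.standard_normal(n)
        assert wilcoxon_signed_rank(d) == pytest.approx(_enumeration_p(d), abs=1e-12)


def test_wilcoxon_all_positive_n6_exact():
    assert wilcoxon_signed_rank([1, 2, 3, 4, 5, 6]) == pytest.approx(2 / 64)


def test_wilcoxon_degenerate_inputs():
    assert wilcoxon_signed_rank(np.zeros(8)) == 1.0  # vacuous by convention
    # pairs interface and NaN pair-dropping
    x = np.array([1.0, 2.0, np.nan, 4.0])
    y = np.array([0.5, 2.5, 1.0, 3.0])
    assert wilcoxon_signed_rank(x, y) == pytest.approx(
        wilcoxon_signed_rank([0.5, -0.5, 1.0])
    )
    # antisymmetric differences sit at the null center
    assert wilcoxon_signed_rank([2.0, -2.0, 1.0, -1.0]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _synthetic_summaries(n=100, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        mc = float(rng.normal(28, 8))
        oth = float(rng.normal(16, 4))
        out.append(
            ContrastSummary(
                listener_id=i,
                p_ada_mc=mc,
                p_ada_oth_mc=oth,
                p_ada_ada=float(rng.normal(17, 5)),
                p_ada_oth_ada=float(rng.normal(15, 4)),
                p_ada_all=float(rng.normal(18, 4)),
                c_stim=tuple(rng.normal((80, 83, 98, 98, 87, 98), 3)),
            )
        )
    return out


def test_resample_whole_cohort_reproduces_cohort_medians():
    summaries = _synthetic_summaries()
    dist = resample_groups(summaries, n_samples=1, group_size=100, rng=0)
    assert dist.p_mc[0] == pytest.approx(np.median([s.p_ada_mc for s in summaries]))
    assert dist.p_oth[0] == pytest.approx(np.median([s.p_ada_oth_mc for s in summaries]))


def test_resample_deterministic_and_group_size_checked():
    summaries = _synthetic_summaries()
    a = resample_groups(summaries, n_samples=50, group_size=27, rng=3)
    b = resample_groups(summaries, n_samples=50, group_size=27, rng=3)
    np.testing.assert_array_equal(a.indices, b.indices)
    np.testing.assert_array_equal(a.p_mc, b.p_mc)
    np.testing.assert_array_equal(a.wilcoxon_p, b.wilcoxon_p)
    with pytest.raises(ValueError):
        resample_groups(summaries, group_size=101)


def test_resample_median_spread_shrinks_with_group_size():
    summaries = _synthetic_summaries()
    spreads = [
        resample_groups(summaries, n_samples=400, group_size=g, rng=1).p_mc.std()
        for g in (10, 27, 90)
    ]
    assert spreads[0] > spreads[1] > spreads[2]


def test_resample_groups_draw_without_replacement():
    dist = resample_groups(_synthetic_summaries(), n_samples=20, group_size=27, rng=2)
    for row in dist.indices:
        assert len(set(row.tolist())) == 27


def test_representative_sample_is_lower_middle_median():
    summaries = _synthetic_summaries()
    dist = resample_groups(summaries, n_samples=10, group_size=27, rng=5)
    order = np.argsort(dist.combined, kind="stable")
    assert dist.representative_index == order[(10 - 1) // 2]


def test_ci_median_difference_degenerate_and_order():
    class D:
        diff = np.full(100, 3.25)
    lo, hi = ci_median_difference(D.diff)
    assert (lo, hi) == (3.25, 3.25)
    dist = resample_groups(_synthetic_summaries(), n_samples=500, group_size=27, rng=4)
    lo, hi = ci_median_difference(dist)
    assert lo < np.median(dist.diff) < hi


# ---------------------------------------------------------------------------
# grid search and selection
# ---------------------------------------------------------------------------

def test_select_best_recovers_planted_optimum():
    def point(dmc):
        return GridPointResult(
            perceptual_params={"id": dmc},
            rule_params=RuleParams.none(),
            summaries=[],
            fit=FitMetrics(delta_mc=dmc, delta_overall=0.0),
        )

    grid = [point(5.0), point(1.5), point(0.2), point(1.5)]
    assert select_best(grid).fit.delta_mc == 0.2
    # ties broken by grid order
    grid = [point(1.5), point(1.5)]
    assert select_best(grid) is grid[0]
    with pytest.raises(ValueError):
        select_best([])


def test_run_grid_single_point_structure_and_determinism():
    one_point = ({"noise_V": 0.1, "noise_A": 0.1, "sigma_kA": 0.1, "sigma_kV": 0.1},)
    a = run_grid(RuleParams.none(), perceptual_grid=one_point, n_listeners=3,
                 master_seed=6)
    b = run_grid(RuleParams.none(), perceptual_grid=one_point, n_listeners=3,
                 master_seed=6)
    assert len(a) == 1
    assert len(a[0].summaries) == 3
    assert a[0].fit.delta_mc == b[0].fit.delta_mc
    assert select_best(a) is a[0]
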