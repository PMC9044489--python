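"""Statistical battery: contingency tests, ANOVA post hocs, correlations,
Ward clustering with model-based k selection, regression screens."""

import itertools
import numpy as np
import pytest
from scipy import stats as sps

from pmscohort.stats import (
    contingency_test,
    correlations,
    fisher_exact_rxc,
    group_anova,
    regression_screen,
    select_k,
    ward_cluster,
)


# -- contingency -------------------------------------------------------------

def test_chi_square_matches_2x2_closed_form():
    a, b, c, d = 10, 0, 0, 10
    res = contingency_test([[a, b], [c, d]])
    n = a + b + c + d
    closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert res.statistic == pytest.approx(closed) == pytest.approx(20.0)


def test_uniform_2x2_gives_zero_statistic():
    res = contingency_test([[1, 1], [1, 1]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_small_expected_counts_trigger_fisher():
    table = [[2, 3, 1], [4, 1, 5]]
    res = contingency_test(table)
    assert "FET" in res.method_notes
    # independent oracle for 2x2 via scipy's exact test
    res22 = contingency_test([[2, 1], [1, 4]])
    _, p_scipy = sps.fisher_exact([[2, 1], [1, 4]])
    assert res22.p_value == pytest.approx(p_scipy, rel=1e-9)


def test_rxc_fisher_matches_independent_enumeration():
    """Oracle: brute force over the full cell lattice with itertools."""
    table = np.array([[2, 3, 1], [4, 1, 5]])
    rs, cs = table.sum(1), table.sum(0)
    n = table.sum()

    def prob(t):
        # multivariate hypergeometric via exact integer factorial products
        from math import factorial as f, prod

        num = prod(f(int(x)) for x in rs) * prod(f(int(x)) for x in cs)
        den = f(int(n)) * prod(f(int(x)) for x in t.ravel())
        return num / den

    p_obs = prob(table)
    total = 0.0
    for top in itertools.product(*(range(min(rs[0], c) + 1) for c in cs)):
        top = np.array(top)
        if top.sum() != rs[0]:
            continue
        bottom = cs - top
        if (bottom < 0).any():
            continue
        t = np.vstack([top, bottom])
        pt = prob(t)
        if pt <= p_obs * (1 + 1e-9):
            total += pt
    assert fisher_exact_rxc(table) == pytest.approx(total, rel=1e-9)


def test_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        contingency_test([[0, 0], [3, 4]])


def test_column_proportion_posthoc_bonferroni():
    # columns 1 and 3 clearly differ, 1 and 2 do not
    table = [[40, 38, 5], [10, 12, 45]]
    res = contingency_test(table, post_hoc=True)
    flags = {pair: sig for pair, _, sig in res.post_hoc}
    assert flags[(1, 3)] and flags[(2, 3)]
    assert not flags[(1, 2)]
    for (_, p_adj, _), (_, p_raw_pair, _) in zip(res.post_hoc, res.post_hoc):
        assert 0 <= p_adj <= 1


# -- ANOVA -------------------------------------------------------------------

def test_identical_groups_give_zero_F():
    res = group_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_two_group_F_equals_squared_pooled_t():
    rng = np.random.default_rng(0)
    a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
    res = group_anova([a, b])
    t, p = sps.ttest_ind(a, b)
    assert res.statistic == pytest.approx(t**2)
    assert res.p_value == pytest.approx(p)


@pytest.mark.parametrize("method", ["bonferroni", "dunnett_t3"])
def test_posthoc_flags_only_separated_pairs(method):
    rng = np.random.default_rng(1)
    g1, g2 = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
    g3 = rng.normal(10, 1, 20)
    res = group_anova([g1, g2, g3], post_hoc=method)
    sig = {pair for pair, _, s in res.post_hoc if s}
    assert sig == {(1, 3), (2, 3)}


def test_adjusted_p_never_below_raw():
    rng = np.random.default_rng(2)
    groups = [rng.normal(i * 0.3, 1, 15) for i in range(4)]
    res = group_anova(groups, post_hoc="bonferroni")
    m = len(res.post_hoc)
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_err = sum(len(g) for g in groups) - 4
    mse = sse / df_err
    for (i, j), p_adj, _ in res.post_hoc:
        gi, gj = groups[i - 1], groups[j - 1]
        t = (gi.mean() - gj.mean()) / np.sqrt(mse * (1 / len(gi) + 1 / len(gj)))
        p_raw = 2 * sps.t.sf(abs(t), df_err)
        assert p_adj >= p_raw - 1e-12
        assert p_adj == pytest.approx(min(1.0, m * p_raw))


# -- correlations ------------------------------------------------------------

def test_perfect_correlation_all_methods():
    x = np.arange(10.0)
    for method in ("pearson", "spearman", "kendall_tau_b"):
        r, _ = correlations(x, x, method)
        assert r == pytest.approx(1.0)


def test_anticoncordant_binary_tau_b():
    x = np.array([0, 0, 0, 1, 1, 1])
    r, _ = correlations(x, 1 - x, "kendall_tau_b")
    assert r == pytest.approx(-1.0)


def test_tau_b_matches_pair_counting_oracle():
    rng = np.random.default_rng(8)
    x = rng.integers(0, 2, 30).astype(float)
    y = rng.integers(0, 2, 30).astype(float)
    r, _ = correlations(x, y, "kendall_tau_b")
    conc = disc = tx = ty = 0
    for i in range(30):
        for j in range(i + 1, 30):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    oracle = (conc - disc) / np.sqrt((conc + disc + tx) * (conc + disc + ty))
    assert r == pytest.approx(oracle, rel=1e-10)


def test_zero_variance_flagged():
    with pytest.raises(ValueError, match="variance"):
        correlations([1, 1, 1, 1], [1, 2, 3, 4])


def test_pairwise_deletion_of_missing():
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
    y = np.array([2.0, 4.0, 9.0, 8.0, 10.0])
    r, _ = correlations(x, y)
    assert r == pytest.approx(1.0)


# -- Ward clustering ---------------------------------------------------------

def ward_greedy_oracle(values):
    """Brute-force greedy agglomeration minimizing the ESS increase, with
    lowest-index tie-breaking; returns the partition at every k."""
    clusters = [[i] for i in range(len(values))]
    partitions = {len(clusters): [set(c) for c in clusters]}
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                xa = values[clusters[a]]
                xb = values[clusters[b]]
                d = (
                    len(xa) * len(xb) / (len(xa) + len(xb))
                    * (xa.mean() - xb.mean()) ** 2
                )
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        partitions[len(clusters)] = [set(c) for c in clusters]
    return partitions


def test_merge_tree_matches_greedy_oracle_small_n():
    rng = np.random.default_rng(21)
    for _ in range(10):
        values = rng.normal(0, 1, 8)
        solutions = ward_cluster(values, k_max=7)
        oracle = ward_greedy_oracle(values)
        for sol in solutions:
            got = [set(np.where(sol.assignments == c)[0]) for c in range(1, sol.k + 1)]
            assert sorted(map(sorted, got)) == sorted(map(sorted, oracle[sol.k]))


def test_separated_pairs_split_cleanly():
    sols = ward_cluster([0.0, 0.1, 10.0, 10.1], k_max=2)
    two = next(s for s in sols if s.k == 2)
    assert two.means == pytest.approx([0.05, 10.05])
    assert two.counts.tolist() == [2, 2]


def test_all_equal_values_deterministic():
    a = ward_cluster([2.0] * 6, k_max=2)
    b = ward_cluster([2.0] * 6, k_max=2)
    assert (a[1].assignments == b[1].assignments).all()


def test_k_selection_recovers_generative_structure():
    rng = np.random.default_rng(0)
    x4 = np.concatenate([rng.normal(m, 0.3, 50) for m in (0.5, 3.4, 6.1, 8.3)])
    assert select_k(ward_cluster(x4, 8)) == 4
    single = rng.normal(5.0, 0.3, 200)
    assert select_k(ward_cluster(single, 8)) == 1
    coincident = np.concatenate([rng.normal(m, 0.3, 50) for m in (0.5, 3.4, 6.1, 6.1)])
    assert select_k(ward_cluster(coincident, 8)) < 4


def test_k_max_validation():
    with pytest.raises(ValueError):
        ward_cluster([1.0, 2.0], k_max=0)
    with pytest.raises(ValueError):
        ward_cluster([1.0, 2.0], k_max=5)


# -- regression screen -------------------------------------------------------

def test_screen_separates_planted_from_null_features():
    from pmscohort.simulate import default_calibration, generate_cohort
    from pmscohort.catalog import SIZE_LINKED

    cfg = default_calibration(seed=17, n_patients=800)
    cohort, _ = generate_cohort(cfg)
    table, summary = regression_screen(cohort, dependent="size")
    table = table.set_index("feature_id")
    # strongly size-coupled adverse item is detected with the planted sign
    assert table.loc["lymphedema", "significant"]
    assert summary["tested"] > 0
    planted = [f for f, s in SIZE_LINKED.items()]
    hit_rate_planted = table.loc[planted, "significant"].mean()
    null = [f for f in table.index if f not in planted and table.loc[f, "note"] == ""]
    hit_rate_null = table.loc[null, "significant"].mean()
    assert hit_rate_planted > hit_rate_null


def test_null_features_flag_near_alpha():
    """61 size-independent items: significant count stays near the 5%
    chance expectation (binomial check)."""
    from pmscohort.simulate import default_calibration, generate_cohort

    cfg = default_calibration(seed=23, n_patients=600)
    cfg.feature_models = {
        fid: (base, 0.0, miss) for fid, (base, _, miss) in cfg.feature_models.items()
    }
    cohort, _ = generate_cohort(cfg)
    table, summary = regression_screen(cohort, dependent="size")
    n, p = summary["tested"], 0.05
    assert summary["expected_by_chance"] == pytest.approx(n * p)
    # 3 binomial SDs around the expectation
    assert abs(summary["significant"] - n * p) <= 3 * np.sqrt(n * p * (1 - p)) + 1


def test_constant_feature_skipped():
    from pmscohort.simulate import default_calibration, generate_cohort

    cfg = default_calibration(seed=2, n_patients=50)
    cohort, _ = generate_cohort(cfg)
    for p in cohort.phenotypes:
        p.items["obesity"] = "absent"
    table, _ = regression_screen(cohort, dependent="size")
    row = table.set_index("feature_id").loc["obesity"]
    assert row["note"].startswith("skipped")
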