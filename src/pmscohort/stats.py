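"""Genotype-phenotype statistical battery.

Frequency comparisons (chi-square with automatic Fisher-exact fallback and
pairwise column-proportion z tests), one-way ANOVA with Bonferroni or
Dunnett-T3 post hoc procedures, the three correlation coefficients
(Pearson, Spearman, tie-corrected Kendall tau-b), Ward minimum-variance
clustering of deletion sizes with BIC/AIC cluster-count selection, and the
per-feature linear-regression screen against a continuous dependent
variable (deletion size or age).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .cnv import deletion_size
from .cohort import ABSENT, Cohort, PRESENT

ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: object
    p_value: float
    post_hoc: list[tuple[tuple[int, int], float, bool]] = field(default_factory=list)
    method_notes: str = ""


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, row_sums, col_sums, n) -> float:
    # multivariate hypergeometric probability of a table with fixed margins
    lp = sum(lgamma(r + 1) for r in row_sums) + sum(lgamma(c + 1) for c in col_sums)
    lp -= lgamma(n + 1)
    lp -= sum(lgamma(x + 1) for x in table.ravel())
    return lp


def _enumerate_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def fill(row_idx, cols_left, rows):
        if row_idx == r - 1:
            last = np.array(cols_left)
            if (last >= 0).all():
                yield rows + [last]
            return
        target = row_sums[row_idx]

        def fill_row(col_idx, remaining, row):
            if col_idx == c - 1:
                if 0 <= remaining <= cols_left[col_idx]:
                    yield row + [remaining]
                return
            hi = min(remaining, cols_left[col_idx])
            for v in range(hi + 1):
                yield from fill_row(col_idx + 1, remaining - v, row + [v])

        for row in fill_row(0, target, []):
            new_left = [cl - v for cl, v in zip(cols_left, row)]
            yield from fill(row_idx + 1, new_left, rows + [np.array(row)])

    yield from (np.array(t) for t in fill(0, list(col_sums), []))


def fisher_exact_rxc(table: np.ndarray, max_tables: int = 2_000_000) -> float:
    """Fisher's exact test for an r x c table by full enumeration.

    Two-sided p: sum of probabilities of all margin-consistent tables at
    most as probable as the observed one (standard small-p rule).
    """
    table = np.asarray(table, dtype=int)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())
    lp_obs = _log_table_prob(table, row_sums, col_sums, n)
    total = 0.0
    count = 0
    for t in _enumerate_tables(list(row_sums), list(col_sums)):
        count += 1
        if count > max_tables:
            raise RuntimeError("table lattice too large for exact enumeration")
        lp = _log_table_prob(t, row_sums, col_sums, n)
        if lp <= lp_obs + 1e-9:
            total += np.exp(lp)
    return min(total, 1.0)


def contingency_test(table, post_hoc: bool = False, alpha: float = ALPHA) -> TestResult:
    """Pearson chi-square on an r x c count table; automatic Fisher-exact
    substitution when any expected count falls below 5 (noted "FET").

    With ``post_hoc`` pairwise column-proportion z tests (first row treated
    as successes) are run with Bonferroni adjustment.
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold nonnegative integer counts")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: a zero margin")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=False)
    notes = "chi-square"
    if (expected < 5).any():
        try:
            p = fisher_exact_rxc(table.astype(int))
            notes = "FET (expected count < 5; Fisher exact substitution)"
        except RuntimeError:
            notes = "chi-square (expected count < 5 but table too large for FET)"
    result = TestResult("contingency", float(chi2), int(df), float(p), method_notes=notes)
    if post_hoc and table.shape[0] >= 2 and table.shape[1] >= 2:
        pairs = list(combinations(range(table.shape[1]), 2))
        m = len(pairs)
        for i, j in pairs:
            x = np.array([table[0, i], table[0, j]])
            ntot = np.array([table[:, i].sum(), table[:, j].sum()])
            p_pool = x.sum() / ntot.sum()
            se = np.sqrt(p_pool * (1 - p_pool) * (1 / ntot[0] + 1 / ntot[1]))
            if se == 0:
                continue
            z = (x[0] / ntot[0] - x[1] / ntot[1]) / se
            p_raw = 2 * stats.norm.sf(abs(z))
            p_adj = min(1.0, m * p_raw)
            result.post_hoc.append(((i + 1, j + 1), float(p_adj), p_adj < alpha))
    return result


# ---------------------------------------------------------------------------
# ANOVA and post hoc procedures
# ---------------------------------------------------------------------------

def group_anova(
    groups: Sequence[Sequence[float]],
    post_hoc: str = "bonferroni",
    alpha: float = ALPHA,
) -> TestResult:
    """One-way ANOVA with Bonferroni or Dunnett-T3 pairwise post hoc tests.

    Bonferroni: pairwise t on the pooled ANOVA error variance (df = N - k),
    raw p multiplied by the number of pairs.  Dunnett T3: pairwise Welch t
    with studentized-maximum-modulus adjustment, robust to unequal
    variances.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    F, p = stats.f_oneway(*groups)
    N = sum(len(g) for g in groups)
    if not np.isfinite(F):  # identical groups, zero between and within variance
        F, p = 0.0, 1.0
    result = TestResult("anova", float(F), (k - 1, N - k), float(p))

    pairs = list(combinations(range(k), 2))
    m = len(pairs)
    if post_hoc == "bonferroni":
        sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_err = N - k
        mse = sse / df_err
        for i, j in pairs:
            gi, gj = groups[i], groups[j]
            se = np.sqrt(mse * (1 / len(gi) + 1 / len(gj)))
            if se == 0:
                p_adj = 1.0
            else:
                t = (gi.mean() - gj.mean()) / se
                p_adj = min(1.0, m * 2 * stats.t.sf(abs(t), df_err))
            result.post_hoc.append(((i + 1, j + 1), float(p_adj), p_adj < alpha))
        result.method_notes = "bonferroni (pooled-variance t)"
    elif post_hoc == "dunnett_t3":
        for i, j in pairs:
            gi, gj = groups[i], groups[j]
            vi, vj = gi.var(ddof=1) / len(gi), gj.var(ddof=1) / len(gj)
            se = np.sqrt(vi + vj)
            if se == 0:
                p_adj = 1.0
            else:
                t = (gi.mean() - gj.mean()) / se
                df_w = (vi + vj) ** 2 / (
                    vi**2 / (len(gi) - 1) + vj**2 / (len(gj) - 1)
                )
                # studentized-maximum-modulus approximation over m moduli
                p_adj = 1.0 - (2 * stats.t.cdf(abs(t), df_w) - 1.0) ** m
            result.post_hoc.append(((i + 1, j + 1), float(p_adj), p_adj < alpha))
        result.method_notes = "dunnett_t3 (Welch t, studentized maximum modulus)"
    else:
        raise ValueError(f"unknown post hoc procedure {post_hoc!r}")
    return result


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def correlations(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and p-value after pairwise deletion.

    ``kendall_tau_b`` uses the tie-corrected denominator.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    elif method == "kendall_tau_b":
        res = stats.kendalltau(x, y, variant="b")
        r, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Ward clustering with BIC/AIC cluster-count selection
# ---------------------------------------------------------------------------

@dataclass
class ClusterSolution:
    k: int
    assignments: np.ndarray  # cluster index 1..k per observation, labels sorted by mean
    means: np.ndarray  # ascending
    sds: np.ndarray
    counts: np.ndarray
    bic: float
    aic: float
    log_likelihood: float
    values: np.ndarray  # the clustered data (needed for model-based selection)


def _dispersion_loglik(values: np.ndarray, labels: np.ndarray, k: int, s2: float):
    """Log-likelihood dispersion term of a hard partition.

    Per cluster ``-n_c/2 * log(s2 + var_c)`` where ``s2`` is the total data
    variance.  The additive offset regularizes tiny within-cluster
    variances, so refining a cut beyond the real structure yields almost no
    gain — the behaviour of the log-likelihood distance used by the
    auto-clustering procedures of mainstream statistical packages.
    """
    ll = 0.0
    means, sds, counts = [], [], []
    for c in range(1, k + 1):
        x = values[labels == c]
        var = x.var(ddof=0) if len(x) > 1 else 0.0
        ll += -len(x) * 0.5 * np.log(s2 + var)
        means.append(x.mean())
        sds.append(np.sqrt(x.var(ddof=1)) if len(x) > 1 else 0.0)
        counts.append(len(x))
    return ll, np.array(means), np.array(sds), np.array(counts)


def ward_cluster(sizes: Sequence[float], k_max: int) -> list[ClusterSolution]:
    """Ward minimum-variance hierarchical clustering of a 1-D variable.

    One agglomerative tree is built and cut at k = 1..k_max; each cut is
    scored with the variance-offset dispersion likelihood and penalized
    with 2k parameters (per-cluster mean and variance):
    BIC = -2 LL + 2k ln n, AIC = -2 LL + 4k.  Cluster labels are relabeled
    in ascending order of mean; ties in the tree are resolved
    deterministically (lowest merge index).
    """
    values = np.asarray(sizes, dtype=float)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = len(values)
    if n < k_max + 1:
        raise ValueError("need more observations than k_max")
    Z = linkage(values[:, None], method="ward")
    s2 = max(values.var(ddof=0), 1e-12)  # flagged floor for degenerate data
    solutions = []
    for k in range(1, k_max + 1):
        raw = fcluster(Z, t=k, criterion="maxclust")
        # zero-height ties can leave fewer populated clusters than requested
        present = sorted(set(int(c) for c in raw))
        k_eff = len(present)
        order = np.argsort([values[raw == c].mean() for c in present])
        relabel = {present[int(old)]: int(new + 1) for new, old in enumerate(order)}
        labels = np.array([relabel[int(c)] for c in raw])
        ll, means, sds, counts = _dispersion_loglik(values, labels, k_eff, s2)
        params = 2 * k_eff
        solutions.append(
            ClusterSolution(
                k=k,
                assignments=labels,
                means=means,
                sds=sds,
                counts=counts,
                bic=float(-2 * ll + params * np.log(n)),
                aic=float(-2 * ll + 2 * params),
                log_likelihood=float(ll),
                values=values,
            )
        )
    return solutions


def _prefers_single_component(values: np.ndarray) -> bool:
    """Mixture-model check that the data cluster at all.

    Compares 1- vs 2-component Gaussian-mixture BIC (maximum likelihood via
    EM); a unimodal sample prefers one component, in which case cutting the
    Ward tree is refinement of noise.
    """
    from sklearn.mixture import GaussianMixture

    X = np.asarray(values, dtype=float)[:, None]
    if np.ptp(X) == 0:
        return True
    fits = [
        GaussianMixture(n_components=k, n_init=3, random_state=0).fit(X).bic(X)
        for k in (1, 2)
    ]
    return fits[0] <= fits[1]


def select_k(solutions: Sequence[ClusterSolution], criterion: str = "aic") -> int:
    """Cluster count minimizing the information criterion over Ward cuts.

    A preliminary mixture-model comparison guards against splitting
    unimodal data (returns 1); otherwise the k minimizing AIC (default) or
    BIC of the dispersion likelihood is returned.  AIC is the default
    selector: with few observations per candidate component the heavier
    BIC penalty is known to merge adjacent real components.
    """
    if not solutions:
        raise ValueError("no solutions")
    if criterion not in ("aic", "bic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if _prefers_single_component(solutions[0].values):
        return 1
    best = min(solutions, key=lambda s: getattr(s, criterion))
    return best.k


def cluster_deletion_sizes(cohort: Cohort, k_max: int = 8) -> tuple[list[ClusterSolution], int]:
    """Ward+BIC clustering of the cohort's deletion sizes (Mb)."""
    sizes = [
        deletion_size(f) / 1e6 for f in cohort.findings if f.kind == "deletion"
    ]
    solutions = ward_cluster(sizes, k_max=min(k_max, len(sizes) - 1))
    return solutions, select_k(solutions)


# ---------------------------------------------------------------------------
# Per-feature regression screen
# ---------------------------------------------------------------------------

def _dependent_values(cohort: Cohort, dependent: str) -> dict[str, float]:
    out = {}
    if dependent == "size":
        for f in cohort.findings:
            if f.kind == "deletion":
                out[f.patient_id] = deletion_size(f) / 1e6
    elif dependent == "age_dx":
        for p in cohort.phenotypes:
            if p.age_dx_months is not None:
                out[p.patient_id] = p.age_dx_months
    elif dependent == "age_eval":
        for p in cohort.phenotypes:
            if p.age_eval_years is not None:
                out[p.patient_id] = p.age_eval_years
    else:
        raise ValueError(f"unknown dependent variable {dependent!r}")
    return out


def regression_screen(
    cohort: Cohort,
    dependent: str = "size",
    feature_ids: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, dict]:
    """Simple linear regression of a continuous variable on each 0/1 item.

    Per feature the absolute correlation coefficient |r|, R-squared and the
    regression F-test p-value are reported (pairwise deletion of missing
    data); constant features are skipped with a note.  The summary gives
    the significant count over features tested and the count expected by
    chance at the chosen alpha.
    """
    if feature_ids is None:
        feature_ids = [f.feature_id for f in cohort.catalog]
    dep = _dependent_values(cohort, dependent)
    if len(dep) < 10:
        raise ValueError(f"dependent {dependent!r} present for fewer than 10 patients")
    rows = []
    n_tested = 0
    for fid in feature_ids:
        xs, ys = [], []
        for p in cohort.phenotypes:
            state = p.items.get(fid, "missing")
            if state not in (PRESENT, ABSENT) or p.patient_id not in dep:
                continue
            xs.append(1.0 if state == PRESENT else 0.0)
            ys.append(dep[p.patient_id])
        xs, ys = np.array(xs), np.array(ys)
        if len(xs) < 3 or xs.std() == 0 or ys.std() == 0:
            rows.append(
                {"feature_id": fid, "n": len(xs), "abs_r": np.nan, "r2": np.nan,
                 "p_value": np.nan, "significant": False, "note": "skipped (constant)"}
            )
            continue
        n_tested += 1
        fit = stats.linregress(xs, ys)
        rows.append(
            {
                "feature_id": fid,
                "n": len(xs),
                "abs_r": abs(fit.rvalue),
                "r2": fit.rvalue**2,
                "p_value": fit.pvalue,
                "significant": fit.pvalue < alpha,
                "note": "",
            }
        )
    df = pd.DataFrame(rows)
    summary = {
        "dependent": dependent,
        "significant": int(df["significant"].sum()),
        "tested": n_tested,
        "expected_by_chance": alpha * n_tested,
    }
    return df, summary
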