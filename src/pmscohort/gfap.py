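"""Global Functional Assessment of the Patient (GFAP) severity score.

The score weights each clinical item by how common it is in the analyzed
cohort: item frequency (among evaluated patients) is binned to a weight of
1, 2, 5 or 10 points, and a patient's score sums the weights of the adverse
items marked present plus — with reverse scoring — the protective items
marked absent.  Higher scores mean a more severe presentation.

Construct validation follows the classical factor-analysis workup on the
item correlation matrix: Bartlett's sphericity test, the Kaiser-Meyer-Olkin
sampling-adequacy measure, and an unrotated principal-component analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ABSENT, Cohort, PatientPhenotype, PRESENT

#: Default frequency bins, left-open/right-closed: (lo, hi] -> weight.
#: The top weight applies strictly above 70%.
DEFAULT_BINS: tuple[tuple[float, float, int], ...] = (
    (0.0, 20.0, 1),
    (20.0, 35.0, 2),
    (35.0, 70.0, 5),
    (70.0, 100.0, 10),
)


class UndefinedFrequencyError(ValueError):
    """No evaluated patients for a feature: its frequency is undefined."""


class FrequencyResult(NamedTuple):
    percent: float
    n_present: int
    n_evaluated: int


class WeightEntry(NamedTuple):
    frequency: float  # percent in [0, 100]
    weight: int
    n_evaluated: int


WeightTable = dict[str, WeightEntry]


class ScoreResult(NamedTuple):
    score: float
    n_scored: int
    all_missing: bool


def feature_frequency(cohort: Cohort, feature_id: str) -> FrequencyResult:
    """Cohort frequency of a feature among evaluated (non-missing) patients."""
    cohort.feature(feature_id)  # raises KeyError if absent from catalog
    n_present = sum(p.items.get(feature_id) == PRESENT for p in cohort.phenotypes)
    n_absent = sum(p.items.get(feature_id) == ABSENT for p in cohort.phenotypes)
    n_eval = n_present + n_absent
    if n_eval == 0:
        raise UndefinedFrequencyError(
            f"feature {feature_id!r} has no evaluated patients"
        )
    return FrequencyResult(100.0 * n_present / n_eval, n_present, n_eval)


def weight_for_frequency(
    percent: float, bins: Sequence[tuple[float, float, int]] = DEFAULT_BINS
) -> int:
    """Map a frequency (percent) to its severity weight.

    Bins are left-open/right-closed — [0,20]->1, (20,35]->2, (35,70]->5,
    (70,100]->10 — so 70.0% still scores 5 and only frequencies strictly
    above 70% score 10.
    """
    if not np.isfinite(percent) or not (0.0 <= percent <= 100.0):
        raise ValueError(f"frequency {percent!r} outside [0, 100]")
    for lo, hi, weight in bins:
        if (percent > lo or (lo == 0.0 and percent == 0.0)) and percent <= hi:
            return weight
    raise ValueError(f"frequency {percent} not covered by bins {bins}")


def build_weight_table(
    cohort: Cohort,
    feature_ids: Optional[Iterable[str]] = None,
    bins: Sequence[tuple[float, float, int]] = DEFAULT_BINS,
) -> WeightTable:
    """One weight entry per feature, from the cohort's own frequencies."""
    if feature_ids is None:
        feature_ids = [f.feature_id for f in cohort.catalog]
    table: WeightTable = {}
    for fid in feature_ids:
        freq = feature_frequency(cohort, fid)
        table[fid] = WeightEntry(freq.percent, weight_for_frequency(freq.percent, bins), freq.n_evaluated)
    return table


def gfap_score(
    patient: PatientPhenotype,
    weights: WeightTable,
    cohort: Cohort,
    reverse_protective: bool = True,
    normalize: bool = False,
) -> ScoreResult:
    """Severity score for one patient.

    Adverse items contribute their weight when present; protective items
    contribute their weight when absent (reverse scoring, switchable off).
    Missing items contribute 0.  With ``normalize`` the score is divided by
    the maximum attainable over the patient's evaluated items.
    """
    score = 0.0
    attainable = 0.0
    n_scored = 0
    for fid, entry in weights.items():
        state = patient.items.get(fid, "missing")
        if state not in (PRESENT, ABSENT):
            continue
        n_scored += 1
        attainable += entry.weight
        polarity = cohort.feature(fid).polarity
        if polarity == "adverse":
            if state == PRESENT:
                score += entry.weight
        elif reverse_protective:
            if state == ABSENT:
                score += entry.weight
        else:
            if state == PRESENT:
                score += entry.weight
    if normalize and attainable > 0:
        score /= attainable
    return ScoreResult(score, n_scored, all_missing=(n_scored == 0))


def score_cohort(cohort: Cohort, weights: Optional[WeightTable] = None, **kwargs) -> pd.DataFrame:
    """Per-patient GFAP table (``patient_id, gfap, n_scored``)."""
    if weights is None:
        weights = build_weight_table(cohort)
    rows = []
    for p in cohort.phenotypes:
        res = gfap_score(p, weights, cohort, **kwargs)
        rows.append({"patient_id": p.patient_id, "gfap": res.score, "n_scored": res.n_scored})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Construct validation: Bartlett, KMO, PCA
# ---------------------------------------------------------------------------

@dataclass
class ConstructValidation:
    correlation_matrix: pd.DataFrame
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    kmo_overall: float
    kmo_per_item: dict[str, float]
    pc_loadings: pd.DataFrame
    variance_explained: np.ndarray
    n_used: int


def _item_matrix(cohort: Cohort, feature_ids: Sequence[str]) -> pd.DataFrame:
    data = {}
    for fid in feature_ids:
        col = []
        for p in cohort.phenotypes:
            state = p.items.get(fid, "missing")
            col.append(1.0 if state == PRESENT else 0.0 if state == ABSENT else np.nan)
        data[fid] = col
    return pd.DataFrame(data, index=[p.patient_id for p in cohort.phenotypes])


def usable_validation_features(cohort: Cohort) -> list[str]:
    """Feature ids with both states observed (non-degenerate correlations)."""
    out = []
    for f in cohort.catalog:
        states = {p.items.get(f.feature_id, "missing") for p in cohort.phenotypes}
        if PRESENT in states and ABSENT in states:
            out.append(f.feature_id)
    return out


def validate_construct(
    cohort: Cohort, feature_ids: Optional[Sequence[str]] = None
) -> ConstructValidation:
    """Bartlett sphericity, KMO and unrotated PCA on the item correlations.

    The Pearson correlation matrix of the 0/1 item codes is computed
    pairwise-complete.  Bartlett's statistic uses
    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R) with df = p(p-1)/2, where n is
    the mean pairwise-complete sample size.  KMO compares squared marginal
    correlations with squared anti-image partial correlations.
    """
    if feature_ids is None:
        feature_ids = [f.feature_id for f in cohort.catalog]
    feature_ids = list(feature_ids)
    p = len(feature_ids)
    if p < 2:
        raise ValueError("construct validation needs >= 2 features")
    X = _item_matrix(cohort, feature_ids)
    R = X.corr(method="pearson", min_periods=2)
    if R.isna().any().any():
        bad = [fid for fid in feature_ids if R[fid].isna().any()]
        raise ValueError(f"correlation undefined (constant or unpaired items): {bad}")
    Rv = R.to_numpy()

    # effective n: mean pairwise-complete count over off-diagonal pairs
    notna = X.notna().to_numpy().astype(float)
    pair_n = notna.T @ notna
    off = ~np.eye(p, dtype=bool)
    n_eff = int(round(pair_n[off].mean()))

    sign, logdet = np.linalg.slogdet(Rv)
    if sign <= 0:
        raise ValueError("correlation matrix is singular; prune collinear features")
    chi2 = -(n_eff - 1 - (2 * p + 5) / 6.0) * logdet
    chi2 = max(chi2, 0.0)
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))

    try:
        Rinv = np.linalg.inv(Rv)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is singular; prune collinear features") from exc
    d = np.sqrt(np.outer(np.diag(Rinv), np.diag(Rinv)))
    partial = -Rinv / d
    r2 = Rv[off] ** 2
    q2 = partial[off] ** 2
    kmo_overall = float(r2.sum() / (r2.sum() + q2.sum()))
    kmo_items = {}
    for j, fid in enumerate(feature_ids):
        mask = np.ones(p, dtype=bool)
        mask[j] = False
        rj = Rv[j, mask] ** 2
        qj = partial[j, mask] ** 2
        kmo_items[fid] = float(rj.sum() / (rj.sum() + qj.sum()))

    eigval, eigvec = np.linalg.eigh(Rv)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0.0, None)
    loadings = eigvec * np.sqrt(eigval)[None, :]
    pc_cols = [f"PC{i + 1}" for i in range(p)]

    return ConstructValidation(
        correlation_matrix=R,
        bartlett_chi2=float(chi2),
        bartlett_df=df,
        bartlett_p=pval,
        kmo_overall=kmo_overall,
        kmo_per_item=kmo_items,
        pc_loadings=pd.DataFrame(loadings, index=feature_ids, columns=pc_cols),
        variance_explained=eigval / p,
        n_used=n_eff,
    )
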