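"""GFAP severity score: frequencies, bin weights, scoring, construct checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmscohort.cohort import Cohort, PatientPhenotype
from pmscohort.gfap import (
    UndefinedFrequencyError,
    build_weight_table,
    feature_frequency,
    gfap_score,
    validate_construct,
    weight_for_frequency,
)
from .conftest import make_feature


def cohort_with_counts(n_present, n_absent, n_missing, fid="hypotonia"):
    catalog = [make_feature(fid)]
    phenos = []
    states = ["present"] * n_present + ["absent"] * n_absent + ["missing"] * n_missing
    for i, s in enumerate(states):
        phenos.append(PatientPhenotype(f"P{i}", "unknown", None, None, {fid: s}))
    return Cohort(catalog=catalog, phenotypes=phenos, findings=[])


@pytest.mark.parametrize(
    "present,absent,expected",
    [
        (142, 45, 75.9),  # hypotonia
        (125, 62, 66.8),  # high pain threshold
        (0, 10, 0.0),
    ],
)
def test_feature_frequency_matches_count_arithmetic(present, absent, expected):
    res = feature_frequency(cohort_with_counts(present, absent, 2), "hypotonia")
    assert round(res.percent, 1) == expected
    assert res.n_evaluated == present + absent


def test_all_missing_frequency_undefined():
    with pytest.raises(UndefinedFrequencyError, match="hypotonia"):
        feature_frequency(cohort_with_counts(0, 0, 5), "hypotonia")


@pytest.mark.parametrize(
    "percent,weight",
    [
        (0.0, 1), (12.2, 1), (20.0, 1),
        (20.1, 2), (31.0, 2), (35.0, 2),
        (35.1, 5), (66.8, 5), (70.0, 5),
        (70.1, 10), (75.9, 10), (97.4, 10), (100.0, 10),
    ],
)
def test_weight_bins_left_open_right_closed(percent, weight):
    assert weight_for_frequency(percent) == weight


def test_weight_rejects_out_of_range():
    for bad in (-1.0, 101.0, float("nan")):
        with pytest.raises(ValueError):
            weight_for_frequency(bad)


@settings(max_examples=200, derandomize=True)
@given(st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100))
def test_weight_is_nondecreasing_in_frequency(a, b):
    lo, hi = sorted((a, b))
    assert weight_for_frequency(lo) <= weight_for_frequency(hi)
    assert weight_for_frequency(a) in {1, 2, 5, 10}


def test_weight_table_reproducible_from_frequencies():
    catalog = [make_feature("speech_delay"), make_feature("growth_lt_3")]
    phenos = []
    for i in range(189):
        phenos.append(
            PatientPhenotype(
                f"P{i}", "unknown", None, None,
                {
                    "speech_delay": "present" if i < 184 else "absent",
                    "growth_lt_3": "present" if i < 23 else ("absent" if i < 188 else "missing"),
                },
            )
        )
    cohort = Cohort(catalog=catalog, phenotypes=phenos, findings=[])
    table = build_weight_table(cohort)
    assert table["speech_delay"].weight == 10  # 184/189 = 97.4%
    assert table["growth_lt_3"].weight == 1  # 23/188 = 12.2%
    for fid, entry in table.items():
        assert entry.weight == weight_for_frequency(entry.frequency)


def test_all_missing_feature_names_offender():
    catalog = [make_feature("hypotonia"), make_feature("ghost")]
    phenos = [
        PatientPhenotype("P1", "unknown", None, None, {"hypotonia": "present", "ghost": "missing"})
        for _ in range(1)
    ]
    cohort = Cohort(catalog=catalog, phenotypes=phenos, findings=[])
    with pytest.raises(UndefinedFrequencyError, match="ghost"):
        build_weight_table(cohort)


@pytest.fixture
def scoring_cohort():
    catalog = [
        make_feature("hypotonia"),
        make_feature("seizures"),
        make_feature("sphincter_control", polarity="protective"),
    ]
    # frequencies force weights 10 / 2 / 2
    phenos = []
    for i in range(100):
        phenos.append(
            PatientPhenotype(
                f"P{i}", "unknown", None, None,
                {
                    "hypotonia": "present" if i < 76 else "absent",
                    "seizures": "present" if i < 31 else "absent",
                    "sphincter_control": "present" if i < 30 else "absent",
                },
            )
        )
    return Cohort(catalog=catalog, phenotypes=phenos, findings=[])


def test_gfap_score_sums_adverse_present_and_protective_absent(scoring_cohort):
    weights = build_weight_table(scoring_cohort)
    assert {weights[f].weight for f in weights} == {10, 2}
    patient = PatientPhenotype(
        "X", "unknown", None, None,
        {"hypotonia": "present", "seizures": "present", "sphincter_control": "present"},
    )
    res = gfap_score(patient, weights, scoring_cohort)
    assert res.score == 12  # 10 + 2, protective item present adds nothing
    best = PatientPhenotype(
        "Y", "unknown", None, None,
        {"hypotonia": "absent", "seizures": "absent", "sphincter_control": "present"},
    )
    assert gfap_score(best, weights, scoring_cohort).score == 0


def test_all_missing_patient_flagged(scoring_cohort):
    weights = build_weight_table(scoring_cohort)
    ghost = PatientPhenotype("Z", "unknown", None, None, {})
    res = gfap_score(ghost, weights, scoring_cohort)
    assert (res.score, res.n_scored, res.all_missing) == (0, 0, True)


def test_switching_adverse_to_present_never_decreases_score(scoring_cohort):
    weights = build_weight_table(scoring_cohort)
    base = PatientPhenotype(
        "A", "unknown", None, None,
        {"hypotonia": "absent", "seizures": "absent", "sphincter_control": "absent"},
    )
    s0 = gfap_score(base, weights, scoring_cohort).score
    for fid in ("hypotonia", "seizures"):
        items = dict(base.items)
        items[fid] = "present"
        flipped = PatientPhenotype("B", "unknown", None, None, items)
        assert gfap_score(flipped, weights, scoring_cohort).score >= s0


def test_normalized_score_bounded(scoring_cohort):
    weights = build_weight_table(scoring_cohort)
    worst = PatientPhenotype(
        "W", "unknown", None, None,
        {"hypotonia": "present", "seizures": "present", "sphincter_control": "absent"},
    )
    res = gfap_score(worst, weights, scoring_cohort, normalize=True)
    assert res.score == pytest.approx(1.0)


# -- construct validation ----------------------------------------------------

def random_binary_cohort(n=200, p=5, seed=42):
    rng = np.random.default_rng(seed)
    catalog = [make_feature(f"f{j}") for j in range(p)]
    X = rng.random((n, p)) < rng.uniform(0.3, 0.7, size=p)
    phenos = [
        PatientPhenotype(
            f"P{i}", "unknown", None, None,
            {f"f{j}": "present" if X[i, j] else "absent" for j in range(p)},
        )
        for i in range(n)
    ]
    return Cohort(catalog=catalog, phenotypes=phenos, findings=[]), X.astype(float)


def test_identity_correlation_gives_zero_bartlett():
    # orthogonal design: f0/f1/f2 uncorrelated by construction
    catalog = [make_feature(f"f{j}") for j in range(3)]
    phenos = []
    for i in range(48):
        bits = [(i >> j) & 1 for j in range(3)]
        phenos.append(
            PatientPhenotype(
                f"P{i}", "unknown", None, None,
                {f"f{j}": "present" if bits[j] else "absent" for j in range(3)},
            )
        )
    cohort = Cohort(catalog=catalog, phenotypes=phenos, findings=[])
    val = validate_construct(cohort)
    assert val.bartlett_chi2 == pytest.approx(0.0, abs=1e-8)
    assert val.bartlett_p == pytest.approx(1.0)
    assert val.bartlett_df == 3


def test_two_feature_kmo_is_half():
    cohort, _ = random_binary_cohort(n=100, p=2, seed=1)
    val = validate_construct(cohort)
    assert val.kmo_overall == pytest.approx(0.5)


def test_bartlett_and_kmo_match_direct_formula_oracle():
    """Independent oracle: partial correlations via explicit OLS residuals,
    Bartlett via the raw determinant formula on numpy's own corrcoef."""
    cohort, X = random_binary_cohort(n=200, p=5, seed=7)
    val = validate_construct(cohort)
    n, p = X.shape
    R = np.corrcoef(X, rowvar=False)
    chi2_oracle = -(n - 1 - (2 * p + 5) / 6.0) * np.log(np.linalg.det(R))
    assert val.bartlett_chi2 == pytest.approx(chi2_oracle, rel=1e-10)
    assert val.bartlett_df == p * (p - 1) // 2

    # partial corr of (i, j) given the rest, via regression residuals
    def partial(i, j):
        others = [k for k in range(p) if k not in (i, j)]
        Z = np.column_stack([X[:, others], np.ones(n)])
        ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
        rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
        return np.corrcoef(ri, rj)[0, 1]

    num = den = 0.0
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            num += R[i, j] ** 2
            den += partial(i, j) ** 2
    kmo_oracle = num / (num + den)
    assert val.kmo_overall == pytest.approx(kmo_oracle, rel=1e-8)


def test_kmo_invariant_under_feature_reordering():
    cohort, _ = random_binary_cohort(n=150, p=4, seed=9)
    fids = [f.feature_id for f in cohort.catalog]
    a = validate_construct(cohort, fids)
    b = validate_construct(cohort, fids[::-1])
    assert a.kmo_overall == pytest.approx(b.kmo_overall)


def test_variance_explained_nonincreasing():
    cohort, _ = random_binary_cohort(n=200, p=6, seed=3)
    val = validate_construct(cohort)
    ve = val.variance_explained
    assert (np.diff(ve) <= 1e-12).all()
    assert ve.sum() == pytest.approx(1.0)


def test_singular_matrix_suggests_pruning():
    catalog = [make_feature("a"), make_feature("b")]
    phenos = [
        PatientPhenotype(f"P{i}", "unknown", None, None,
                         {"a": s, "b": s})  # perfectly collinear
        for i, s in enumerate(["present", "absent"] * 10)
    ]
    cohort = Cohort(catalog=catalog, phenotypes=phenos, findings=[])
    with pytest.raises(ValueError, match="prune"):
        validate_construct(cohort)
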