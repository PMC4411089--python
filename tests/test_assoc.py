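"""Contingency statistics, IRLS logistic regression, haplotype ORs, ROC."""

import math

import numpy as np
import pytest

from celiacrisk.assoc import (
    SeparationError,
    auc_rank,
    bonferroni,
    chi_square,
    crude_or,
    fit_logistic,
    haplotype_or,
    roc_compare,
    snp_association,
)
from celiacrisk.em import HaplotypeFreqTable
from celiacrisk.loci import DEFAULT_PANEL, LocusDef, panel_by_id
from celiacrisk.tables import ContingencyTable

from conftest import subject_with_haps, subjects_from_genotype_table


# --- chi-square -------------------------------------------------------------

def test_sex_chi_square_matches_published_value(printed):
    stat, df, p = chi_square(printed["sex_by_status"])
    assert round(stat, 2) == 10.17
    assert df == 1
    assert p == pytest.approx(0.001, abs=5e-4)


def test_chi_square_null_table_and_permutation_invariance(printed):
    tab = ContingencyTable(("r1", "r2"), ("c1", "c2"), [[30, 70], [15, 35]])
    stat, _, p = chi_square(tab)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    t = printed["sex_by_status"]
    permuted = ContingencyTable(
        t.row_labels[::-1], t.col_labels[::-1], t.counts[::-1, ::-1]
    )
    assert chi_square(t)[0] == pytest.approx(chi_square(permuted)[0], abs=1e-12)


def test_chi_square_2x3_hand_summed():
    counts = np.array([[10, 20, 30], [30, 20, 10]])
    tab = ContingencyTable(("a", "b"), ("x", "y", "z"), counts)
    # direct arithmetic: expected = 20 everywhere
    expected = 20.0
    by_hand = sum((o - expected) ** 2 / expected for o in counts.ravel())
    stat, df, _ = chi_square(tab)
    assert stat == pytest.approx(by_hand, abs=1e-12)
    assert df == 2


def test_chi_square_zero_expected_cell_errors():
    tab = ContingencyTable(("a", "b"), ("x", "y"), [[0, 5], [0, 7]])
    with pytest.raises(ValueError, match="exact"):
        chi_square(tab)


# --- crude odds ratio -------------------------------------------------------

def test_atrophy_crude_or(printed):
    res = crude_or(printed["atrophy_by_hla"])
    assert res.or_est == pytest.approx(1.6, abs=5e-3)
    # the Woolf interval, like the published one, straddles 1 (not significant)
    assert res.ci_low < 1.0 < res.ci_high
    assert res.p > 0.05


def test_crude_or_symmetric_and_haldane():
    sym = ContingencyTable(("e", "u"), ("case", "control"), [[10, 10], [10, 10]])
    res = crude_or(sym)
    assert res.or_est == 1.0
    assert res.ci_low < 1.0 < res.ci_high
    zero = ContingencyTable(("e", "u"), ("case", "control"), [[5, 0], [5, 5]])
    assert crude_or(zero, "haldane").or_est == pytest.approx(11.0)
    with pytest.raises(ValueError):
        crude_or(zero, "error")


# --- logistic regression ----------------------------------------------------

def test_logistic_single_binary_predictor_reproduces_crude_or(printed):
    a, b = printed["atrophy_by_hla"].counts[0]
    c, d = printed["atrophy_by_hla"].counts[1]
    y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    x = np.array([1.0] * (a + b) + [0.0] * (c + d))
    fit = fit_logistic(y, np.column_stack([np.ones_like(x), x]), terms=("int", "x"))
    res = fit.term_result("x")
    crude = crude_or(printed["atrophy_by_hla"])
    assert res.or_est == pytest.approx(crude.or_est, abs=1e-6)
    assert res.ci_low == pytest.approx(crude.ci_low, abs=1e-6)
    assert res.ci_high == pytest.approx(crude.ci_high, abs=1e-6)


def test_logistic_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(17)
    n = 400
    X = np.column_stack(
        [np.ones(n), rng.normal(size=n), rng.binomial(1, 0.4, n), rng.normal(2, 1, n)]
    )
    beta_true = np.array([-0.5, 0.8, -1.0, 0.3])
    p = 1 / (1 + np.exp(-(X @ beta_true)))
    y = rng.random(n) < p
    fit = fit_logistic(y.astype(float), X)
    ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)
    assert fit.loglik == pytest.approx(ref.llf, abs=1e-6)


def test_logistic_fractional_weights_match_expanded_rows():
    # an integer row weight equals duplicating the row
    X = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
    y = np.array([0.0, 1.0, 1.0, 0.0])
    w = np.array([3.0, 1.0, 2.0, 1.0])
    fit_w = fit_logistic(y, X, weights=w)
    X2 = np.repeat(X, w.astype(int), axis=0)
    y2 = np.repeat(y, w.astype(int))
    fit_e = fit_logistic(y2, X2)
    np.testing.assert_allclose(fit_w.coef, fit_e.coef, atol=1e-8)
    np.testing.assert_allclose(fit_w.se, fit_e.se, atol=1e-8)


def test_logistic_degenerate_outcome_and_separation():
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    with pytest.raises(SeparationError):
        fit_logistic(np.zeros(10), X)
    y = (np.arange(10.0) >= 5).astype(float)  # perfectly separated
    with pytest.raises(SeparationError):
        fit_logistic(y, X)


def test_logistic_rank_deficiency_names_columns():
    X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
    y = np.tile([0.0, 1.0], 10)
    with pytest.raises(np.linalg.LinAlgError, match="x2"):
        fit_logistic(y, X)


# --- SNP association --------------------------------------------------------

def test_snp_308_dominant_crude_or(printed):
    subjects = subjects_from_genotype_table(
        "TNFA_-308", printed["genotype_by_status"]["TNFA_-308"]
    )
    locus = panel_by_id(DEFAULT_PANEL)["TNFA_-308"]
    res = snp_association(subjects, locus, "dominant")
    # carriers 137/107 cases vs 61/206 controls -> ad/bc
    assert res.or_est == pytest.approx((137 * 206) / (107 * 61), rel=1e-6)
    assert round(res.or_est, 2) == 4.32
    tab = ContingencyTable(
        ("carrier", "noncarrier"), ("case", "control"), [[137, 61], [107, 206]]
    )
    assert res.or_est == pytest.approx(crude_or(tab).or_est, abs=1e-6)


def test_recessive_with_no_minor_homozygotes_errors(printed):
    table = printed["genotype_by_status"]["TNFA_-376"]
    controls_only = subjects_from_genotype_table(
        "TNFA_-376", table, statuses=("control",)
    )
    # give half of them case status so the outcome is not constant
    for i, s in enumerate(controls_only):
        if i % 2 == 0:
            s.status = "case"
    locus = panel_by_id(DEFAULT_PANEL)["TNFA_-376"]
    with pytest.raises(ValueError, match="constant"):
        snp_association(controls_only, locus, "recessive")


def test_adjusted_or_with_null_covariate_close_to_crude(printed):
    rng = np.random.default_rng(3)
    subjects = subjects_from_genotype_table(
        "TNFA_-308", printed["genotype_by_status"]["TNFA_-308"]
    )
    for s in subjects:  # covariate independent of everything
        s.age = float(rng.uniform(1, 18))
    locus = panel_by_id(DEFAULT_PANEL)["TNFA_-308"]
    crude = snp_association(subjects, locus, "dominant")
    adjusted = snp_association(subjects, locus, "dominant", covariates=("age",))
    assert adjusted.or_est == pytest.approx(crude.or_est, rel=0.1)


# --- haplotype ORs ----------------------------------------------------------

def test_haplotype_or_unambiguous_equals_hard_count_or():
    L1 = LocusDef("L1", "rs1", "A", "a")
    L2 = LocusDef("L2", "rs2", "B", "b")
    panel = (L1, L2)
    # all homozygotes: carriage is certain
    subjects = (
        [subject_with_haps(f"c{i}", "case", ("AB", "AB"), panel) for i in range(30)]
        + [subject_with_haps(f"d{i}", "case", ("ab", "ab"), panel) for i in range(20)]
        + [subject_with_haps(f"e{i}", "control", ("AB", "AB"), panel) for i in range(40)]
        + [subject_with_haps(f"f{i}", "control", ("ab", "ab"), panel) for i in range(10)]
    )
    table = HaplotypeFreqTable(
        panel=("L1", "L2"),
        haplotypes=("AB", "ab"),
        freqs=np.array([0.7, 0.3]),
        loglik=0.0,
        n_iter=1,
        converged=True,
        n_used=100,
    )
    results = haplotype_or(subjects, table, panel)
    by_term = {r.term: r for r in results}
    assert by_term["hap_AB"].or_est == 1.0  # reference = most frequent
    expected = (20 * 40) / (30 * 10)  # ad/bc of ab-carriage vs AB-carriage
    assert by_term["hap_ab"].or_est == pytest.approx(expected, rel=1e-4)


def test_haplotype_or_reference_validation():
    table = HaplotypeFreqTable(
        panel=("L1",),
        haplotypes=("A", "a"),
        freqs=np.array([0.5, 0.5]),
        loglik=0.0,
        n_iter=1,
        converged=True,
        n_used=2,
    )
    with pytest.raises(ValueError, match="reference"):
        haplotype_or([], table, (LocusDef("L1", "rs1", "A", "a"),), reference="zz")


# --- Bonferroni -------------------------------------------------------------

def test_bonferroni_published_pairs():
    assert bonferroni([0.003], m=10) == [pytest.approx(0.030)]
    assert bonferroni([0.049], m=10) == [pytest.approx(0.490)]


def test_bonferroni_cap_monotone_idempotent():
    assert bonferroni([0.2], m=10) == [1.0]
    ps = [0.001, 0.02, 0.5]
    adj = bonferroni(ps, m=5)
    assert adj == sorted(adj)  # monotone in p
    assert bonferroni([0.25], m=1) == [0.25]  # identity at m=1
    with pytest.raises(ValueError):
        bonferroni([0.1, 0.2], m=1)
    with pytest.raises(ValueError):
        bonferroni([0.1], m=0)


# --- ROC / DeLong -----------------------------------------------------------

def _model_from_scores(y, scores):
    from celiacrisk.assoc import LogisticModel

    return LogisticModel(
        terms=("s",),
        coef=np.array([1.0]),
        se=np.array([1.0]),
        cov=np.eye(1),
        loglik=0.0,
        n_used=len(y),
        converged=True,
        fitted=np.asarray(scores, dtype=float),
        outcome=np.asarray(y, dtype=float),
    )


def test_roc_self_comparison_is_null():
    y = np.array([1.0] * 10 + [0.0] * 10)
    scores = np.linspace(0, 1, 20)[::-1]
    m = _model_from_scores(y, scores)
    auc_a, auc_b, p = roc_compare(m, m)
    assert auc_a == auc_b
    assert p == 1.0


def test_perfect_separation_auc():
    y = np.array([1.0] * 5 + [0.0] * 5)
    scores = np.array([0.9] * 5 + [0.1] * 5)
    assert auc_rank(y, scores) == 1.0


def test_delong_matches_pROC_reference():
    """Frozen oracle: pROC roc.test(method='delong', paired=TRUE)."""
    rng = np.random.default_rng(42)
    n = 40
    y = np.array([1.0] * 20 + [0.0] * 20)
    a = y * 0.8 + rng.normal(0, 1, n)
    b = y * 0.4 + rng.normal(0, 1, n)
    ma = _model_from_scores(y, a)
    mb = _model_from_scores(y, b)
    auc_a, auc_b, p = roc_compare(ma, mb)
    assert auc_a == pytest.approx(0.7350000000, abs=1e-9)
    assert auc_b == pytest.approx(0.7100000000, abs=1e-9)
    assert p == pytest.approx(0.8419069437, abs=1e-8)
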