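"""Case-control association statistics.

Covers the study's statistical toolkit: Pearson chi-square on contingency
tables, crude 2x2 odds ratios with Woolf confidence intervals, binary
logistic regression fitted by iteratively reweighted least squares (with
optional fractional row weights, which posterior-weighted haplotype
regression needs), dominant/recessive SNP codings, haplotype carriage odds
ratios, Bonferroni adjustment, and DeLong's paired comparison of ROC areas.

The haplotype odds ratios approximate a retrospective profile-likelihood
fit by prospective logistic regression on posterior expected carriage: under
case-control sampling the carriage log-odds-ratio is consistently estimated
with the intercept absorbing the sampling fractions, so estimates are
expected to track (not exactly equal) a true retrospective fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .cohort import SubjectRecord
from .em import HaplotypeFreqTable, diplotype_posteriors
from .loci import LocusDef
from .tables import ContingencyTable

__all__ = [
    "AssociationResult",
    "LogisticModel",
    "SeparationError",
    "chi_square",
    "crude_or",
    "fit_logistic",
    "snp_association",
    "haplotype_or",
    "bonferroni",
    "roc_compare",
    "auc_rank",
    "covariate_design",
    "COVARIATE_PROFILE",
]

#: The study's default adjustment set.
COVARIATE_PROFILE: Tuple[str, ...] = ("age", "sex", "hpylori")

Z95 = norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Perfect separation (or a degenerate outcome): no finite MLE exists."""


@dataclass(frozen=True)
class AssociationResult:
    term: str
    or_est: float
    ci_low: float
    ci_high: float
    p: float
    model: str
    p_adj: Optional[float] = None
    covariates: Tuple[str, ...] = ()
    n_used: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_est <= self.ci_high):
            raise ValueError("CI must bracket the OR estimate")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("p-value out of range")
        if self.p_adj is not None and self.p_adj < self.p - 1e-12:
            raise ValueError("adjusted p cannot be smaller than raw p")


@dataclass(frozen=True)
class LogisticModel:
    terms: Tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    n_used: int
    converged: bool
    fitted: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, dtype=float) @ self.coef
        return 1.0 / (1.0 + np.exp(-eta))

    def term_result(self, term: str, model: str = "logistic") -> AssociationResult:
        i = self.terms.index(term)
        beta = self.coef[i]
        se = self.se[i]
        z = beta / se
        p = 2.0 * norm.sf(abs(z))
        return AssociationResult(
            term=term,
            or_est=math.exp(beta),
            ci_low=math.exp(beta - Z95 * se),
            ci_high=math.exp(beta + Z95 * se),
            p=float(p),
            model=model,
            n_used=self.n_used,
        )


def chi_square(
    table: ContingencyTable, correction: str = "none"
) -> Tuple[float, int, float]:
    """Pearson chi-square test of independence; df = (r-1)(c-1)."""
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    counts = table.counts.astype(float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    expected = row @ col / counts.sum()
    if (expected <= 0).any():
        raise ValueError(
            "zero expected cell count: the chi-square approximation is "
            "invalid, use an exact test"
        )
    diff = np.abs(counts - expected)
    if correction == "yates":
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, df, float(chi2_dist.sf(stat, df))


def crude_or(table: ContingencyTable, zero_cell: str = "haldane") -> AssociationResult:
    """Crude odds ratio ad/bc from a 2x2 table with a Woolf 95% CI."""
    if table.counts.shape != (2, 2):
        raise ValueError("crude_or requires a 2x2 table")
    if zero_cell not in ("haldane", "error"):
        raise ValueError(f"unknown zero-cell policy {zero_cell!r}")
    a, b = (float(x) for x in table.counts[0])
    c, d = (float(x) for x in table.counts[1])
    if min(a, b, c, d) == 0.0:
        if zero_cell == "error":
            raise ValueError("zero cell in 2x2 table")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_est)
    p = 2.0 * norm.sf(abs(log_or) / se)
    return AssociationResult(
        term="exposure",
        or_est=or_est,
        ci_low=math.exp(log_or - Z95 * se),
        ci_high=math.exp(log_or + Z95 * se),
        p=float(p),
        model="crude",
        n_used=int(table.total),
    )


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns from the QR decomposition
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [terms[i] for i in np.flatnonzero(diag < 1e-8 * max(diag.max(), 1.0))]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad or 'unidentified'}"
        )


def fit_logistic(
    outcome: Sequence[float],
    design: np.ndarray,
    terms: Optional[Sequence[str]] = None,
    weights: Optional[Sequence[float]] = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticModel:
    """Binary logistic regression by iteratively reweighted least squares.

    ``design`` must include the intercept column.  ``weights`` are optional
    fractional row weights.  Standard errors come from the inverse observed
    information; ``converged`` is False when the iteration limit is hit or
    the coefficients diverge (separation).
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design matrix does not match outcome length")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if terms is None:
        terms = tuple(f"x{i}" for i in range(X.shape[1]))
    terms = tuple(terms)
    if len(terms) != X.shape[1]:
        raise ValueError("terms must match design columns")

    y_mean = float(np.average(y, weights=w))
    if y_mean in (0.0, 1.0):
        raise SeparationError("outcome is constant; no finite estimates exist")
    _check_rank(X, terms)

    beta = np.zeros(X.shape[1])
    beta[0] = math.log(y_mean / (1 - y_mean))  # intercept warm start
    converged = False
    diverged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        irls_w = w * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        XtW = X.T * irls_w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            diverged = True
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if np.max(np.abs(beta)) > 30.0:
            diverged = True
            break
        if step < tol:
            converged = True
            break

    if diverged:
        raise SeparationError(
            "coefficients diverged during IRLS: data are (quasi-)separated"
        )

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    info = (X.T * (w * mu * (1 - mu))) @ X
    cov = np.linalg.inv(info)
    cov = (cov + cov.T) / 2.0
    loglik = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
    return LogisticModel(
        terms=terms,
        coef=beta,
        se=np.sqrt(np.diag(cov)),
        cov=cov,
        loglik=loglik,
        n_used=int(y.shape[0]),
        converged=converged,
        fitted=mu,
        outcome=y,
    )


def covariate_design(
    subjects: Sequence[SubjectRecord], covariates: Sequence[str]
) -> Tuple[np.ndarray, List[str], np.ndarray]:
    """Covariate columns + complete-case mask over the requested profile.

    Supported covariates: ``age`` (years), ``sex`` (indicator of F) and
    ``hpylori`` (indicator of infection).  Returns (matrix, names, mask);
    rows failing completeness are masked out, never imputed.
    """
    cols: List[np.ndarray] = []
    names: List[str] = []
    mask = np.ones(len(subjects), dtype=bool)
    for cov in covariates:
        if cov == "age":
            vals = np.array(
                [s.age if s.age is not None else np.nan for s in subjects]
            )
            mask &= ~np.isnan(vals)
            cols.append(vals)
            names.append("age")
        elif cov == "sex":
            cols.append(np.array([1.0 if s.sex == "F" else 0.0 for s in subjects]))
            names.append("sex_F")
        elif cov == "hpylori":
            vals = np.array(
                [
                    1.0 if s.hpylori == "yes" else 0.0 if s.hpylori == "no" else np.nan
                    for s in subjects
                ]
            )
            mask &= ~np.isnan(vals)
            cols.append(vals)
            names.append("hpylori")
        else:
            raise ValueError(f"unknown covariate {cov!r}")
    mat = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    return mat, names, mask


def snp_association(
    subjects: Sequence[SubjectRecord],
    locus: LocusDef,
    model: str = "dominant",
    covariates: Sequence[str] = (),
) -> AssociationResult:
    """Dominant or recessive minor-allele association with CD status.

    Dominant codes carriage of >= 1 minor allele; recessive codes
    minor-allele homozygosity.  With covariates, the odds ratio is the
    adjusted logistic coefficient for the genotype term.
    """
    if model not in ("dominant", "recessive"):
        raise ValueError(f"unknown genetic model {model!r}")
    dose = np.array(
        [
            s.genotype(locus.locus_id).minor_count(locus)
            if not s.genotype(locus.locus_id).is_missing
            else np.nan
            for s in subjects
        ],
        dtype=float,
    )
    cov_mat, cov_names, cov_mask = covariate_design(subjects, covariates)
    mask = ~np.isnan(dose) & cov_mask
    if mask.sum() == 0:
        raise ValueError(f"{locus.locus_id}: no complete-case subjects")
    threshold = 1 if model == "dominant" else 2
    x = (dose[mask] >= threshold).astype(float)
    if x.min() == x.max():
        raise ValueError(
            f"{locus.locus_id}: {model} coding is constant in the sample "
            f"(all {int(x[0])})"
        )
    y = np.array([1.0 if s.is_case else 0.0 for s in subjects])[mask]
    X = np.column_stack([np.ones(x.shape[0]), x, cov_mat[mask]])
    terms = ["intercept", f"{locus.locus_id}_{model}"] + cov_names
    fit = fit_logistic(y, X, terms=terms)
    res = fit.term_result(terms[1], model=model)
    return AssociationResult(
        term=res.term,
        or_est=res.or_est,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        p=res.p,
        model=model if not covariates else f"{model}+adjusted",
        covariates=tuple(covariates),
        n_used=int(mask.sum()),
    )


def haplotype_or(
    subjects: Sequence[SubjectRecord],
    freq_table: HaplotypeFreqTable,
    panel: Sequence[LocusDef],
    reference: Optional[str] = None,
    covariates: Sequence[str] = (),
    min_freq: float = 1e-5,
) -> List[AssociationResult]:
    """Dominant (carriage) odds ratio per haplotype versus a reference.

    Each subject contributes their posterior probability of carrying at
    least one copy of each haplotype; a single logistic model regresses
    status on all non-reference carriage exposures (plus covariates), so
    the baseline is carriage of the reference haplotype alone.  The
    reference defaults to the most frequent haplotype and is reported with
    OR 1 by construction.
    """
    reported = [h for h, f in freq_table.as_dict().items() if f >= min_freq]
    if not reported:
        raise ValueError("no haplotypes above the reporting floor")
    if reference is None:
        reference = max(reported, key=freq_table.freq)
    elif reference not in freq_table.haplotypes:
        raise ValueError(f"reference haplotype {reference!r} not in frequency table")

    others = [h for h in reported if h != reference]
    cov_mat, cov_names, cov_mask = covariate_design(subjects, covariates)

    rows: List[np.ndarray] = []
    y: List[float] = []
    cov_rows: List[np.ndarray] = []
    n_used = 0
    for i, s in enumerate(subjects):
        if not cov_mask[i]:
            continue
        try:
            post = diplotype_posteriors(s, freq_table, panel)
        except ValueError:
            continue
        carriage = np.zeros(len(others))
        for pair, prob in zip(post.pairs, post.posteriors):
            for j, h in enumerate(others):
                if h in pair:
                    carriage[j] += prob
        rows.append(carriage)
        cov_rows.append(cov_mat[i])
        y.append(1.0 if s.is_case else 0.0)
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable subjects for haplotype regression")

    X = np.column_stack(
        [np.ones(n_used), np.array(rows)]
        + ([np.array(cov_rows)] if cov_names else [])
    )
    terms = ["intercept"] + [f"hap_{h}" for h in others] + cov_names
    fit = fit_logistic(np.array(y), X, terms=terms)

    results = [
        AssociationResult(
            term=f"hap_{reference}",
            or_est=1.0,
            ci_low=1.0,
            ci_high=1.0,
            p=1.0,
            model="haplotype",
            covariates=tuple(covariates),
            n_used=n_used,
        )
    ]
    for h in others:
        res = fit.term_result(f"hap_{h}", model="haplotype")
        results.append(
            AssociationResult(
                term=res.term,
                or_est=res.or_est,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                p=res.p,
                model="haplotype",
                covariates=tuple(covariates),
                n_used=n_used,
            )
        )
    return results


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> List[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < 1:
        raise ValueError("multiplicity m must be >= 1")
    if m < len(p_values):
        raise ValueError("multiplicity m must cover the number of tests")
    return [min(1.0, m * p) for p in p_values]


def auc_rank(y: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic."""
    y = np.asarray(y, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC needs both outcome classes")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def _placements(y: np.ndarray, scores: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    pos = scores[y == 1]
    neg = scores[y == 0]
    v_pos = ((pos[:, None] > neg[None, :]).sum(axis=1) + 0.5 * (pos[:, None] == neg[None, :]).sum(axis=1)) / len(neg)
    v_neg = ((pos[:, None] > neg[None, :]).sum(axis=0) + 0.5 * (pos[:, None] == neg[None, :]).sum(axis=0)) / len(pos)
    return v_pos, v_neg


def roc_compare(
    model_a: LogisticModel, model_b: LogisticModel
) -> Tuple[float, float, float]:
    """DeLong's paired comparison of two models' ROC areas.

    Both models must have been fitted on the same subjects in the same
    order (paired design).  Returns (auc_a, auc_b, two-sided p).
    """
    if model_a.n_used != model_b.n_used or not np.array_equal(
        model_a.outcome, model_b.outcome
    ):
        raise ValueError("roc_compare requires models fitted on the same subjects")
    y = model_a.outcome
    if y.min() == y.max():
        raise ValueError("outcome is constant")

    auc_a = auc_rank(y, model_a.fitted)
    auc_b = auc_rank(y, model_b.fitted)
    va_pos, va_neg = _placements(y, model_a.fitted)
    vb_pos, vb_neg = _placements(y, model_b.fitted)
    m, n = len(va_pos), len(va_neg)

    s_pos = np.cov(np.vstack([va_pos, vb_pos]))
    s_neg = np.cov(np.vstack([va_neg, vb_neg]))
    var = (
        (s_pos[0, 0] + s_pos[1, 1] - 2 * s_pos[0, 1]) / m
        + (s_neg[0, 0] + s_neg[1, 1] - 2 * s_neg[0, 1]) / n
    )
    delta = auc_a - auc_b
    if var <= 0:
        p = 1.0 if abs(delta) < 1e-12 else 0.0
    else:
        z = delta / math.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return auc_a, auc_b, p
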