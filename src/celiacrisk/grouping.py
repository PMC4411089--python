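"""TNFA haplotype combinations, A-E risk groups and the joint HLA model.

Each subject's assigned diplotype (an unordered pair of promoter haplotypes,
written with the short H-codes, e.g. ``H1/H5``) is tallied against
case/control status.  Combinations are banded by their CD fraction into
groups A (<10% of carriers are CD) through E (>80%).  Groups learned from
the analysis cohort itself are circular for inference; a frozen
combination-to-group map can be supplied to apply reference definitions to
new subjects.

The joint model is a logistic regression of CD status on HLA risk tier
(negative / intermediate / high) and TNFA group (A reference), optionally
adjusted for the study covariates, with Bonferroni-corrected p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assoc import (
    AssociationResult,
    LogisticModel,
    bonferroni,
    covariate_design,
    fit_logistic,
)
from .cohort import SubjectRecord
from .hla import RiskTier
from .loci import HAPLOTYPE_CODES

__all__ = [
    "ComboGroupTable",
    "MarginalProbability",
    "GROUP_LABELS",
    "DEFAULT_BANDS",
    "combo_key",
    "assign_group",
    "combo_table",
    "joint_model",
    "marginal_probabilities",
    "atrophy_trend",
]

logger = logging.getLogger(__name__)

GROUP_LABELS = ("A", "B", "C", "D", "E")
#: Lower-closed band edges on the CD fraction: A [0,.1) B [.1,.4) C [.4,.6)
#: D [.6,.8) E [.8,1].
DEFAULT_BANDS: Tuple[float, ...] = (0.10, 0.40, 0.60, 0.80)

MARSH_SCORE = {"none": 0, "1": 1, "2": 2, "3a": 3, "3b": 4, "3c": 5}


def combo_key(
    pair: Tuple[str, str], code_map: Mapping[str, str] = HAPLOTYPE_CODES
) -> str:
    """Canonical combination label for an unordered haplotype pair, e.g. H1/H5."""
    codes = sorted(
        (code_map.get(h, h) for h in pair),
        key=lambda c: (len(c), c),
    )
    return "/".join(codes)


def assign_group(cd_fraction: float, bands: Sequence[float] = DEFAULT_BANDS) -> str:
    """Band a combination's CD fraction into groups A-E (lower-closed bands)."""
    if not (0.0 <= cd_fraction <= 1.0):
        raise ValueError(f"CD fraction {cd_fraction} outside [0, 1]")
    if len(bands) != 4 or list(bands) != sorted(bands):
        raise ValueError("bands must be 4 increasing cut points")
    for label, edge in zip(GROUP_LABELS, bands):
        if cd_fraction < edge:
            return label
    return GROUP_LABELS[-1]


@dataclass(frozen=True)
class ComboGroupTable:
    """Per-combination counts, CD fractions and group assignments."""

    df: pd.DataFrame  # columns: combination, n_cd, n_ctrl, cd_fraction, group
    n_unassigned: int
    bands: Tuple[float, ...]

    def group_of(self, combination: str) -> str:
        row = self.df.loc[self.df["combination"] == combination]
        if row.empty:
            raise KeyError(f"combination {combination!r} not observed")
        return str(row["group"].iloc[0])

    def as_map(self) -> Dict[str, str]:
        return dict(zip(self.df["combination"], self.df["group"]))


def combo_table(
    assignments: Sequence[Tuple[str, str, Optional[Tuple[str, str]]]],
    bands: Sequence[float] = DEFAULT_BANDS,
    code_map: Mapping[str, str] = HAPLOTYPE_CODES,
    frozen_groups: Optional[Mapping[str, str]] = None,
) -> ComboGroupTable:
    """Tally assigned diplotypes by status and band them into groups.

    ``assignments`` holds (subject_id, status, pair-or-None); subjects with
    no assigned diplotype are excluded and counted.  When ``frozen_groups``
    is given, group labels come from that reference map instead of the
    cohort's own CD fractions.
    """
    counts: Dict[str, List[int]] = {}
    n_unassigned = 0
    for subject_id, status, pair in assignments:
        if pair is None:
            n_unassigned += 1
            continue
        key = combo_key(pair, code_map)
        cell = counts.setdefault(key, [0, 0])
        cell[0 if status == "case" else 1] += 1
    if n_unassigned:
        logger.info("combo_table: %d subjects had no assigned diplotype", n_unassigned)

    rows = []
    for key in sorted(counts):
        n_cd, n_ctrl = counts[key]
        frac = n_cd / (n_cd + n_ctrl)
        if frozen_groups is not None:
            if key not in frozen_groups:
                raise KeyError(f"combination {key!r} missing from frozen group map")
            group = frozen_groups[key]
        else:
            group = assign_group(frac, bands)
        rows.append(
            {
                "combination": key,
                "n_cd": n_cd,
                "n_ctrl": n_ctrl,
                "cd_fraction": frac,
                "group": group,
            }
        )
    df = pd.DataFrame(
        rows, columns=["combination", "n_cd", "n_ctrl", "cd_fraction", "group"]
    )
    return ComboGroupTable(df=df, n_unassigned=n_unassigned, bands=tuple(bands))


def _tier_group_design(
    tiers: Sequence[RiskTier], groups: Sequence[str]
) -> Tuple[np.ndarray, List[str]]:
    cols: List[np.ndarray] = []
    names: List[str] = []
    tier_arr = np.array([t.name for t in tiers])
    for level in ("INTERMEDIATE", "HIGH"):
        cols.append((tier_arr == level).astype(float))
        names.append(f"tier_{level}")
    group_arr = np.array(groups)
    for level in GROUP_LABELS[1:]:
        col = (group_arr == level).astype(float)
        if col.any():
            cols.append(col)
            names.append(f"group_{level}")
    return np.column_stack(cols), names


def joint_model(
    subjects: Sequence[SubjectRecord],
    tiers: Sequence[RiskTier],
    groups: Sequence[str],
    covariates: Sequence[str] = (),
    multiplicity: int = 10,
) -> Tuple[LogisticModel, List[AssociationResult]]:
    """Joint HLA-tier + TNFA-group logistic model of CD status.

    Reference levels are tier NEG and group A; both must be populated.
    Returns the fitted model and per-level odds ratios with
    Bonferroni-adjusted p-values (default multiplicity 10).
    """
    if len(subjects) != len(tiers) or len(subjects) != len(groups):
        raise ValueError("subjects, tiers and groups must align")
    tier_arr = np.array([t.name for t in tiers])
    group_arr = np.array(groups)
    if (tier_arr == "NEG").sum() == 0:
        raise ValueError(
            "no subjects in the reference HLA tier (NEG); merge levels before fitting"
        )
    if (group_arr == "A").sum() == 0:
        raise ValueError(
            "no subjects in the reference TNFA group (A); merge groups before fitting"
        )

    cov_mat, cov_names, mask = covariate_design(subjects, covariates)
    idx = np.flatnonzero(mask)
    y = np.array([1.0 if subjects[i].is_case else 0.0 for i in idx])
    tg_design, tg_names = _tier_group_design(
        [tiers[i] for i in idx], [groups[i] for i in idx]
    )
    X = np.column_stack([np.ones(len(idx)), tg_design, cov_mat[idx]])
    terms = ["intercept"] + tg_names + cov_names
    fit = fit_logistic(y, X, terms=terms)

    level_terms = tg_names
    raw = [fit.term_result(t, model="category") for t in level_terms]
    adj = bonferroni([r.p for r in raw], m=max(multiplicity, len(raw)))
    results = [
        AssociationResult(
            term=r.term,
            or_est=r.or_est,
            ci_low=r.ci_low,
            ci_high=r.ci_high,
            p=r.p,
            p_adj=a,
            model="category",
            covariates=tuple(covariates),
            n_used=fit.n_used,
        )
        for r, a in zip(raw, adj)
    ]
    return fit, results


@dataclass(frozen=True)
class MarginalProbability:
    hla_tier: str
    tnfa_group: str
    probability: float
    se: float
    extrapolated: bool


def marginal_probabilities(
    model: LogisticModel,
    subjects: Sequence[SubjectRecord],
    tiers: Sequence[RiskTier],
    groups: Sequence[str],
    covariates: Sequence[str] = (),
) -> List[MarginalProbability]:
    """Model-based CD probability per (HLA tier, TNFA group) cell.

    Predictive margins: for each cell, every subject's tier/group indicators
    are set to that cell and predictions are averaged over the cohort's
    covariate distribution.  Standard errors by the delta method on the
    coefficient covariance.  Cells never observed in the data are still
    computable and flagged as extrapolated.
    """
    if not model.converged:
        raise ValueError("marginal probabilities need a converged model")
    cov_mat, cov_names, mask = covariate_design(subjects, covariates)
    idx = np.flatnonzero(mask)
    n = len(idx)
    observed = {
        (tiers[i].name, groups[i]) for i in idx
    }
    group_levels_in_model = [
        t.split("_", 1)[1] for t in model.terms if t.startswith("group_")
    ]

    out: List[MarginalProbability] = []
    for tier_level in ("NEG", "INTERMEDIATE", "HIGH"):
        for group_level in GROUP_LABELS:
            if group_level != "A" and group_level not in group_levels_in_model:
                continue
            X = np.zeros((n, len(model.terms)))
            for j, term in enumerate(model.terms):
                if term == "intercept":
                    X[:, j] = 1.0
                elif term.startswith("tier_"):
                    X[:, j] = 1.0 if term == f"tier_{tier_level}" else 0.0
                elif term.startswith("group_"):
                    X[:, j] = 1.0 if term == f"group_{group_level}" else 0.0
                else:
                    X[:, j] = cov_mat[idx, cov_names.index(term)]
            p = model.predict(X)
            margin = float(p.mean())
            grad = (p * (1 - p))[:, None] * X
            g = grad.mean(axis=0)
            var = float(g @ model.cov @ g)
            out.append(
                MarginalProbability(
                    hla_tier=tier_level,
                    tnfa_group=group_level,
                    probability=margin,
                    se=math.sqrt(max(var, 0.0)),
                    extrapolated=(tier_level, group_level) not in observed,
                )
            )
    return out


def atrophy_trend(
    cd_subjects: Sequence[SubjectRecord],
    groups: Sequence[str],
    atrophy_grades: Sequence[str] = ("3c",),
) -> AssociationResult:
    """Per-step trend of total atrophy over groups A..E within CD subjects.

    The group label is scored linearly (A=0 ... E=4) and total atrophy
    (default: Marsh 3c) is regressed on the score; the reported OR is the
    change in atrophy odds per one-group step.
    """
    if len(cd_subjects) != len(groups):
        raise ValueError("subjects and groups must align")
    score_of = {g: i for i, g in enumerate(GROUP_LABELS)}
    y: List[float] = []
    x: List[float] = []
    for s, g in zip(cd_subjects, groups):
        if not s.is_case:
            raise ValueError(f"{s.subject_id}: atrophy analysis is CD-only")
        if s.marsh is None:
            continue
        y.append(1.0 if s.marsh in atrophy_grades else 0.0)
        x.append(float(score_of[g]))
    if not y:
        raise ValueError("no CD subjects with histology")
    y_arr = np.array(y)
    x_arr = np.array(x)
    if x_arr.min() == x_arr.max():
        raise np.linalg.LinAlgError("group score is constant in this stratum")
    if y_arr.min() == y_arr.max():
        raise ValueError("no atrophy variation in this stratum")
    X = np.column_stack([np.ones_like(x_arr), x_arr])
    fit = fit_logistic(y_arr, X, terms=("intercept", "group_score"))
    res = fit.term_result("group_score", model="trend")
    return AssociationResult(
        term="group_score",
        or_est=res.or_est,
        ci_low=res.ci_low,
        ci_high=res.ci_high,
        p=res.p,
        model="trend",
        n_used=len(y),
    )
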