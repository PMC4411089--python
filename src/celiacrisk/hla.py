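"""HLA-DQ risk categories and post-test celiac disease probability.

Children are classified into eight categories from their DQA1 allele groups
(*05, *03, *0201, other) and DQB1 alleles (*02 dose 0/1/2, *0302 presence,
anything else collapsed to X).  The gradient runs from HLA-DQ negative
(neither DQ2 nor DQ8 heterodimer possible) up to DQ2.5 homozygosity, and
collapses to three clinical tiers: negative, intermediate and high risk.

Post-test risk is expressed as "1 case in N": anchored to a population
prevalence of 1 in P (default 184 for the study region), a category seen
with frequency f_case among cases and f_ctrl among controls gives
N = (f_ctrl / f_case) * P.  The default "paper" mode mirrors the published
computation (within-category row frequencies rounded to two decimals before
dividing); "exact" mode uses unrounded frequencies.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Tuple

__all__ = ["HLACategory", "RiskTier", "RiskEstimate", "classify_hla", "risk_tier", "posttest_risk"]


class HLACategory(enum.Enum):
    """The eight HLA-DQ categories, in increasing order of CD risk."""

    NEG = "Neg"
    DQ8 = "DQ8"
    B2_HETERO = "B2 hetero"
    DQ8_B102_POS = "DQ8/B1*02 pos"
    DQ25_HETERO = "DQ2.5 hetero"
    DQ2_DQ8 = "DQ2/DQ8"
    B2_HOMO = "B2 homo"
    DQ25_HOMO = "DQ2.5 homo"


class RiskTier(enum.Enum):
    NEG = "negative"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


_TIER_OF = {
    HLACategory.NEG: RiskTier.NEG,
    HLACategory.DQ25_HOMO: RiskTier.HIGH,
}


@dataclass(frozen=True)
class RiskEstimate:
    category: HLACategory
    prevalence_P: float
    case_freq: float
    control_freq: float
    N: float

    @property
    def label(self) -> str:
        if math.isinf(self.N):
            return "1:inf"
        return f"1:{self.N:g}"


def classify_hla(
    dqa1_alleles: Iterable[str], dqb1_alleles: Sequence[str]
) -> HLACategory:
    """Classify one subject's DQA1/DQB1 allele calls.

    ``dqa1_alleles``: allele-group labels among {*0201, *03, *05, other};
    ``dqb1_alleles``: up to two of {*02, *0302, X}.  The rules are applied
    in a fixed first-match order so every legal input maps to exactly one
    category.
    """
    dqa1 = set(dqa1_alleles)
    dqb1 = list(dqb1_alleles)
    if not dqa1 <= {"*0201", "*03", "*05", "other"}:
        raise ValueError(f"unknown DQA1 labels: {sorted(dqa1)}")
    if len(dqb1) > 2 or any(b not in ("*02", "*0302", "X") for b in dqb1):
        raise ValueError(f"malformed DQB1 alleles: {dqb1}")

    has_05 = "*05" in dqa1
    has_03 = "*03" in dqa1
    b02_dose = sum(b == "*02" for b in dqb1)
    has_0302 = "*0302" in dqb1

    if has_05 and b02_dose == 2:
        return HLACategory.DQ25_HOMO
    if not has_05 and b02_dose == 2:
        return HLACategory.B2_HOMO
    if has_05 and has_03 and has_0302 and b02_dose == 1:
        return HLACategory.DQ2_DQ8
    if has_05 and b02_dose == 1:
        return HLACategory.DQ25_HETERO
    if not has_05 and has_03 and has_0302 and b02_dose == 1:
        return HLACategory.DQ8_B102_POS
    if not has_05 and b02_dose == 1:
        return HLACategory.B2_HETERO
    if b02_dose == 0 and has_03 and has_0302:
        return HLACategory.DQ8
    return HLACategory.NEG


def risk_tier(category: HLACategory) -> RiskTier:
    """Collapse the eight categories to negative / intermediate / high risk."""
    return _TIER_OF.get(category, RiskTier.INTERMEDIATE)


def _round_half_up(x: Decimal, places: int) -> Decimal:
    quantum = Decimal(1).scaleb(-places)
    return x.quantize(quantum, rounding=ROUND_HALF_UP)


def posttest_risk(
    n_cases_cat: int,
    n_controls_cat: int,
    prevalence_P: float = 184.0,
    rounding: str = "paper",
    category: HLACategory = HLACategory.NEG,
) -> RiskEstimate:
    """Post-test 1-in-N disease risk for one HLA-DQ category.

    ``paper`` mode reproduces the published arithmetic: the within-category
    control frequency is rounded half-up to two decimals, the case frequency
    is its complement, and N = (f_ctrl / f_case) * P is rounded to the
    nearest integer (ties downward).  ``exact`` mode divides the unrounded
    frequencies and leaves N unrounded.
    """
    if n_cases_cat < 0 or n_controls_cat < 0:
        raise ValueError("category counts must be non-negative")
    total = n_cases_cat + n_controls_cat
    if total == 0:
        raise ValueError("empty category")
    if rounding not in ("paper", "exact"):
        raise ValueError(f"unknown rounding mode {rounding!r}")

    if n_cases_cat == 0:
        warnings.warn(
            f"{category.value}: no cases in category; post-test risk is infinite"
        )
        f_case = 0.0
        f_ctrl = 1.0
        return RiskEstimate(category, prevalence_P, f_case, f_ctrl, math.inf)

    if rounding == "exact":
        f_case = n_cases_cat / total
        f_ctrl = n_controls_cat / total
        N = (f_ctrl / f_case) * prevalence_P
        return RiskEstimate(category, prevalence_P, f_case, f_ctrl, N)

    f_ctrl_d = _round_half_up(Decimal(n_controls_cat) / Decimal(total), 2)
    f_case_d = Decimal(1) - f_ctrl_d
    if f_case_d <= 0:
        warnings.warn(
            f"{category.value}: rounded case frequency is zero; risk is infinite"
        )
        return RiskEstimate(category, prevalence_P, 0.0, float(f_ctrl_d), math.inf)
    N_real = f_ctrl_d / f_case_d * Decimal(str(prevalence_P))
    # nearest integer, exact halves rounded down (matches the published rows)
    N = int(math.ceil(float(N_real) - 0.5))
    return RiskEstimate(category, prevalence_P, float(f_case_d), float(f_ctrl_d), float(N))
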