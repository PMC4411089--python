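"""Synthetic case-control cohorts with the structure the analysis assumes.

Two generation modes:

* **retrospective** (the study design): cases and controls are drawn
  independently from per-status distributions — TNFA promoter diplotypes
  under Hardy-Weinberg random mating from per-status haplotype frequencies,
  an eight-category HLA-DQ distribution, independent extra SNPs, and
  covariate marginals (sex, age, H. pylori, tTG, Marsh grade).
* **prospective**: a large latent population is generated from the
  control-like distributions, disease status is assigned by a logistic
  model with known coefficients, and the requested numbers of cases and
  controls are subsampled.  Only this mode has ground-truth logistic
  coefficients, which is what parameter-recovery checks need.

Default frequencies reproduce the study's single-SNP minor-allele
frequencies and marginal tables; the split of the -308A-bearing and
-1031C-bearing haplotype mass between individual haplotypes is not printed
in the study and is chosen here (documented in the methods note).

True phased diplotypes are retained on each record (``true_haplotypes``)
as a validation side-channel; they are never serialized.

A single integer seed drives one ``numpy.random.default_rng`` stream; all
sampling draws from it in a fixed documented order (per subject: HLA
category, TNFA diplotype, extra SNPs in panel order, sex, age, H. pylori,
tTG, Marsh grade).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .cohort import SubjectRecord
from .grouping import assign_group, combo_key, DEFAULT_BANDS
from .hla import HLACategory, RiskTier, classify_hla, risk_tier
from .loci import DEFAULT_PANEL, Genotype, LocusDef, TNFA_HAPLOTYPE_LOCI, panel_subset

__all__ = [
    "SimulationConfig",
    "sample_diplotypes",
    "generate_cohort",
    "generate_latent_population",
    "default_combo_groups",
    "prospective_design",
    "CASE_TNFA_FREQS",
    "CONTROL_TNFA_FREQS",
]

# Per-status TNFA promoter haplotype frequencies over (-1031,-857,-376,-308).
# These reproduce the study's per-status single-SNP minor allele frequencies;
# see the module docstring for what is and is not pinned down by the study.
CASE_TNFA_FREQS: Dict[str, float] = {
    "CCGG": 0.0909,  # H1
    "TTGG": 0.1045,  # H2
    "TCGG": 0.4173,  # H3
    "CCAG": 0.0656,  # H4
    "TCGA": 0.2917,  # H5
    "CCGA": 0.0300,  # H6
}
CONTROL_TNFA_FREQS: Dict[str, float] = {
    "CCGG": 0.2241,
    "TTGG": 0.1966,
    "TCGG": 0.4295,
    "CCAG": 0.0300,
    "TCGA": 0.1098,
    "CCGA": 0.0100,
}

# HLA-DQ category probabilities from the observed per-status distribution.
HLA_ORDER: Tuple[HLACategory, ...] = (
    HLACategory.NEG,
    HLACategory.DQ8,
    HLACategory.B2_HETERO,
    HLACategory.DQ8_B102_POS,
    HLACategory.DQ25_HETERO,
    HLACategory.DQ2_DQ8,
    HLACategory.B2_HOMO,
    HLACategory.DQ25_HOMO,
)
CASE_HLA_COUNTS = (1, 7, 8, 3, 104, 10, 7, 104)
CONTROL_HLA_COUNTS = (158, 17, 19, 5, 58, 4, 2, 4)

# Representative DQA1/DQB1 calls per category (inverse of the classifier).
HLA_ALLELES: Dict[HLACategory, Tuple[frozenset, Tuple[str, ...]]] = {
    HLACategory.NEG: (frozenset({"other"}), ("X", "X")),
    HLACategory.DQ8: (frozenset({"*03"}), ("*0302", "X")),
    HLACategory.B2_HETERO: (frozenset({"*0201"}), ("*02", "X")),
    HLACategory.DQ8_B102_POS: (frozenset({"*03", "*0201"}), ("*0302", "*02")),
    HLACategory.DQ25_HETERO: (frozenset({"*05"}), ("*02", "X")),
    HLACategory.DQ2_DQ8: (frozenset({"*03", "*05"}), ("*0302", "*02")),
    HLACategory.B2_HOMO: (frozenset({"*0201"}), ("*02", "*02")),
    HLACategory.DQ25_HOMO: (frozenset({"*05"}), ("*02", "*02")),
}

# Minor-allele frequencies of the non-haplotype SNPs, per status.
CASE_EXTRA_MAFS: Dict[str, float] = {
    "TNFA_-238": 0.0779,
    "IFNG_+874": 0.4508,
    "TNFRSF1A_625+10": 0.3529,
}
CONTROL_EXTRA_MAFS: Dict[str, float] = {
    "TNFA_-238": 0.0581,
    "IFNG_+874": 0.4644,
    "TNFRSF1A_625+10": 0.3712,
}

# Covariate marginals (sex = P(female), age in years, P(H. pylori), tTG units).
CASE_COVARIATES = {"p_female": 167 / 244, "age_mean": 7.0, "age_sd": 4.0,
                   "p_hpylori": 12 / 244, "ttg_mean": 153.0, "ttg_sd": 79.0}
CONTROL_COVARIATES = {"p_female": 146 / 267, "age_mean": 10.0, "age_sd": 4.0,
                      "p_hpylori": 50 / 267, "ttg_mean": 5.0, "ttg_sd": 9.0}

MARSH_LEVELS = ("none", "1", "2", "3a", "3b", "3c")
CASE_MARSH_PROBS = (0, 9, 16, 34, 51, 134)
CONTROL_MARSH_PROBS = (262, 5, 0, 0, 0, 0)

AGE_RANGE = (0.5, 23.0)


def _normalize(v: Sequence[float]) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    return arr / arr.sum()


@dataclass
class SimulationConfig:
    """Everything the generator needs; defaults follow the study marginals."""

    n_cases: int = 244
    n_controls: int = 267
    seed: int = 0
    mode: str = "retrospective"  # or "prospective"
    tnfa_freqs_case: Dict[str, float] = field(
        default_factory=lambda: dict(CASE_TNFA_FREQS)
    )
    tnfa_freqs_control: Dict[str, float] = field(
        default_factory=lambda: dict(CONTROL_TNFA_FREQS)
    )
    hla_probs_case: Tuple[float, ...] = tuple(_normalize(CASE_HLA_COUNTS))
    hla_probs_control: Tuple[float, ...] = tuple(_normalize(CONTROL_HLA_COUNTS))
    extra_mafs_case: Dict[str, float] = field(
        default_factory=lambda: dict(CASE_EXTRA_MAFS)
    )
    extra_mafs_control: Dict[str, float] = field(
        default_factory=lambda: dict(CONTROL_EXTRA_MAFS)
    )
    covariates_case: Dict[str, float] = field(
        default_factory=lambda: dict(CASE_COVARIATES)
    )
    covariates_control: Dict[str, float] = field(
        default_factory=lambda: dict(CONTROL_COVARIATES)
    )
    marsh_probs_case: Tuple[float, ...] = tuple(_normalize(CASE_MARSH_PROBS))
    marsh_probs_control: Tuple[float, ...] = tuple(_normalize(CONTROL_MARSH_PROBS))
    prospective_betas: Optional[Dict[str, float]] = None
    latent_n: int = 20000
    combo_groups: Optional[Dict[str, str]] = None
    atrophy_betas: Optional[Tuple[float, float]] = None  # (intercept, per-step)

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.mode not in ("retrospective", "prospective"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, freqs in (
            ("tnfa_freqs_case", self.tnfa_freqs_case),
            ("tnfa_freqs_control", self.tnfa_freqs_control),
        ):
            _check_freqs(name, freqs)
        for name, probs in (
            ("hla_probs_case", self.hla_probs_case),
            ("hla_probs_control", self.hla_probs_control),
            ("marsh_probs_case", self.marsh_probs_case),
            ("marsh_probs_control", self.marsh_probs_control),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if self.combo_groups is None:
            self.combo_groups = default_combo_groups(
                self.tnfa_freqs_case, self.tnfa_freqs_control,
                self.n_cases, self.n_controls,
            )


def _check_freqs(name: str, freqs: Mapping[str, float]) -> None:
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name}: haplotype frequencies must sum to 1")
    loci = panel_subset(DEFAULT_PANEL, TNFA_HAPLOTYPE_LOCI)
    for hap in freqs:
        if len(hap) != len(loci):
            raise ValueError(f"{name}: haplotype {hap!r} has wrong length")
        for allele, locus in zip(hap, loci):
            if allele not in locus.alleles:
                raise ValueError(
                    f"{name}: haplotype {hap!r} uses allele {allele!r} "
                    f"not defined at {locus.locus_id}"
                )


def default_combo_groups(
    case_freqs: Mapping[str, float] = CASE_TNFA_FREQS,
    control_freqs: Mapping[str, float] = CONTROL_TNFA_FREQS,
    n_cases: int = 244,
    n_controls: int = 267,
    bands: Sequence[float] = DEFAULT_BANDS,
) -> Dict[str, str]:
    """Expected A-E group of every possible combination under the defaults.

    For each unordered haplotype pair, the expected CD fraction among its
    carriers follows from Hardy-Weinberg diplotype probabilities per status
    and the case/control sizes; the fraction is banded as usual.
    """
    haps = sorted(set(case_freqs) | set(control_freqs))
    out: Dict[str, str] = {}
    for i, h1 in enumerate(haps):
        for h2 in haps[i:]:
            mult = 2.0 if h1 != h2 else 1.0
            e_cd = n_cases * mult * case_freqs.get(h1, 0) * case_freqs.get(h2, 0)
            e_ctrl = n_controls * mult * control_freqs.get(h1, 0) * control_freqs.get(h2, 0)
            if e_cd + e_ctrl == 0:
                continue
            out[combo_key((h1, h2))] = assign_group(e_cd / (e_cd + e_ctrl), bands)
    return out


def sample_diplotypes(
    freqs: Mapping[str, float], n: int, seed_or_rng
) -> List[Tuple[str, str]]:
    """Draw n unordered haplotype pairs under Hardy-Weinberg random mating."""
    if abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must sum to 1")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    haps = sorted(freqs)
    p = _normalize([freqs[h] for h in haps])
    draws = rng.choice(len(haps), size=(n, 2), p=p)
    return [tuple(sorted((haps[i], haps[j]))) for i, j in draws]


def _hw_genotype(maf: float, locus: LocusDef, rng: np.random.Generator) -> Genotype:
    k = rng.binomial(2, maf)
    alleles = tuple(
        [locus.allele_minor] * k + [locus.allele_major] * (2 - k)
    )
    return Genotype(locus.locus_id, (alleles[0], alleles[1]))


def _tnfa_genotypes(pair: Tuple[str, str]) -> Dict[str, Genotype]:
    loci = panel_subset(DEFAULT_PANEL, TNFA_HAPLOTYPE_LOCI)
    return {
        locus.locus_id: Genotype(locus.locus_id, (pair[0][i], pair[1][i]))
        for i, locus in enumerate(loci)
    }


def _draw_subject(
    subject_id: str,
    status: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    draw_marsh: bool = True,
) -> SubjectRecord:
    case = status == "case"
    hla_probs = config.hla_probs_case if case else config.hla_probs_control
    tnfa = config.tnfa_freqs_case if case else config.tnfa_freqs_control
    extra = config.extra_mafs_case if case else config.extra_mafs_control
    cov = config.covariates_case if case else config.covariates_control
    marsh_probs = config.marsh_probs_case if case else config.marsh_probs_control

    category = HLA_ORDER[rng.choice(len(HLA_ORDER), p=np.asarray(hla_probs))]
    dqa1, dqb1 = HLA_ALLELES[category]
    pair = sample_diplotypes(tnfa, 1, rng)[0]
    genotypes = _tnfa_genotypes(pair)
    for locus in DEFAULT_PANEL:
        if locus.locus_id in genotypes or locus.locus_id not in extra:
            continue
        genotypes[locus.locus_id] = _hw_genotype(extra[locus.locus_id], locus, rng)

    sex = "F" if rng.random() < cov["p_female"] else "M"
    age = float(np.clip(rng.normal(cov["age_mean"], cov["age_sd"]), *AGE_RANGE))
    hpylori = "yes" if rng.random() < cov["p_hpylori"] else "no"
    ttg = float(max(rng.normal(cov["ttg_mean"], cov["ttg_sd"]), 0.0))

    marsh: Optional[str] = None
    if draw_marsh:
        if case and config.atrophy_betas is not None:
            a, b = config.atrophy_betas
            score = "ABCDE".index(config.combo_groups.get(combo_key(pair), "A"))
            p_atrophy = 1.0 / (1.0 + np.exp(-(a + b * score)))
            if rng.random() < p_atrophy:
                marsh = "3c"
            else:
                sub = _normalize(config.marsh_probs_case[1:5])
                marsh = MARSH_LEVELS[1:5][rng.choice(4, p=sub)]
        else:
            marsh = MARSH_LEVELS[rng.choice(len(MARSH_LEVELS), p=np.asarray(marsh_probs))]

    return SubjectRecord(
        subject_id=subject_id,
        status=status,
        sex=sex,
        age=round(age, 1),
        hpylori=hpylori,
        ttg=round(ttg, 1),
        marsh=marsh,
        dqa1_alleles=dqa1,
        dqb1_alleles=dqb1,
        genotypes=genotypes,
        true_haplotypes=pair,
    )


def prospective_design(
    subjects: Sequence[SubjectRecord],
    betas: Mapping[str, float],
    combo_groups: Mapping[str, str],
) -> Tuple[np.ndarray, List[str]]:
    """Design matrix for the prospective risk model's term vocabulary.

    Recognized terms: ``intercept``, ``tier_INTERMEDIATE``, ``tier_HIGH``,
    ``group_score`` (A=0..E=4 from the frozen combination-group map on the
    true diplotype), ``sex_F``, ``age``, ``hpylori`` and
    ``snp_dom:<locus_id>`` (dominant minor-allele carriage).
    """
    from .loci import panel_by_id

    by_id = panel_by_id(DEFAULT_PANEL)
    terms = list(betas)
    cols = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(len(subjects)))
        elif term in ("tier_INTERMEDIATE", "tier_HIGH"):
            level = term.split("_", 1)[1]
            cols.append(
                np.array(
                    [
                        1.0
                        if risk_tier(
                            classify_hla(s.dqa1_alleles, s.dqb1_alleles)
                        ).name
                        == level
                        else 0.0
                        for s in subjects
                    ]
                )
            )
        elif term == "group_score":
            scores = []
            for s in subjects:
                if s.true_haplotypes is None:
                    raise ValueError("group_score needs the phased side-channel")
                group = combo_groups.get(combo_key(s.true_haplotypes), "A")
                scores.append(float("ABCDE".index(group)))
            cols.append(np.array(scores))
        elif term == "sex_F":
            cols.append(np.array([1.0 if s.sex == "F" else 0.0 for s in subjects]))
        elif term == "age":
            cols.append(np.array([s.age for s in subjects], dtype=float))
        elif term == "hpylori":
            cols.append(
                np.array([1.0 if s.hpylori == "yes" else 0.0 for s in subjects])
            )
        elif term.startswith("snp_dom:"):
            locus = by_id[term.split(":", 1)[1]]
            cols.append(
                np.array(
                    [
                        float(s.genotype(locus.locus_id).minor_count(locus) >= 1)
                        for s in subjects
                    ]
                )
            )
        else:
            raise ValueError(f"unknown prospective term {term!r}")
    return np.column_stack(cols), terms


def generate_latent_population(
    config: SimulationConfig, n: Optional[int] = None
) -> List[SubjectRecord]:
    """Control-like latent population with status assigned by the risk model."""
    if config.prospective_betas is None:
        raise ValueError("prospective mode requires prospective_betas")
    if "intercept" not in config.prospective_betas:
        raise ValueError("prospective_betas must include an intercept")
    n = config.latent_n if n is None else n
    rng = np.random.default_rng(config.seed)
    # draw everything as control-like, then overwrite status
    latent = [
        _draw_subject(f"L{i:06d}", "control", config, rng, draw_marsh=False)
        for i in range(n)
    ]
    X, terms = prospective_design(latent, config.prospective_betas, config.combo_groups)
    beta = np.array([config.prospective_betas[t] for t in terms])
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    is_case = rng.random(n) < p
    out = []
    for s, case in zip(latent, is_case):
        out.append(dataclasses.replace(s, status="case" if case else "control",
                                       true_haplotypes=s.true_haplotypes))
    return out


def generate_cohort(config: SimulationConfig) -> List[SubjectRecord]:
    """Generate a case-control cohort; deterministic given ``config.seed``."""
    if config.mode == "retrospective":
        rng = np.random.default_rng(config.seed)
        subjects = [
            _draw_subject(f"C{i:05d}", "case", config, rng)
            for i in range(config.n_cases)
        ]
        subjects += [
            _draw_subject(f"N{i:05d}", "control", config, rng)
            for i in range(config.n_controls)
        ]
        return subjects

    latent = generate_latent_population(config)
    rng = np.random.default_rng(config.seed + 1)
    cases = [s for s in latent if s.is_case]
    controls = [s for s in latent if not s.is_case]
    if len(cases) < config.n_cases or len(controls) < config.n_controls:
        raise ValueError(
            f"latent population too small: {len(cases)} cases / "
            f"{len(controls)} controls available"
        )
    # cases need a histology grade; controls keep marsh none/1 marginals
    marsh_case = np.asarray(config.marsh_probs_case)
    marsh_ctrl = np.asarray(config.marsh_probs_control)
    chosen = cases[: config.n_cases] + controls[: config.n_controls]
    out = []
    for i, s in enumerate(chosen):
        probs = marsh_case if s.is_case else marsh_ctrl
        marsh = MARSH_LEVELS[rng.choice(len(MARSH_LEVELS), p=probs)]
        out.append(
            dataclasses.replace(
                s,
                subject_id=f"{'C' if s.is_case else 'N'}{i:05d}",
                marsh=marsh,
                true_haplotypes=s.true_haplotypes,
            )
        )
    return out
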