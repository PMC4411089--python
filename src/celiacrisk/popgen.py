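"""Allele frequencies, Hardy-Weinberg testing and pairwise LD.

The exact Hardy-Weinberg test conditions on the observed allele counts and
enumerates every heterozygote count compatible with them, summing the
probabilities of all configurations no more probable than the observed one.
At cohort scale (hundreds of subjects) this enumeration is exact and fast,
which is why it is preferred over a Markov-chain approximation.

Pairwise LD between unphased loci goes through the two-locus haplotype EM:
D, D' and r-squared are computed from the EM haplotype frequencies with the
minor alleles as the focal alleles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .cohort import SubjectRecord
from .loci import LocusDef

__all__ = ["HWEResult", "LDResult", "allele_freq", "hwe_exact", "pairwise_ld", "genotype_counts"]


@dataclass(frozen=True)
class HWEResult:
    locus_id: str
    n_minor_homo: int
    n_het: int
    n_major_homo: int
    p_exact: float
    chi2: float
    p_chi2: float


@dataclass(frozen=True)
class LDResult:
    locus_pair: Tuple[str, str]
    D: float
    D_prime: float
    r2: float
    hap_freqs: Dict[str, float]
    phase_ambiguous: bool = False


def allele_freq(counts: Sequence[int]) -> float:
    """Minor-allele frequency from (minor-homo, het, major-homo) counts."""
    n_mm, n_het, n_MM = (int(c) for c in counts)
    total = n_mm + n_het + n_MM
    if total <= 0:
        raise ValueError("allele_freq: no genotyped subjects")
    if min(n_mm, n_het, n_MM) < 0:
        raise ValueError("allele_freq: negative genotype count")
    return (2 * n_mm + n_het) / (2 * total)


def genotype_counts(subjects: Sequence[SubjectRecord], locus: LocusDef) -> Tuple[int, int, int]:
    """Complete-case (minor-homo, het, major-homo) counts at one locus."""
    tallies = [0, 0, 0]
    for s in subjects:
        k = s.genotype(locus.locus_id).minor_count(locus)
        if k is not None:
            tallies[2 - k] += 1
    return tallies[0], tallies[1], tallies[2]


def _log_het_probs(n: int, n_minor: int) -> Tuple[np.ndarray, np.ndarray]:
    """Log P(n_het | n subjects, n_minor alleles) for all feasible het counts.

    Conditional distribution of the heterozygote count given the allele
    counts under Hardy-Weinberg (Levene / Haldane):

        P(h) = n! / (n_mm! h! n_MM!) * 2^h * n_a! * n_A! / (2n)!
    """
    n_major = 2 * n - n_minor
    h_max = min(n_minor, n_major)
    hets = np.arange(n_minor % 2, h_max + 1, 2)
    n_mm = (n_minor - hets) // 2
    n_MM = (n_major - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(n_mm + 1)
        - gammaln(hets + 1)
        - gammaln(n_MM + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    return hets, logp


def hwe_exact(counts: Sequence[int], locus_id: str = "") -> HWEResult:
    """Exact Hardy-Weinberg test from (minor-homo, het, major-homo) counts."""
    n_mm, n_het, n_MM = (int(c) for c in counts)
    n = n_mm + n_het + n_MM
    if n <= 0:
        raise ValueError("hwe_exact: no genotyped subjects")
    n_minor = 2 * n_mm + n_het

    if n_minor == 0 or n_minor == 2 * n:
        p_exact = 1.0
        chi2 = 0.0
        p_chi2 = 1.0
    else:
        hets, logp = _log_het_probs(n, n_minor)
        obs_logp = logp[hets == n_het][0]
        # tolerance guards against ties lost to floating point
        p_exact = float(np.exp(logp[logp <= obs_logp + 1e-10]).sum())
        p_exact = min(1.0, p_exact)

        q = n_minor / (2 * n)
        expected = np.array([n * q * q, 2 * n * q * (1 - q), n * (1 - q) ** 2])
        observed = np.array([n_mm, n_het, n_MM], dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        p_chi2 = float(chi2_dist.sf(chi2, 1))

    return HWEResult(locus_id, n_mm, n_het, n_MM, p_exact, chi2, p_chi2)


def pairwise_ld(
    subjects: Sequence[SubjectRecord],
    locus_a: LocusDef,
    locus_b: LocusDef,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """Two-locus LD from unphased genotypes via haplotype EM.

    D is reported for the minor-allele/minor-allele haplotype:
    ``D = p(minor_a, minor_b) - maf_a * maf_b``.
    """
    from .em import em_haplotype_freqs

    complete = [
        s
        for s in subjects
        if not s.genotype(locus_a.locus_id).is_missing
        and not s.genotype(locus_b.locus_id).is_missing
    ]
    if len(complete) < 2:
        raise ValueError("pairwise_ld: need at least 2 complete-case subjects")
    for locus in (locus_a, locus_b):
        n_mm, n_het, n_MM = genotype_counts(complete, locus)
        if n_mm + n_het == 0 or n_het + n_MM == 0:
            raise ValueError(f"pairwise_ld: locus {locus.locus_id} is monomorphic")

    table = em_haplotype_freqs(complete, (locus_a, locus_b), tol=tol, max_iter=max_iter)
    freqs = {h: float(f) for h, f in zip(table.haplotypes, table.freqs)}

    def freq_of(a1: str, a2: str) -> float:
        return freqs.get(a1 + a2, 0.0)

    p_a = freq_of(locus_a.allele_minor, locus_b.allele_minor) + freq_of(
        locus_a.allele_minor, locus_b.allele_major
    )
    p_b = freq_of(locus_a.allele_minor, locus_b.allele_minor) + freq_of(
        locus_a.allele_major, locus_b.allele_minor
    )
    p_ab = freq_of(locus_a.allele_minor, locus_b.allele_minor)
    D = p_ab - p_a * p_b
    if D >= 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    D_prime = 0.0 if d_max == 0 else D / d_max
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    r2 = 0.0 if denom == 0 else D * D / denom

    # A mirrored solution (swap coupling/repulsion in the double
    # heterozygotes) with the same likelihood means phase is unidentifiable.
    mirrored = dict(freqs)
    for a1 in (locus_a.allele_major, locus_a.allele_minor):
        for a2 in (locus_b.allele_major, locus_b.allele_minor):
            other_a1 = (
                locus_a.allele_minor if a1 == locus_a.allele_major else locus_a.allele_major
            )
            mirrored[a1 + a2] = freqs.get(other_a1 + a2, 0.0)
    ambiguous = False
    if any(abs(mirrored[h] - freqs.get(h, 0.0)) > 1e-6 for h in mirrored):
        mirror_ll = _two_locus_loglik(complete, locus_a, locus_b, mirrored)
        ambiguous = abs(mirror_ll - table.loglik) < 1e-9

    return LDResult(
        locus_pair=(locus_a.locus_id, locus_b.locus_id),
        D=D,
        D_prime=D_prime,
        r2=r2,
        hap_freqs=freqs,
        phase_ambiguous=ambiguous,
    )


def _two_locus_loglik(
    subjects: Sequence[SubjectRecord],
    locus_a: LocusDef,
    locus_b: LocusDef,
    freqs: Dict[str, float],
) -> float:
    from .em import enumerate_compatible_diplotypes, diplotype_pair_weight

    ll = 0.0
    for s in subjects:
        pairs = enumerate_compatible_diplotypes(s, (locus_a, locus_b))
        lik = sum(diplotype_pair_weight(h1, h2, freqs) for h1, h2 in pairs)
        ll += np.log(lik) if lik > 0 else -np.inf
    return float(ll)
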