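"""Multi-locus haplotype frequency estimation from unphased genotypes.

Expectation-maximization under Hardy-Weinberg random mating: the E-step
distributes each subject over the diplotypes compatible with their unphased
genotypes with weight 2^[h1 != h2] * p(h1) * p(h2) (normalized per subject);
the M-step sets every haplotype frequency to its expected allele share.
The observed-data log-likelihood is checked to be non-decreasing at every
iteration.  Because double-heterozygote-rich data can have local optima,
the fit is repeated from a uniform start plus random Dirichlet restarts and
the best log-likelihood wins.

Per-subject diplotype posteriors and maximum-a-posteriori assignment follow
the same Hardy-Weinberg weighting.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .cohort import SubjectRecord
from .loci import LocusDef

__all__ = [
    "HaplotypeFreqTable",
    "DiplotypePosterior",
    "enumerate_compatible_diplotypes",
    "em_haplotype_freqs",
    "diplotype_posteriors",
    "assign_diplotype",
    "diplotype_pair_weight",
]

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]


@dataclass(frozen=True)
class HaplotypeFreqTable:
    """Estimated population haplotype frequencies over an ordered locus panel."""

    panel: Tuple[str, ...]
    haplotypes: Tuple[str, ...]
    freqs: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_used: int

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.shape != (len(self.haplotypes),):
            raise ValueError("freqs length must match haplotypes")
        if (freqs < -1e-12).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be a probability vector")
        object.__setattr__(self, "freqs", freqs)

    def freq(self, haplotype: str) -> float:
        try:
            return float(self.freqs[self.haplotypes.index(haplotype)])
        except ValueError:
            return 0.0

    def as_dict(self) -> Dict[str, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.freqs)}

    def report(self, floor: float = 1e-5) -> Dict[str, float]:
        """Frequencies above the reporting floor (pruned view, not the model)."""
        return {h: float(f) for h, f in zip(self.haplotypes, self.freqs) if f >= floor}


@dataclass(frozen=True)
class DiplotypePosterior:
    subject_id: str
    pairs: Tuple[Pair, ...]
    posteriors: np.ndarray

    def __post_init__(self) -> None:
        post = np.asarray(self.posteriors, dtype=float)
        if post.shape != (len(self.pairs),):
            raise ValueError("posteriors length must match pairs")
        if abs(post.sum() - 1.0) > 1e-9:
            raise ValueError("posteriors must sum to 1")
        object.__setattr__(self, "posteriors", post)

    def top(self) -> Tuple[Pair, float]:
        i = int(np.argmax(self.posteriors))
        return self.pairs[i], float(self.posteriors[i])


def diplotype_pair_weight(h1: str, h2: str, freqs: Mapping[str, float]) -> float:
    """Hardy-Weinberg probability of an unordered haplotype pair."""
    p1 = freqs.get(h1, 0.0)
    p2 = freqs.get(h2, 0.0)
    return (2.0 if h1 != h2 else 1.0) * p1 * p2


def _subject_genotype_pattern(
    subject: SubjectRecord, panel: Sequence[LocusDef], tolerant: bool
) -> Optional[Tuple[Tuple[str, str], ...]]:
    """Per-locus sorted allele pairs; None drops the subject (complete-case)."""
    pattern = []
    for locus in panel:
        gt = subject.genotype(locus.locus_id)
        if gt.is_missing:
            if not tolerant:
                return None
            pattern.append(None)
        else:
            pattern.append(gt.alleles)
    return tuple(pattern)


def _pairs_for_pattern(
    pattern: Sequence[Optional[Tuple[str, str]]], panel: Sequence[LocusDef]
) -> List[Pair]:
    # expand missing loci to all three unordered genotypes, then take the
    # union of compatible pairs
    per_locus_options: List[List[Tuple[str, str]]] = []
    for locus, alleles in zip(panel, pattern):
        if alleles is None:
            M, m = locus.allele_major, locus.allele_minor
            per_locus_options.append([(M, M), tuple(sorted((M, m))), (m, m)])
        else:
            per_locus_options.append([alleles])
    pairs = set()
    for concrete in itertools.product(*per_locus_options):
        het_sites = [i for i, (a, b) in enumerate(concrete) if a != b]
        if not het_sites:
            hap = "".join(a for a, _ in concrete)
            pairs.add((hap, hap))
            continue
        # fix the first het site to break the hap1/hap2 symmetry
        for choices in itertools.product((0, 1), repeat=len(het_sites) - 1):
            flip = dict(zip(het_sites[1:], choices))
            flip[het_sites[0]] = 0
            h1 = []
            h2 = []
            for i, (a, b) in enumerate(concrete):
                if a == b:
                    h1.append(a)
                    h2.append(a)
                elif flip[i] == 0:
                    h1.append(a)
                    h2.append(b)
                else:
                    h1.append(b)
                    h2.append(a)
            pair = tuple(sorted(("".join(h1), "".join(h2))))
            pairs.add(pair)
    return sorted(pairs)


def enumerate_compatible_diplotypes(
    subject: SubjectRecord, panel: Sequence[LocusDef], tolerant: bool = False
) -> List[Pair]:
    """All unordered haplotype pairs consistent with a subject's genotypes.

    With k heterozygous loci (and no missing data) there are exactly
    ``2**(k-1)`` such pairs (one when k = 0).
    """
    pattern = _subject_genotype_pattern(subject, panel, tolerant)
    if pattern is None:
        missing = [
            locus.locus_id
            for locus in panel
            if subject.genotype(locus.locus_id).is_missing
        ]
        raise ValueError(
            f"{subject.subject_id}: missing genotype at {missing} "
            "(enable tolerant mode to sum over missing loci)"
        )
    return _pairs_for_pattern(pattern, panel)


def _em_run(
    pattern_pairs: List[List[Pair]],
    pattern_counts: np.ndarray,
    hap_index: Dict[str, int],
    start: np.ndarray,
    tol: float,
    max_iter: int,
) -> Tuple[np.ndarray, float, int, bool]:
    n_hap = len(hap_index)
    n_subjects = float(pattern_counts.sum())
    freqs = start.copy()

    # index arrays per pattern for vectorized E-step
    idx1 = [np.array([hap_index[h1] for h1, _ in pairs]) for pairs in pattern_pairs]
    idx2 = [np.array([hap_index[h2] for _, h2 in pairs]) for pairs in pattern_pairs]
    mult = [
        np.array([2.0 if h1 != h2 else 1.0 for h1, h2 in pairs])
        for pairs in pattern_pairs
    ]

    def loglik(f: np.ndarray) -> float:
        ll = 0.0
        for k in range(len(pattern_pairs)):
            lik = float((mult[k] * f[idx1[k]] * f[idx2[k]]).sum())
            ll += pattern_counts[k] * (np.log(lik) if lik > 0 else -np.inf)
        return ll

    prev_ll = loglik(freqs)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        expected = np.zeros(n_hap)
        for k in range(len(pattern_pairs)):
            w = mult[k] * freqs[idx1[k]] * freqs[idx2[k]]
            total = w.sum()
            if total <= 0:
                # pattern unreachable under current frequencies: restart weight
                w = mult[k] / mult[k].sum()
                total = 1.0
            w = pattern_counts[k] * w / total
            np.add.at(expected, idx1[k], w)
            np.add.at(expected, idx2[k], w)
        freqs = expected / (2.0 * n_subjects)
        ll = loglik(freqs)
        if ll < prev_ll - 1e-9:
            raise RuntimeError(
                f"EM log-likelihood decreased ({prev_ll} -> {ll}); this is a bug"
            )
        if ll - prev_ll < tol:
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
    return freqs, prev_ll, n_iter, converged


def em_haplotype_freqs(
    subjects: Sequence[SubjectRecord],
    panel: Sequence[LocusDef],
    tol: float = 1e-8,
    max_iter: int = 1000,
    n_restarts: int = 3,
    seed: Optional[int] = None,
    tolerant: bool = False,
) -> HaplotypeFreqTable:
    """Maximum-likelihood haplotype frequencies for a locus panel.

    Subjects missing any panel genotype are excluded (complete-case) unless
    ``tolerant`` is set, in which case missing loci are summed over.
    """
    patterns: Dict[Tuple, int] = {}
    for s in subjects:
        pat = _subject_genotype_pattern(s, panel, tolerant)
        if pat is None:
            continue
        patterns[pat] = patterns.get(pat, 0) + 1
    if not patterns:
        raise ValueError("em_haplotype_freqs: no subjects with complete panel genotypes")

    pattern_list = sorted(patterns)
    pattern_pairs = [_pairs_for_pattern(p, panel) for p in pattern_list]
    pattern_counts = np.array([patterns[p] for p in pattern_list], dtype=float)

    haplotypes = sorted({h for pairs in pattern_pairs for pair in pairs for h in pair})
    hap_index = {h: i for i, h in enumerate(haplotypes)}

    rng = np.random.default_rng(seed)
    starts = [np.full(len(haplotypes), 1.0 / len(haplotypes))]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(rng.dirichlet(np.ones(len(haplotypes))))

    best = None
    for start in starts:
        freqs, ll, n_iter, converged = _em_run(
            pattern_pairs, pattern_counts, hap_index, start, tol, max_iter
        )
        if best is None or ll > best[1]:
            best = (freqs, ll, n_iter, converged)

    freqs, ll, n_iter, converged = best
    freqs = np.clip(freqs, 0.0, None)
    freqs = freqs / freqs.sum()
    return HaplotypeFreqTable(
        panel=tuple(l.locus_id for l in panel),
        haplotypes=tuple(haplotypes),
        freqs=freqs,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        n_used=int(pattern_counts.sum()),
    )


def diplotype_posteriors(
    subject: SubjectRecord,
    freq_table: HaplotypeFreqTable,
    panel: Sequence[LocusDef],
    tolerant: bool = False,
) -> DiplotypePosterior:
    """Posterior over the haplotype pairs compatible with one subject."""
    pairs = enumerate_compatible_diplotypes(subject, panel, tolerant=tolerant)
    freqs = freq_table.as_dict()
    weights = np.array([diplotype_pair_weight(h1, h2, freqs) for h1, h2 in pairs])
    total = weights.sum()
    if total <= 0:
        raise ValueError(
            f"{subject.subject_id}: genotype impossible under the fitted "
            "haplotype frequencies (all compatible pairs have zero frequency)"
        )
    return DiplotypePosterior(
        subject_id=subject.subject_id,
        pairs=tuple(pairs),
        posteriors=weights / total,
    )


def assign_diplotype(
    posterior: DiplotypePosterior,
    policy: str = "map",
    threshold: float = 0.8,
) -> Optional[Pair]:
    """MAP (or thresholded) diplotype call; None means unassigned."""
    if policy not in ("map", "threshold"):
        raise ValueError(f"unknown assignment policy {policy!r}")
    post = posterior.posteriors
    best = float(post.max())
    winners = [posterior.pairs[i] for i in np.flatnonzero(post >= best - 1e-12)]
    if len(winners) > 1:
        logger.warning(
            "%s: tie between diplotypes %s; taking the lexicographically smallest",
            posterior.subject_id,
            winners,
        )
    pair = min(winners)
    if policy == "threshold" and best < threshold:
        return None
    return pair
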