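"""Haplotype EM: enumeration, likelihood optimality, posteriors, assignment."""

import itertools

import numpy as np
import pytest

from celiacrisk.em import (
    HaplotypeFreqTable,
    assign_diplotype,
    diplotype_posteriors,
    diplotype_pair_weight,
    em_haplotype_freqs,
    enumerate_compatible_diplotypes,
)
from celiacrisk.loci import LocusDef
from celiacrisk.popgen import allele_freq, genotype_counts

from conftest import subject_with_haps

L1 = LocusDef("L1", "rs1", "A", "a")
L2 = LocusDef("L2", "rs2", "B", "b")
L3 = LocusDef("L3", "rs3", "C", "c")
L4 = LocusDef("L4", "rs4", "D", "d")


def brute_force_pairs(genotypes):
    """All ordered phase assignments collapsed to unordered pairs."""
    per_locus = [
        [(a, b), (b, a)] if a != b else [(a, b)] for a, b in genotypes
    ]
    pairs = set()
    for assignment in itertools.product(*per_locus):
        h1 = "".join(x for x, _ in assignment)
        h2 = "".join(x for _, x in assignment)
        pairs.add(tuple(sorted((h1, h2))))
    return sorted(pairs)


@pytest.mark.parametrize(
    "hap_pair,k_expected",
    [
        (("ABCD", "ABCD"), 0),
        (("ABCD", "aBCD"), 1),
        (("ABCD", "abCD"), 2),
        (("ABCD", "abcD"), 3),
        (("ABCD", "abcd"), 4),
    ],
)
def test_enumeration_counts_and_oracle(hap_pair, k_expected):
    panel = (L1, L2, L3, L4)
    s = subject_with_haps("E1", "case", hap_pair, panel)
    pairs = enumerate_compatible_diplotypes(s, panel)
    expected_n = 1 if k_expected == 0 else 2 ** (k_expected - 1)
    assert len(pairs) == expected_n
    genotypes = [tuple(sorted((hap_pair[0][i], hap_pair[1][i]))) for i in range(4)]
    assert pairs == brute_force_pairs(genotypes)
    assert tuple(sorted(hap_pair)) in pairs  # the true pair is always included


def test_missing_genotype_requires_tolerant_mode():
    panel = (L1, L2)
    s = subject_with_haps("M1", "case", ("AB", "AB"), panel)
    s.genotypes.pop("L2")
    with pytest.raises(ValueError, match="L2"):
        enumerate_compatible_diplotypes(s, panel)
    pairs = enumerate_compatible_diplotypes(s, panel, tolerant=True)
    assert ("AB", "AB") in pairs and ("Ab", "Ab") in pairs and ("AB", "Ab") in pairs


def test_single_locus_em_equals_allele_freq():
    subjects = (
        [subject_with_haps(f"H{i}", "case", ("a", "a"), (L1,)) for i in range(3)]
        + [subject_with_haps(f"h{i}", "case", ("A", "a"), (L1,)) for i in range(5)]
        + [subject_with_haps(f"m{i}", "case", ("A", "A"), (L1,)) for i in range(12)]
    )
    table = em_haplotype_freqs(subjects, (L1,))
    maf = allele_freq(genotype_counts(subjects, L1))
    assert table.freq("a") == pytest.approx(maf, abs=1e-12)
    # no phase ambiguity: the first M-step lands on the MLE,
    # the next iteration only confirms convergence
    assert table.converged and table.n_iter <= 2


def grid_search_oracle(subjects, panel, haplotypes, step=0.005):
    """Exhaustive simplex grid maximization of the observed-data likelihood."""
    k = int(round(1.0 / step))
    h_index = {h: i for i, h in enumerate(haplotypes)}
    grids = np.mgrid[0:k + 1, 0:k + 1, 0:k + 1].reshape(3, -1).T
    grids = grids[grids.sum(axis=1) <= k]
    freqs = np.column_stack([grids, k - grids.sum(axis=1)]) / k  # (G, 4)

    total_ll = np.zeros(len(freqs))
    for s in subjects:
        pairs = enumerate_compatible_diplotypes(s, panel)
        lik = np.zeros(len(freqs))
        for h1, h2 in pairs:
            mult = 2.0 if h1 != h2 else 1.0
            lik += mult * freqs[:, h_index[h1]] * freqs[:, h_index[h2]]
        with np.errstate(divide="ignore"):
            total_ll += np.log(lik)
    best = np.argmax(total_ll)
    return dict(zip(haplotypes, freqs[best])), float(total_ll[best])


def test_em_matches_grid_oracle_two_locus():
    panel = (L1, L2)
    subjects = (
        [subject_with_haps(f"x{i}", "case", ("AB", "AB"), panel) for i in range(2)]
        + [subject_with_haps(f"y{i}", "case", ("ab", "ab"), panel) for i in range(2)]
        + [subject_with_haps(f"z{i}", "case", ("AB", "ab"), panel) for i in range(2)]
    )
    table = em_haplotype_freqs(subjects, panel, seed=0, n_restarts=3)
    grid_freqs, grid_ll = grid_search_oracle(
        subjects, panel, ("AB", "Ab", "aB", "ab")
    )
    assert table.loglik >= grid_ll - 1e-6
    for h, f in grid_freqs.items():
        assert table.freq(h) == pytest.approx(f, abs=0.005)


def test_em_matches_grid_oracle_three_locus():
    panel = (L1, L2, L3)
    subjects = (
        [subject_with_haps(f"p{i}", "case", ("ABc", "ABc"), panel) for i in range(4)]
        + [subject_with_haps(f"q{i}", "case", ("abc", "abc"), panel) for i in range(4)]
        + [subject_with_haps(f"r{i}", "case", ("ABc", "abc"), panel) for i in range(4)]
    )
    table = em_haplotype_freqs(subjects, panel, seed=0, n_restarts=3)
    grid_freqs, grid_ll = grid_search_oracle(
        subjects, panel, ("ABc", "Abc", "aBc", "abc")
    )
    assert table.loglik >= grid_ll - 1e-6
    for h, f in grid_freqs.items():
        assert table.freq(h) == pytest.approx(f, abs=0.005)


def test_posterior_hand_computed_normalization():
    panel = (L1, L2)
    table = HaplotypeFreqTable(
        panel=("L1", "L2"),
        haplotypes=("AB", "Ab", "aB", "ab"),
        freqs=np.array([0.4, 0.1, 0.1, 0.4]),
        loglik=0.0,
        n_iter=1,
        converged=True,
        n_used=1,
    )
    s = subject_with_haps("DH", "case", ("AB", "ab"), panel)
    post = diplotype_posteriors(s, table, panel)
    by_pair = dict(zip(post.pairs, post.posteriors))
    # 2*0.4*0.4 / (2*0.4*0.4 + 2*0.1*0.1) = 0.941...
    assert by_pair[("AB", "ab")] == pytest.approx(0.941, abs=5e-4)
    assert post.posteriors.sum() == pytest.approx(1.0, abs=1e-12)
    # threshold policy keeps the confident call, MAP always calls
    assert assign_diplotype(post, "threshold", threshold=0.8) == ("AB", "ab")
    assert assign_diplotype(post) == ("AB", "ab")


def test_posterior_homozygote_is_certain():
    panel = (L1, L2)
    table = HaplotypeFreqTable(
        panel=("L1", "L2"),
        haplotypes=("AB", "ab"),
        freqs=np.array([0.5, 0.5]),
        loglik=0.0,
        n_iter=1,
        converged=True,
        n_used=1,
    )
    s = subject_with_haps("HOM", "case", ("AB", "AB"), panel)
    post = diplotype_posteriors(s, table, panel)
    assert post.pairs == (("AB", "AB"),)
    assert post.posteriors[0] == 1.0


def test_impossible_genotype_raises():
    panel = (L1, L2)
    table = HaplotypeFreqTable(
        panel=("L1", "L2"),
        haplotypes=("AB", "ab"),
        freqs=np.array([1.0, 0.0]),
        loglik=0.0,
        n_iter=1,
        converged=True,
        n_used=1,
    )
    s = subject_with_haps("IMP", "case", ("Ab", "Ab"), panel)
    with pytest.raises(ValueError, match="impossible"):
        diplotype_posteriors(s, table, panel)


def test_tie_breaks_lexicographically():
    panel = (L1, L2)
    table = HaplotypeFreqTable(
        panel=("L1", "L2"),
        haplotypes=("AB", "Ab", "aB", "ab"),
        freqs=np.array([0.25, 0.25, 0.25, 0.25]),
        loglik=0.0,
        n_iter=1,
        converged=True,
        n_used=1,
    )
    s = subject_with_haps("TIE", "case", ("AB", "ab"), panel)
    post = diplotype_posteriors(s, table, panel)
    assert assign_diplotype(post) == min(post.pairs)
    assert assign_diplotype(post, "threshold", threshold=0.8) is None


def test_map_assignment_recovers_truth_when_unambiguous(tnfa_panel):
    from celiacrisk.simulate import SimulationConfig, generate_cohort

    subjects = generate_cohort(SimulationConfig(n_cases=300, n_controls=300, seed=9))
    table = em_haplotype_freqs(subjects, tnfa_panel, seed=0)
    n_unamb = correct = 0
    for s in subjects:
        pairs = enumerate_compatible_diplotypes(s, tnfa_panel)
        k_het = sum(
            s.genotype(l.locus_id).is_het() for l in tnfa_panel
        )
        post = diplotype_posteriors(s, table, tnfa_panel)
        call = assign_diplotype(post)
        if k_het <= 1:
            n_unamb += 1
            assert call == s.true_haplotypes  # phase is determined
        correct += call == s.true_haplotypes
    assert n_unamb > 0
    assert correct / len(subjects) >= 0.95


def test_per_status_and_pooled_frequencies_sum_to_one(tnfa_panel):
    from celiacrisk.simulate import SimulationConfig, generate_cohort

    subjects = generate_cohort(SimulationConfig(n_cases=80, n_controls=80, seed=4))
    for grp in (
        subjects,
        [s for s in subjects if s.is_case],
        [s for s in subjects if not s.is_case],
    ):
        table = em_haplotype_freqs(grp, tnfa_panel, seed=0)
        assert table.freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert table.converged
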