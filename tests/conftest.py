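import numpy as np
import pytest

from celiacrisk.cohort import SubjectRecord
from celiacrisk.loci import DEFAULT_PANEL, Genotype, LocusDef, panel_by_id, panel_subset, TNFA_HAPLOTYPE_LOCI
from celiacrisk.tables import load_printed_tables


@pytest.fixture(scope="session")
def panel():
    return DEFAULT_PANEL


@pytest.fixture(scope="session")
def tnfa_panel():
    return panel_subset(DEFAULT_PANEL, TNFA_HAPLOTYPE_LOCI)


@pytest.fixture(scope="session")
def printed():
    return load_printed_tables()


def make_subject(
    subject_id="S1",
    status="case",
    sex="F",
    age=8.0,
    hpylori="no",
    genotypes=None,
    dqa1=frozenset({"*05"}),
    dqb1=("*02", "X"),
    marsh=None,
    true_haplotypes=None,
):
    """Minimal valid subject for unit tests."""
    return SubjectRecord(
        subject_id=subject_id,
        status=status,
        sex=sex,
        age=age,
        hpylori=hpylori,
        marsh=marsh,
        dqa1_alleles=dqa1,
        dqb1_alleles=dqb1,
        genotypes=genotypes or {},
        true_haplotypes=true_haplotypes,
    )


def subject_with_haps(subject_id, status, pair, panel_loci):
    """Subject whose panel genotypes collapse the given phased pair."""
    genotypes = {
        locus.locus_id: Genotype(locus.locus_id, (pair[0][i], pair[1][i]))
        for i, locus in enumerate(panel_loci)
    }
    return make_subject(
        subject_id=subject_id,
        status=status,
        genotypes=genotypes,
        true_haplotypes=tuple(sorted(pair)),
    )


def subjects_from_genotype_table(locus_id, table, statuses=("case", "control")):
    """Expand a per-locus genotype count table into SubjectRecords."""
    by_id = panel_by_id(DEFAULT_PANEL)
    locus = by_id[locus_id]
    subjects = []
    i = 0
    for r, gt_label in enumerate(table.row_labels):
        gt = Genotype.from_string(locus, gt_label)
        for c, status in enumerate(table.col_labels):
            if status not in statuses:
                continue
            for _ in range(int(table.counts[r, c])):
                subjects.append(
                    make_subject(
                        subject_id=f"T{i:04d}",
                        status=status,
                        genotypes={locus_id: gt},
                    )
                )
                i += 1
    return subjects
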