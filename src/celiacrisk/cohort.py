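"""Subject-level cohort model and TSV/VCF readers.

The cohort file is a UTF-8 tab-separated table with one row per child:

    subject_id  status  sex  age  hpylori  ttg  marsh  dqa1  dqb1  <locus...>

``dqa1``/``dqb1`` are comma-joined allele-group labels (DQB1 alleles other
than *02/*0302 are collapsed to ``X``, as the risk classification requires);
genotype columns hold ``X/Y`` strings; ``NA`` marks missing values
throughout.  Subjects are unphased: genotypes are unordered allele pairs and
phase is never an input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .loci import MISSING, Genotype, LocusDef, panel_by_id

__all__ = [
    "SubjectRecord",
    "read_cohort",
    "write_cohort",
    "read_vcf_genotypes",
    "CohortFormatError",
]

DQA1_LABELS = ("*0201", "*03", "*05", "other")
DQB1_LABELS = ("*02", "*0302", "X")
MARSH_LEVELS = ("none", "1", "2", "3a", "3b", "3c")
FIXED_COLUMNS = ("subject_id", "status", "sex", "age", "hpylori", "ttg", "marsh", "dqa1", "dqb1")


class CohortFormatError(ValueError):
    """Raised when a cohort file violates the TSV schema."""


@dataclass(eq=True)
class SubjectRecord:
    """One child of the case-control cohort.

    ``true_haplotypes`` is a simulator side-channel carrying the phased
    TNFA diplotype that generated the unphased genotypes; it is never
    serialized and does not take part in equality.
    """

    subject_id: str
    status: str  # "case" | "control"
    sex: str  # "F" | "M"
    age: Optional[float] = None
    hpylori: Optional[str] = None  # "yes" | "no" | None (unknown)
    ttg: Optional[float] = None
    marsh: Optional[str] = None
    dqa1_alleles: frozenset = frozenset()
    dqb1_alleles: Tuple[str, ...] = ()
    genotypes: Dict[str, Genotype] = field(default_factory=dict)
    true_haplotypes: Optional[Tuple[str, str]] = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"{self.subject_id}: status must be case/control, got {self.status!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"{self.subject_id}: sex must be F/M, got {self.sex!r}")
        if self.age is not None and self.age < 0:
            raise ValueError(f"{self.subject_id}: negative age")
        if self.hpylori not in ("yes", "no", None):
            raise ValueError(f"{self.subject_id}: bad hpylori value {self.hpylori!r}")
        if self.marsh is not None and self.marsh not in MARSH_LEVELS:
            raise ValueError(f"{self.subject_id}: bad Marsh grade {self.marsh!r}")
        if len(self.dqb1_alleles) > 2:
            raise ValueError(f"{self.subject_id}: more than 2 DQB1 alleles")
        for a in self.dqa1_alleles:
            if a not in DQA1_LABELS:
                raise ValueError(f"{self.subject_id}: unknown DQA1 label {a!r}")
        for b in self.dqb1_alleles:
            if b not in DQB1_LABELS:
                raise ValueError(f"{self.subject_id}: unknown DQB1 label {b!r}")
        self.dqb1_alleles = tuple(sorted(self.dqb1_alleles))

    @property
    def is_case(self) -> bool:
        return self.status == "case"

    @property
    def dqb1_02_dose(self) -> int:
        return sum(b == "*02" for b in self.dqb1_alleles)

    def genotype(self, locus_id: str) -> Genotype:
        return self.genotypes.get(locus_id, Genotype(locus_id, None))


def _fmt_opt(value) -> str:
    return MISSING if value is None else str(value)


def _parse_float(text: str, what: str, line_no: int) -> Optional[float]:
    if text == MISSING:
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortFormatError(f"line {line_no}: bad {what} value {text!r}") from None


def read_cohort(path, panel: Sequence[LocusDef]) -> List[SubjectRecord]:
    """Read a cohort TSV; one SubjectRecord per data row, in file order."""
    by_id = panel_by_id(panel)
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        header_line = handle.readline().rstrip("\n")
        if not header_line:
            raise CohortFormatError(f"{path}: empty file")
        header = header_line.split("\t")
        if tuple(header[: len(FIXED_COLUMNS)]) != FIXED_COLUMNS:
            raise CohortFormatError(
                f"{path}: header must start with {' '.join(FIXED_COLUMNS)}"
            )
        locus_cols = header[len(FIXED_COLUMNS):]
        unknown = [c for c in locus_cols if c not in by_id]
        if unknown:
            raise CohortFormatError(f"{path}: genotype columns not in panel: {unknown}")

        subjects: List[SubjectRecord] = []
        for line_no, raw in enumerate(handle, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != len(header):
                raise CohortFormatError(
                    f"line {line_no}: expected {len(header)} fields, got {len(fields)}"
                )
            row = dict(zip(header, fields))
            hpylori = None if row["hpylori"] == MISSING else row["hpylori"]
            marsh = None if row["marsh"] == MISSING else row["marsh"]
            dqa1 = frozenset() if row["dqa1"] == MISSING else frozenset(row["dqa1"].split(","))
            dqb1: Tuple[str, ...] = ()
            if row["dqb1"] != MISSING:
                dqb1 = tuple(row["dqb1"].split(","))
            genotypes: Dict[str, Genotype] = {}
            for col in locus_cols:
                try:
                    genotypes[col] = Genotype.from_string(by_id[col], row[col])
                except ValueError as exc:
                    raise CohortFormatError(f"line {line_no}: {exc}") from exc
            try:
                subjects.append(
                    SubjectRecord(
                        subject_id=row["subject_id"],
                        status=row["status"],
                        sex=row["sex"],
                        age=_parse_float(row["age"], "age", line_no),
                        hpylori=hpylori,
                        ttg=_parse_float(row["ttg"], "ttg", line_no),
                        marsh=marsh,
                        dqa1_alleles=dqa1,
                        dqb1_alleles=dqb1,
                        genotypes=genotypes,
                    )
                )
            except ValueError as exc:
                raise CohortFormatError(f"line {line_no}: {exc}") from exc
    return subjects


def write_cohort(subjects: Sequence[SubjectRecord], path, panel: Sequence[LocusDef]) -> None:
    """Write a cohort TSV such that ``read_cohort`` restores it exactly."""
    path = Path(path)
    locus_ids = [locus.locus_id for locus in panel]
    with path.open("w", encoding="utf-8") as handle:
        handle.write("\t".join(list(FIXED_COLUMNS) + locus_ids) + "\n")
        for s in subjects:
            row = [
                s.subject_id,
                s.status,
                s.sex,
                _fmt_opt(s.age),
                _fmt_opt(s.hpylori),
                _fmt_opt(s.ttg),
                _fmt_opt(s.marsh),
                ",".join(sorted(s.dqa1_alleles)) if s.dqa1_alleles else MISSING,
                ",".join(s.dqb1_alleles) if s.dqb1_alleles else MISSING,
            ]
            row += [s.genotype(l).to_string() for l in locus_ids]
            handle.write("\t".join(row) + "\n")


def read_vcf_genotypes(path, panel: Sequence[LocusDef]) -> Dict[str, Dict[str, Genotype]]:
    """Read SNP genotypes for the panel loci from a VCF 4.x file.

    Records are matched to panel loci by their ID field (rs identifier).
    REF/ALT are mapped onto the panel's major/minor alleles by identity, so
    the study's minor-allele designations stay authoritative regardless of
    sample frequencies.  Only biallelic SNP records are accepted.  Returns
    ``{sample_id: {locus_id: Genotype}}``.
    """
    import pysam

    by_rs = {locus.rs_id: locus for locus in panel}
    out: Dict[str, Dict[str, Genotype]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for sample in vcf.header.samples:
            out[sample] = {}
        for rec in vcf:
            locus = by_rs.get(rec.id)
            if locus is None:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                raise CohortFormatError(
                    f"{rec.id}: only biallelic records are supported"
                )
            site_alleles = {rec.ref, rec.alts[0]}
            if site_alleles != set(locus.alleles):
                raise CohortFormatError(
                    f"{rec.id}: VCF alleles {sorted(site_alleles)} do not match "
                    f"panel alleles {sorted(locus.alleles)} for {locus.locus_id}"
                )
            for sample in rec.samples.values():
                calls = sample.alleles
                if calls is None or None in calls:
                    gt = Genotype(locus.locus_id, None)
                else:
                    gt = Genotype(locus.locus_id, (calls[0], calls[1]))
                out[sample.name][locus.locus_id] = gt
    return out
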