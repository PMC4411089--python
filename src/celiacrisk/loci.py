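"""Locus definitions and genotype primitives for the studied SNP panel.

The panel covers five TNFA promoter SNPs, IFNG +874A>T and the intronic
TNFRSF1A c.625+10A>G variant.  Major/minor allele designations are fixed by
the panel definition (they are study conventions, not re-derived per sample),
so a sample in which the designated minor allele happens to exceed 50% still
reports that allele's frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Tuple

__all__ = [
    "LocusDef",
    "Genotype",
    "DEFAULT_PANEL",
    "TNFA_HAPLOTYPE_LOCI",
    "HAPLOTYPE_CODES",
    "panel_by_id",
]

MISSING = "NA"


@dataclass(frozen=True)
class LocusDef:
    """A biallelic locus with a fixed major/minor allele convention."""

    locus_id: str
    rs_id: str
    allele_major: str
    allele_minor: str

    def __post_init__(self) -> None:
        if self.allele_major == self.allele_minor:
            raise ValueError(
                f"{self.locus_id}: major and minor alleles must differ"
            )
        for a in (self.allele_major, self.allele_minor):
            if len(a) != 1:
                raise ValueError(f"{self.locus_id}: allele {a!r} is not a single character")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.allele_major, self.allele_minor))


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of alleles at one locus; ``alleles is None`` = missing."""

    locus_id: str
    alleles: Optional[Tuple[str, str]]

    def __post_init__(self) -> None:
        if self.alleles is not None:
            if len(self.alleles) != 2:
                raise ValueError(f"{self.locus_id}: genotype needs exactly 2 alleles")
            # canonical order makes A/G == G/A
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @classmethod
    def from_string(cls, locus: LocusDef, text: str) -> "Genotype":
        """Parse an ``X/Y`` genotype string; ``NA`` means missing."""
        if text == MISSING or text == "":
            return cls(locus.locus_id, None)
        parts = text.split("/")
        if len(parts) != 2:
            raise ValueError(f"{locus.locus_id}: malformed genotype {text!r}")
        for a in parts:
            if a not in locus.alleles:
                raise ValueError(
                    f"{locus.locus_id}: unknown allele {a!r} "
                    f"(expected {locus.allele_major} or {locus.allele_minor})"
                )
        return cls(locus.locus_id, (parts[0], parts[1]))

    def to_string(self) -> str:
        if self.alleles is None:
            return MISSING
        return "/".join(self.alleles)

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    def minor_count(self, locus: LocusDef) -> Optional[int]:
        """Number of copies of the designated minor allele (None if missing)."""
        if self.alleles is None:
            return None
        return sum(a == locus.allele_minor for a in self.alleles)

    def is_het(self) -> Optional[bool]:
        if self.alleles is None:
            return None
        return self.alleles[0] != self.alleles[1]


# Minor alleles follow the study's MAF designations: the rare promoter
# alleles -1031C, -857T, -376A, -308A, -238A; IFNG +874T; and TNFRSF1A
# c.625+10A (the allele whose frequency the study tabulates as the MAF).
DEFAULT_PANEL: Tuple[LocusDef, ...] = (
    LocusDef("TNFA_-1031", "rs1799964", "T", "C"),
    LocusDef("TNFA_-857", "rs1799724", "C", "T"),
    LocusDef("TNFA_-376", "rs1800750", "G", "A"),
    LocusDef("TNFA_-308", "rs1800629", "G", "A"),
    LocusDef("TNFA_-238", "rs361525", "G", "A"),
    LocusDef("IFNG_+874", "rs2430561", "A", "T"),
    LocusDef("TNFRSF1A_625+10", "rs1800693", "G", "A"),
)

#: The four promoter SNPs whose phased combinations define the TNFA haplotypes,
#: in 5'-to-3' order (-1031, -857, -376, -308).
TNFA_HAPLOTYPE_LOCI: Tuple[str, ...] = (
    "TNFA_-1031",
    "TNFA_-857",
    "TNFA_-376",
    "TNFA_-308",
)

#: Short haplotype codes for the six promoter haplotypes segregating in the
#: cohort, keyed by allele string over (-1031, -857, -376, -308).
HAPLOTYPE_CODES: Mapping[str, str] = {
    "CCGG": "H1",
    "TTGG": "H2",
    "TCGG": "H3",
    "CCAG": "H4",
    "TCGA": "H5",
    "CCGA": "H6",
}


def panel_by_id(panel: Iterable[LocusDef]) -> dict[str, LocusDef]:
    out: dict[str, LocusDef] = {}
    for locus in panel:
        if locus.locus_id in out:
            raise ValueError(f"duplicate locus_id {locus.locus_id!r} in panel")
        out[locus.locus_id] = locus
    return out


def panel_subset(panel: Sequence[LocusDef], locus_ids: Sequence[str]) -> Tuple[LocusDef, ...]:
    by_id = panel_by_id(panel)
    return tuple(by_id[l] for l in locus_ids)
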