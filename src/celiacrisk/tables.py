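"""Contingency tables and the packaged count fixtures.

The ``data/printed_tables.json`` fixture carries every count table the
published analysis reports at desk scale: the cohort sex and H. pylori
margins, the eight-category HLA-DQ distribution, per-SNP genotype counts,
the Marsh-grade distribution and the total-atrophy split of the CD cases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

__all__ = ["ContingencyTable", "load_printed_tables", "printed_maf", "fixture_notes"]


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled rectangular table of non-negative integer counts."""

    row_labels: Tuple[str, ...]
    col_labels: Tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "row_labels", tuple(self.row_labels))
        object.__setattr__(self, "col_labels", tuple(self.col_labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row(self, label: str) -> np.ndarray:
        return self.counts[self.row_labels.index(label)]

    def col(self, label: str) -> np.ndarray:
        return self.counts[:, self.col_labels.index(label)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContingencyTable):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.counts, other.counts)
        )


def _load_raw() -> dict:
    text = resources.files("celiacrisk.data").joinpath("printed_tables.json").read_text()
    return json.loads(text)


def _to_table(obj: dict) -> ContingencyTable:
    return ContingencyTable(
        row_labels=tuple(obj["row_labels"]),
        col_labels=tuple(obj["col_labels"]),
        counts=np.asarray(obj["counts"], dtype=np.int64),
    )


def load_printed_tables() -> Dict[str, Union[ContingencyTable, Dict[str, ContingencyTable]]]:
    """Load the packaged count tables.

    Returns a mapping with keys ``sex_by_status``, ``hpylori_by_status``,
    ``hla_by_status``, ``atrophy_by_hla``, ``marsh_by_status`` (each a
    :class:`ContingencyTable`) and ``genotype_by_status`` (a dict of
    per-locus tables with genotype rows ordered minor-homozygote,
    heterozygote, major-homozygote).
    """
    raw = _load_raw()
    out: Dict[str, Union[ContingencyTable, Dict[str, ContingencyTable]]] = {}
    for key, obj in raw.items():
        if key in ("printed_maf", "notes"):
            continue
        if key == "genotype_by_status":
            out[key] = {locus: _to_table(tab) for locus, tab in obj.items()}
        else:
            out[key] = _to_table(obj)
    return out


def printed_maf() -> Dict[str, float]:
    """Minor-allele frequencies exactly as tabulated in the source study."""
    return dict(_load_raw()["printed_maf"])


def fixture_notes() -> Dict[str, str]:
    """Documented internal inconsistencies of the printed tables."""
    return dict(_load_raw()["notes"])
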