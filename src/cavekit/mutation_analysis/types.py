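"""Core containers for variant-level analysis.

Coordinates are 1-based inclusive throughout (VCF convention); BED inputs are
converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from ..errors import DomainError

CATEGORIES = ("structural", "regulatory", "non_coding")

VariantKey = tuple[int, str, str]  # (position, ref, alt)


@dataclass(frozen=True)
class VariantRecord:
    """One ALT allele at one position in one sample."""

    position: int
    ref: str
    alt: str
    frequency: float
    sample: str = ""

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise DomainError(f"frequency must be in [0, 1], got {self.frequency}")
        if self.ref == self.alt:
            raise DomainError("ref and alt alleles must differ")
        if self.position < 1:
            raise DomainError("positions are 1-based; must be >= 1")

    @property
    def key(self) -> VariantKey:
        return (self.position, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


class VariantTable:
    """Variant records for one sample, keyed by (position, ref, alt)."""

    def __init__(
        self,
        records: Iterable[VariantRecord] = (),
        sample: str = "",
        reference_id: str = "",
    ):
        self.sample = sample
        self.reference_id = reference_id
        self._records: dict[VariantKey, VariantRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: VariantRecord) -> None:
        if rec.key in self._records:
            raise ValueError(f"duplicate variant key {rec.key} in sample {self.sample!r}")
        self._records[rec.key] = rec

    def get(self, key: VariantKey) -> Optional[VariantRecord]:
        return self._records.get(key)

    def frequency(self, key: VariantKey) -> float:
        rec = self._records.get(key)
        return rec.frequency if rec is not None else 0.0

    def keys(self):
        return self._records.keys()

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._records

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        return (
            self.sample == other.sample
            and self.reference_id == other.reference_id
            and self._records == other._records
        )

    def __repr__(self) -> str:
        return (
            f"VariantTable(sample={self.sample!r}, reference={self.reference_id!r}, "
            f"n={len(self)})"
        )


@dataclass(frozen=True)
class GeneFeature:
    """A gene interval (1-based inclusive) with a functional category."""

    gene_id: str
    start: int
    end: int
    strand: str
    category: str
    homolog_id: Optional[str] = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise DomainError(
                f"category {self.category!r} not in {CATEGORIES}"
            )
        if self.strand not in ("+", "-"):
            raise DomainError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise DomainError(f"invalid interval [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class GenomeAnnotation:
    """Gene intervals with categories over a single reference sequence.

    Positions outside every gene are non-coding by convention.
    """

    def __init__(
        self,
        features: Iterable[GeneFeature],
        reference_id: str = "",
        reference_length: int | None = None,
    ):
        self.features = list(features)
        self.reference_id = reference_id
        self.reference_length = reference_length
        self._by_id = {f.gene_id: f for f in self.features}
        if len(self._by_id) != len(self.features):
            raise ValueError("duplicate gene ids in annotation")
        if reference_length is not None:
            for f in self.features:
                if f.end > reference_length:
                    raise DomainError(
                        f"gene {f.gene_id} extends past reference length"
                    )

    def gene(self, gene_id: str) -> GeneFeature:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def gene_ids(self) -> list[str]:
        return [f.gene_id for f in self.features]

    def genes_at(self, position: int) -> list[GeneFeature]:
        return [f for f in self.features if f.contains(position)]

    def category_at(self, position: int) -> str:
        genes = self.genes_at(position)
        return genes[0].category if genes else "non_coding"

    def __len__(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class GeneMutationIndex:
    """Sum of thresholded allele frequencies over a gene's interval."""

    gene_id: str
    value: float
    n_sites: int
    sample: str = ""
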