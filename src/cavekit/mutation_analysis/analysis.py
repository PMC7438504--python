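"""Enrichment analyses over per-round variant tables.

Order of operations follows the processing chain: frequencies are first
background-normalized against a wild-type (negative control) sample, then a
strict > 0.01 threshold is applied when summing per-gene indices.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from ..errors import DomainError
from .types import (
    CATEGORIES,
    GeneFeature,
    GeneMutationIndex,
    GenomeAnnotation,
    VariantKey,
    VariantRecord,
    VariantTable,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.01
DEFAULT_SATURATION = 0.95


def normalize_background(sample: VariantTable, wildtype: VariantTable) -> VariantTable:
    """Subtract wild-type background frequencies, clamping at zero.

    Keys absent from the wild-type table subtract 0; records whose corrected
    frequency is 0 are dropped.  Clamping events are logged.
    """
    if (
        sample.reference_id
        and wildtype.reference_id
        and sample.reference_id != wildtype.reference_id
    ):
        raise ValueError(
            f"reference mismatch: {sample.reference_id!r} vs {wildtype.reference_id!r}"
        )
    out = VariantTable(sample=sample.sample, reference_id=sample.reference_id)
    n_clamped = 0
    for rec in sample:
        corrected = rec.frequency - wildtype.frequency(rec.key)
        if corrected <= 0.0:
            if rec.frequency > 0:
                n_clamped += 1
            continue
        out.add(
            VariantRecord(
                position=rec.position,
                ref=rec.ref,
                alt=rec.alt,
                frequency=corrected,
                sample=rec.sample,
            )
        )
    if n_clamped:
        logger.info(
            "background normalization clamped %d record(s) to 0 (dropped)", n_clamped
        )
    return out


def gene_mutation_index(
    table: VariantTable,
    annotation: GenomeAnnotation,
    gene_id: str,
    threshold: float = DEFAULT_THRESHOLD,
) -> GeneMutationIndex:
    """Sum of allele frequencies strictly above ``threshold`` within the
    gene's annotated interval (indels count by their anchor position)."""
    gene = annotation.gene(gene_id)
    total = 0.0
    n_sites = 0
    for rec in table:
        if rec.frequency > threshold and gene.contains(rec.position):
            total += rec.frequency
            n_sites += 1
    return GeneMutationIndex(
        gene_id=gene_id, value=total, n_sites=n_sites, sample=table.sample
    )


def all_gene_indices(
    table: VariantTable,
    annotation: GenomeAnnotation,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[str, GeneMutationIndex]:
    return {
        gid: gene_mutation_index(table, annotation, gid, threshold)
        for gid in annotation.gene_ids()
    }


def region_fractions(
    table: VariantTable,
    annotation: GenomeAnnotation,
    threshold: float = DEFAULT_THRESHOLD,
    weight_by: str = "frequency",
) -> dict[str, float]:
    """Fraction of thresholded mutation mass per functional category.

    Positions outside every annotated gene count as non-coding.  Fractions
    sum to 1 when total mass is positive; an all-zero result is flagged via a
    log warning.  ``weight_by`` is "frequency" (default) or "count".
    """
    if weight_by not in ("frequency", "count"):
        raise ValueError("weight_by must be 'frequency' or 'count'")
    mass = {c: 0.0 for c in CATEGORIES}
    for rec in table:
        if rec.frequency > threshold:
            w = rec.frequency if weight_by == "frequency" else 1.0
            mass[annotation.category_at(rec.position)] += w
    total = sum(mass.values())
    if total <= 0:
        logger.warning("no mutation mass above threshold; all fractions are zero")
        return {c: 0.0 for c in CATEGORIES}
    return {c: mass[c] / total for c in CATEGORIES}


@dataclass
class TrajectoryResult:
    """Per-variant frequency series across ordered rounds."""

    round_labels: list[str]
    frequencies: dict[VariantKey, np.ndarray]
    saturating: list[VariantKey]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pos, ref, alt), freqs in sorted(self.frequencies.items()):
            for label, f in zip(self.round_labels, freqs):
                rows.append((pos, ref, alt, label, f))
        return pd.DataFrame(rows, columns=["pos", "ref", "alt", "round", "freq"])


def enrichment_trajectory(
    tables: Sequence[VariantTable],
    saturation: float = DEFAULT_SATURATION,
) -> TrajectoryResult:
    """Frequency vector over rounds for every variant seen in any round.

    Variants absent from a round contribute frequency 0 there.  Variants with
    final-round frequency >= ``saturation`` are flagged as saturating.
    """
    if len(tables) < 2:
        raise DomainError("need at least 2 rounds for a trajectory")
    labels = [t.sample or f"round_{i}" for i, t in enumerate(tables)]
    keys = sorted(set().union(*(set(t.keys()) for t in tables)))
    freqs = {
        key: np.array([t.frequency(key) for t in tables], dtype=float) for key in keys
    }
    saturating = [k for k, v in freqs.items() if v[-1] >= saturation]
    return TrajectoryResult(round_labels=labels, frequencies=freqs, saturating=saturating)


@dataclass
class SeriesComparison:
    """Paired gene-index comparison across two series.

    ``spearman_rho`` is a descriptive rank-concordance statistic added by
    this implementation; it is not part of the source analyses.
    """

    table: pd.DataFrame
    spearman_rho: float
    spearman_p: float


def compare_series(
    indices_a: Mapping[str, float] | Mapping[str, GeneMutationIndex],
    indices_b: Mapping[str, float] | Mapping[str, GeneMutationIndex],
    homolog_map: Optional[Mapping[str, str]] = None,
) -> SeriesComparison:
    """Pair gene indices between two series, by id or via a homolog map."""
    a = {g: _value(v) for g, v in indices_a.items()}
    b = {g: _value(v) for g, v in indices_b.items()}
    pairs = []
    if homolog_map is not None:
        for ga, gb in homolog_map.items():
            if ga in a and gb in b:
                pairs.append((ga, gb, a[ga], b[gb]))
        unmatched = sorted(set(homolog_map) - {p[0] for p in pairs})
    else:
        shared = sorted(set(a) & set(b))
        pairs = [(g, g, a[g], b[g]) for g in shared]
        unmatched = sorted(set(a) ^ set(b))
    if not pairs:
        raise ValueError(
            f"no genes could be paired between series; unmatched: {unmatched}"
        )
    df = pd.DataFrame(pairs, columns=["gene_a", "gene_b", "index_a", "index_b"])
    if len(df) > 1 and df["index_a"].nunique() > 1 and df["index_b"].nunique() > 1:
        rho, p = stats.spearmanr(df["index_a"], df["index_b"])
    else:
        rho, p = (1.0 if len(df) and (df["index_a"] == df["index_b"]).all() else np.nan, np.nan)
    return SeriesComparison(table=df, spearman_rho=float(rho), spearman_p=float(p))


def _value(v) -> float:
    return v.value if isinstance(v, GeneMutationIndex) else float(v)


# ---------------------------------------------------------------------------
# variant classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantClassification:
    kind: str  # intergenic | synonymous | missense | nonsense | inframe_indel | frameshift | boundary
    gene_id: Optional[str] = None
    aa_from: Optional[str] = None
    aa_to: Optional[str] = None
    codon_number: Optional[int] = None

    @property
    def aa_change(self) -> Optional[str]:
        if self.aa_from and self.aa_to and self.codon_number:
            return f"{self.aa_from}{self.codon_number}{self.aa_to}"
        return None


def classify_variant(
    record: VariantRecord,
    annotation: GenomeAnnotation,
    reference: str,
) -> VariantClassification:
    """Classify a variant against the annotation, codon- and strand-aware.

    SNVs inside a gene are translated through the standard genetic code with
    reverse-complementation on minus-strand genes.  Indels whose net length
    change is not a multiple of 3 are frameshifts.  Variants whose reference
    span crosses a gene boundary are flagged "boundary" and not classified.
    """
    pos = record.position
    if pos + len(record.ref) - 1 > len(reference):
        raise DomainError("variant extends past the reference sequence")
    if reference[pos - 1 : pos - 1 + len(record.ref)] != record.ref:
        raise DomainError(
            f"ref allele mismatch at {pos}: expected "
            f"{reference[pos - 1 : pos - 1 + len(record.ref)]!r}, got {record.ref!r}"
        )
    span_end = pos + len(record.ref) - 1
    genes = annotation.genes_at(pos)
    if not genes:
        return VariantClassification(kind="intergenic")
    gene = genes[0]
    if span_end > gene.end or pos < gene.start:
        return VariantClassification(kind="boundary", gene_id=gene.gene_id)

    if record.is_indel:
        delta = len(record.alt) - len(record.ref)
        kind = "frameshift" if delta % 3 != 0 else "inframe_indel"
        return VariantClassification(kind=kind, gene_id=gene.gene_id)

    if len(record.ref) == 1:
        return _classify_snv(record, gene, reference)
    # equal-length multi-base substitution: retranslate the affected segment
    return _classify_mnv(record, gene, reference)


def _gene_coding_seq(gene: GeneFeature, reference: str, mutated: str | None = None) -> str:
    seq = (mutated or reference)[gene.start - 1 : gene.end]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _classify_snv(
    record: VariantRecord, gene: GeneFeature, reference: str
) -> VariantClassification:
    if gene.strand == "+":
        offset = record.position - gene.start
        ref_base, alt_base = record.ref, record.alt
    else:
        offset = gene.end - record.position
        ref_base = str(Seq(record.ref).reverse_complement())
        alt_base = str(Seq(record.alt).reverse_complement())
    codon_idx = offset // 3
    within = offset % 3
    coding = _gene_coding_seq(gene, reference)
    codon = coding[codon_idx * 3 : codon_idx * 3 + 3]
    if len(codon) < 3:  # trailing partial codon in a non-multiple-of-3 interval
        return VariantClassification(kind="boundary", gene_id=gene.gene_id)
    assert codon[within] == ref_base
    new_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_from = str(Seq(codon).translate())
    aa_to = str(Seq(new_codon).translate())
    if aa_from == aa_to:
        kind = "synonymous"
    elif aa_to == "*":
        kind = "nonsense"
    else:
        kind = "missense"
    return VariantClassification(
        kind=kind,
        gene_id=gene.gene_id,
        aa_from=aa_from,
        aa_to=aa_to,
        codon_number=codon_idx + 1,
    )


def _classify_mnv(
    record: VariantRecord, gene: GeneFeature, reference: str
) -> VariantClassification:
    mutated = (
        reference[: record.position - 1]
        + record.alt
        + reference[record.position - 1 + len(record.ref) :]
    )
    prot_ref = str(Seq(_gene_coding_seq(gene, reference)).translate())
    prot_alt = str(Seq(_gene_coding_seq(gene, reference, mutated)).translate())
    diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    if not diffs:
        return VariantClassification(kind="synonymous", gene_id=gene.gene_id)
    i = diffs[0]
    kind = "nonsense" if prot_alt[i] == "*" else "missense"
    return VariantClassification(
        kind=kind,
        gene_id=gene.gene_id,
        aa_from=prot_ref[i],
        aa_to=prot_alt[i],
        codon_number=i + 1,
    )


# ---------------------------------------------------------------------------
# amino-acid substitution properties
# ---------------------------------------------------------------------------

#: Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Zamyatnin residue volumes (cubic Angstroms)
ZAMYATNIN_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5, "Q": 143.8,
    "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7, "L": 166.7, "K": 168.6,
    "M": 162.9, "F": 189.9, "P": 112.7, "S": 89.0, "T": 116.1, "W": 227.8,
    "Y": 193.6, "V": 140.0,
}


@dataclass(frozen=True)
class SubstitutionProperties:
    """Property shifts of a substitution; positive = mutant is larger /
    more hydrophobic than the wild-type residue."""

    delta_hydrophobicity: float
    delta_volume: float


def substitution_properties(
    aa_from: str,
    aa_to: str,
    hydrophobicity_scale: Mapping[str, float] = KYTE_DOOLITTLE,
    volume_scale: Mapping[str, float] = ZAMYATNIN_VOLUME,
) -> SubstitutionProperties:
    for aa in (aa_from, aa_to):
        if aa not in hydrophobicity_scale or aa not in volume_scale:
            raise DomainError(f"unknown amino-acid letter {aa!r}")
    return SubstitutionProperties(
        delta_hydrophobicity=hydrophobicity_scale[aa_to] - hydrophobicity_scale[aa_from],
        delta_volume=volume_scale[aa_to] - volume_scale[aa_from],
    )


# ---------------------------------------------------------------------------
# homopolymer-run shifts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomopolymerShift:
    run_start: int  # 1-based
    run_length: int
    position: int
    length_change: int
    frequency: float


def homopolymer_shifts(
    table: VariantTable,
    reference: str,
    base: str = "G",
    min_run: int = 4,
) -> list[HomopolymerShift]:
    """Indel variants anchored inside homopolymer runs of ``base``.

    Runs of length >= ``min_run`` are scanned in the reference; only
    insertion/deletion records whose anchor position lies within a run are
    reported, with net length change ``len(alt) - len(ref)``.
    """
    runs = [
        (m.start() + 1, m.end() - m.start())
        for m in re.finditer(f"{re.escape(base)}{{{min_run},}}", reference)
    ]
    out = []
    for rec in table:
        if not rec.is_indel:
            continue
        for start, length in runs:
            if start <= rec.position <= start + length - 1:
                out.append(
                    HomopolymerShift(
                        run_start=start,
                        run_length=length,
                        position=rec.position,
                        length_change=len(rec.alt) - len(rec.ref),
                        frequency=rec.frequency,
                    )
                )
                break
    return sorted(out, key=lambda s: (s.run_start, s.position))
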