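"""Readers and writers for the standard formats the pipeline consumes.

VCF reading uses cyvcf2; the writer emits the minimal single-sample-free
dialect used by frequency-only variant callers (AF and DP in INFO).  GFF3
reading goes through gffutils; BED intervals (0-based half-open) are
converted to the internal 1-based inclusive convention.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import GeneFeature, GenomeAnnotation, VariantRecord, VariantTable

logger = logging.getLogger(__name__)


def read_fasta(path) -> tuple[str, str]:
    """Return (sequence id, uppercase sequence) of the first FASTA record."""
    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def write_fasta(path, seq_id: str, sequence: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq_id}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def read_variants(vcf_path, sample_label: str = "") -> VariantTable:
    """Read a VCF into a VariantTable, one record per ALT allele.

    Allele frequency comes from the AF INFO field; when AF is absent it is
    computed from AD/DP.  Records with neither are skipped and counted.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    table = VariantTable(sample=sample_label or Path(str(vcf_path)).stem)
    n_skipped = 0
    for v in vcf:
        if not table.reference_id:
            table.reference_id = v.CHROM
        alts = v.ALT or []
        afs = _allele_frequencies(v, len(alts))
        if afs is None:
            n_skipped += len(alts)
            continue
        for alt, af in zip(alts, afs):
            table.add(
                VariantRecord(
                    position=v.POS,
                    ref=v.REF,
                    alt=alt,
                    frequency=float(min(max(af, 0.0), 1.0)),
                    sample=table.sample,
                )
            )
    if n_skipped:
        logger.warning(
            "%s: skipped %d allele record(s) lacking AF and AD/DP", vcf_path, n_skipped
        )
    return table


_AF_RE = re.compile(r"(?:^|;)AF=([^;\s]+)")


def _allele_frequencies(v, n_alt: int):
    # htslib stores INFO floats as float32; parse AF from the raw line to
    # keep full double precision (exact write -> read round trips)
    info_field = str(v).rstrip("\n").split("\t")[7]
    m = _AF_RE.search(info_field)
    if m:
        try:
            vals = np.array([float(x) for x in m.group(1).split(",")])
            if len(vals) == n_alt:
                return vals
        except ValueError:
            pass
    af = v.INFO.get("AF")
    if af is not None:
        vals = np.atleast_1d(np.asarray(af, dtype=float))
        if len(vals) == n_alt:
            return vals
    ad = v.INFO.get("AD")
    dp = v.INFO.get("DP")
    if ad is not None and dp:
        ad = np.atleast_1d(np.asarray(ad, dtype=float))
        # AD convention: ref depth first when length is n_alt + 1
        alt_depths = ad[1:] if len(ad) == n_alt + 1 else ad
        if len(alt_depths) == n_alt:
            return alt_depths / float(dp)
    return None


def write_variants(
    table: VariantTable,
    path,
    reference_length: int | None = None,
    depth: int | None = None,
) -> None:
    """Write a VariantTable as an uncompressed VCF v4.2 with AF (and DP) in INFO.

    Frequencies are formatted with the shortest decimal representation that
    round-trips the float exactly, so read-back reproduces the table.
    """
    chrom = table.reference_id or "ref"
    lines = [
        "##fileformat=VCFv4.2",
        "##source=cavekit",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
    ]
    if reference_length is not None:
        lines.append(f"##contig=<ID={chrom},length={reference_length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(table, key=lambda r: r.key):
        af_str = np.format_float_positional(
            rec.frequency, unique=True, trim="0"
        ).rstrip(".") or "0"
        info = f"AF={af_str}"
        if depth is not None:
            info = f"DP={depth};" + info
        lines.append(
            f"{chrom}\t{rec.position}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


_GFF_CATEGORY_ATTR = "functional_category"


def read_annotation_gff3(path, reference_length: int | None = None) -> GenomeAnnotation:
    """Read gene features from a GFF3; category from the functional_category
    attribute, optional homolog link from a homolog_id attribute."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features = []
    reference_id = ""
    for f in db.all_features():
        if f.featuretype not in ("gene", "CDS"):
            continue
        reference_id = reference_id or f.seqid
        category = f.attributes.get(_GFF_CATEGORY_ATTR, ["non_coding"])[0]
        gene_id = (
            f.attributes.get("ID", [None])[0]
            or f.attributes.get("gene_id", [None])[0]
            or f.id
        )
        homolog = f.attributes.get("homolog_id", [None])[0]
        features.append(
            GeneFeature(
                gene_id=gene_id,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
                category=category,
                homolog_id=homolog,
            )
        )
    return GenomeAnnotation(features, reference_id=reference_id, reference_length=reference_length)


def write_annotation_gff3(annotation: GenomeAnnotation, path) -> None:
    chrom = annotation.reference_id or "ref"
    lines = ["##gff-version 3"]
    if annotation.reference_length:
        lines.append(f"##sequence-region {chrom} 1 {annotation.reference_length}")
    for f in annotation.features:
        attrs = f"ID={f.gene_id};{_GFF_CATEGORY_ATTR}={f.category}"
        if f.homolog_id:
            attrs += f";homolog_id={f.homolog_id}"
        lines.append(
            "\t".join(
                [
                    chrom,
                    "cavekit",
                    "gene",
                    str(f.start),
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_bed(path, reference_length: int | None = None) -> GenomeAnnotation:
    """Read a 4+ column BED (chrom, start, end, name[, category[, strand]]).

    BED is 0-based half-open; start is shifted by +1 on read.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 4:
        raise ValueError("BED annotation needs at least 4 columns (incl. name)")
    features = []
    reference_id = str(df.iloc[0, 0])
    for _, row in df.iterrows():
        category = str(row[4]) if df.shape[1] > 4 else "non_coding"
        strand = str(row[5]) if df.shape[1] > 5 and str(row[5]) in "+-" else "+"
        features.append(
            GeneFeature(
                gene_id=str(row[3]),
                start=int(row[1]) + 1,
                end=int(row[2]),
                strand=strand,
                category=category,
            )
        )
    return GenomeAnnotation(features, reference_id=reference_id, reference_length=reference_length)


def read_homolog_map(path) -> dict[str, str]:
    """Two-column TSV mapping series-A gene ids to series-B gene ids."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("homolog map needs 2 columns")
    return dict(zip(df[0], df[1]))
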