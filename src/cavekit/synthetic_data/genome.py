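"""Toy genome and annotation generation for the simulator."""

from __future__ import annotations

import numpy as np

from ..errors import DomainError
from ..mutation_analysis.types import GeneFeature, GenomeAnnotation

# gene categories by genome-length share: 70% structural, 15% regulatory,
# 15% intergenic (configurable through the proportions argument)
DEFAULT_PROPORTIONS = {"structural": 0.70, "regulatory": 0.15}


def generate_genome(
    length: int,
    gc_fraction: float = 0.5,
    n_genes: int = 8,
    seed: int | np.random.Generator = 0,
    proportions: dict[str, float] | None = None,
) -> tuple[str, GenomeAnnotation]:
    """Random reference sequence plus non-overlapping gene annotation.

    Gene lengths are multiples of 3; categories are assigned to genes until
    each category's genome-length quota is met, remaining gaps are
    intergenic.  Deterministic for a given seed.
    """
    if length < 1000:
        raise DomainError("genome length must be >= 1000")
    if n_genes < 1:
        raise DomainError("n_genes must be >= 1")
    props = dict(DEFAULT_PROPORTIONS if proportions is None else proportions)
    coding_frac = sum(props.values())
    if not 0 < coding_frac < 1:
        raise DomainError("category proportions must sum to a value in (0, 1)")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    bases = np.array(list("ACGT"))
    sequence = "".join(rng.choice(bases, size=length, p=p))

    total_coding = int(length * coding_frac)
    gene_len = (total_coding // n_genes) // 3 * 3
    if gene_len < 30:
        raise DomainError(
            f"cannot fit {n_genes} genes of usable length into {length} bp"
        )
    gap = (length - gene_len * n_genes) // (n_genes + 1)
    if gap < 0:
        raise DomainError("genes cannot fit without overlap")

    # category per gene: fill structural quota first, then regulatory
    quota = {c: int(length * f) for c, f in props.items()}
    categories = []
    used = {c: 0 for c in quota}
    for _ in range(n_genes):
        if used["structural"] + gene_len <= quota["structural"]:
            cat = "structural"
        elif "regulatory" in quota and used.get("regulatory", 0) + gene_len <= quota["regulatory"]:
            cat = "regulatory"
        else:
            cat = "structural"
        used[cat] = used.get(cat, 0) + gene_len
        categories.append(cat)
    order = rng.permutation(n_genes)
    categories = [categories[i] for i in order]

    features = []
    pos = gap + 1
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            GeneFeature(
                gene_id=f"gene_{i + 1:02d}",
                start=pos,
                end=pos + gene_len - 1,
                strand=strand,
                category=categories[i],
            )
        )
        pos += gene_len + gap
    annotation = GenomeAnnotation(features, reference_id="simref", reference_length=length)
    return sequence, annotation
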