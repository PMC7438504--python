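"""Lineage-census simulator of iterated mutagenesis + thermal selection.

The population is a census of clonal genotypes (genotype = frozenset of
variant keys -> lineage count), exact for clonally reproducing phage.  One
round applies, in order: (1) mutagenesis, (2) amplification (fixation),
(3) thermal selection, (4) amplification.  Selection survival probabilities
come directly from the kinetics module — there is no reimplementation of the
decay law here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .. import kinetics
from ..errors import DomainError, ExtinctionError
from ..kinetics import DegradationModel
from ..mutation_analysis.types import GenomeAnnotation, VariantKey
from .config import CaveConfig
from .genome import generate_genome

logger = logging.getLogger(__name__)

Genotype = frozenset  # of VariantKey


@dataclass
class Population:
    """Census of genotypes.  Wild type is the empty frozenset."""

    genotypes: dict[Genotype, int]

    @classmethod
    def wild_type(cls, size: int) -> "Population":
        return cls({frozenset(): size})

    @property
    def size(self) -> int:
        return sum(self.genotypes.values())

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    def allele_frequencies(self) -> dict[VariantKey, float]:
        total = self.size
        if total == 0:
            return {}
        counts: dict[VariantKey, int] = {}
        for geno, c in self.genotypes.items():
            for key in geno:
                counts[key] = counts.get(key, 0) + c
        return {k: v / total for k, v in counts.items()}

    def copy(self) -> "Population":
        return Population(dict(self.genotypes))


class GenomeIndex:
    """Per-base position lookup for drawing substitution targets."""

    def __init__(self, reference: str):
        self.reference = reference
        arr = np.frombuffer(reference.encode(), dtype="S1")
        self.positions = {
            b: (np.flatnonzero(arr == b.encode()) + 1).astype(np.int64)
            for b in "ACGT"
        }

    def ref_base(self, position: int) -> str:
        return self.reference[position - 1]


def mutagenize(
    population: Population,
    rate: float,
    spectrum: Mapping[tuple[str, str], float],
    genome_index: GenomeIndex,
    rng: np.random.Generator,
) -> Population:
    """Apply per-lineage Poisson(rate) mutations drawn from the spectrum.

    Substitution types without any eligible reference base yield no mutation.
    A site already mutated in a lineage is not re-mutated.  rate = 0 returns
    an identical census (no-mutagenesis control arm).
    """
    if rate < 0:
        raise DomainError("mutation rate must be >= 0")
    if rate == 0 or population.size == 0:
        return population.copy()

    genos = list(population.genotypes.keys())
    counts = np.fromiter(population.genotypes.values(), dtype=np.int64, count=len(genos))
    lineage_geno = np.repeat(np.arange(len(genos)), counts)
    n_mut = rng.poisson(rate, size=lineage_geno.size)
    mutated = np.flatnonzero(n_mut > 0)

    types = list(spectrum.keys())
    probs = np.fromiter(spectrum.values(), dtype=float, count=len(types))
    probs = probs / probs.sum()

    total_draws = int(n_mut[mutated].sum())
    type_idx = rng.choice(len(types), size=total_draws, p=probs)
    # draw a target position for every mutation (uniform over eligible bases)
    pos_draws = np.empty(total_draws, dtype=np.int64)
    for ti in range(len(types)):
        sel = np.flatnonzero(type_idx == ti)
        if sel.size == 0:
            continue
        eligible = genome_index.positions.get(types[ti][0])
        if eligible is None or eligible.size == 0:
            pos_draws[sel] = -1  # infeasible substitution type: dropped
        else:
            pos_draws[sel] = eligible[rng.integers(0, eligible.size, size=sel.size)]

    out: dict[Genotype, int] = {}
    # unmutated lineages keep their genotype
    unmut_per_geno = np.bincount(
        lineage_geno[n_mut == 0], minlength=len(genos)
    )
    for gi, c in enumerate(unmut_per_geno):
        if c > 0:
            out[genos[gi]] = out.get(genos[gi], 0) + int(c)

    offset = 0
    for li in mutated:
        m = int(n_mut[li])
        geno = genos[lineage_geno[li]]
        new_keys = []
        for j in range(offset, offset + m):
            pos = int(pos_draws[j])
            if pos < 0:
                continue
            key = (pos, types[type_idx[j]][0], types[type_idx[j]][1])
            if key not in geno:
                new_keys.append(key)
        offset += m
        new_geno = geno.union(new_keys) if new_keys else geno
        out[new_geno] = out.get(new_geno, 0) + 1
    return Population(out)


def select_thermal(
    population: Population,
    temperature_k: float,
    duration_min: float,
    effect_model: Mapping[VariantKey, float],
    base_model: DegradationModel,
    rng: np.random.Generator,
) -> Population:
    """Binomially thin each genotype by its survival probability.

    A genotype's survival is the kinetics-module survival fraction of the
    base model with ln k shifted by the sum of its variants' effects
    (N0 = 1 unit), so stabilizing (negative-shift) variants strictly raise
    survival at any temperature.
    """
    if duration_min <= 0:
        raise DomainError("duration must be > 0")
    if population.size == 0:
        logger.warning("thermal selection applied to an empty population")
        return Population({})
    prob_cache: dict[float, float] = {}
    out: dict[Genotype, int] = {}
    for geno, count in population.genotypes.items():
        delta = 0.0
        for key in geno:
            delta += effect_model.get(key, 0.0)
        prob = prob_cache.get(delta)
        if prob is None:
            shifted = base_model.with_log_rate_shift(delta)
            prob = float(
                kinetics.survival_fraction(shifted, 1.0, temperature_k, duration_min)
            )
            prob_cache[delta] = prob
        survivors = int(rng.binomial(count, prob))
        if survivors > 0:
            out[geno] = survivors
    return Population(out)


def genotype_survival_probability(
    genotype: Genotype,
    temperature_k: float,
    duration_min: float,
    effect_model: Mapping[VariantKey, float],
    base_model: DegradationModel,
) -> float:
    """Analytic survival probability of a single genotype (no sampling)."""
    delta = sum(effect_model.get(key, 0.0) for key in genotype)
    shifted = base_model.with_log_rate_shift(delta)
    return float(kinetics.survival_fraction(shifted, 1.0, temperature_k, duration_min))


def amplify(
    population: Population,
    target_size: int,
    rng: np.random.Generator,
    round_index: int = -1,
) -> Population:
    """Multinomial resampling of lineages up to ``target_size``.

    Preserves allele frequencies in expectation; raises ExtinctionError on an
    empty input.
    """
    if target_size <= 0:
        raise DomainError("target_size must be > 0")
    total = population.size
    if total == 0:
        raise ExtinctionError(round_index)
    genos = list(population.genotypes.keys())
    counts = np.fromiter(population.genotypes.values(), dtype=np.float64, count=len(genos))
    new_counts = rng.multinomial(target_size, counts / counts.sum())
    return Population(
        {g: int(c) for g, c in zip(genos, new_counts) if c > 0}
    )


@dataclass
class RoundRecord:
    """Ground truth recorded after each round (index 0 = starting state)."""

    round_index: int
    selection_temperature_c: Optional[float]
    realized_survival: Optional[float]  # survivors / pre-selection size
    assay_survival: float  # analytic population-mean survival at assay condition
    assay_survival_measured: float  # binomial readout of assay_survival
    allele_frequencies: dict[VariantKey, float]
    n_genotypes: int


@dataclass
class CaveTrajectory:
    """Full ground truth of one simulated campaign."""

    config: CaveConfig
    seed: int
    reference: str
    annotation: GenomeAnnotation
    rounds: list[RoundRecord]
    stabilizing_keys: list[VariantKey]
    neutral_keys: list[VariantKey]
    background: dict[VariantKey, float] = field(default_factory=dict)
    vcf_paths: list[str] = field(default_factory=list)

    @property
    def assay_survivals(self) -> np.ndarray:
        return np.array([r.assay_survival for r in self.rounds])

    @property
    def measured_survivals(self) -> np.ndarray:
        return np.array([r.assay_survival_measured for r in self.rounds])

    def final_frequencies(self) -> dict[VariantKey, float]:
        return self.rounds[-1].allele_frequencies


def _pick_designated_sites(
    reference: str,
    annotation: GenomeAnnotation,
    n_stabilizing: int,
    n_neutral: int,
    rng: np.random.Generator,
) -> tuple[list[VariantKey], list[VariantKey]]:
    """Designated G>A sites inside structural genes: effect carriers plus
    matched neutral markers."""
    structural_positions = [
        pos
        for f in annotation.features
        if f.category == "structural"
        for pos in range(f.start, f.end + 1)
        if reference[pos - 1] == "G"
    ]
    need = n_stabilizing + n_neutral
    if len(structural_positions) < need:
        raise DomainError("not enough structural G sites for designated alleles")
    chosen = rng.choice(len(structural_positions), size=need, replace=False)
    keys = [(structural_positions[i], "G", "A") for i in chosen]
    return keys[:n_stabilizing], keys[n_stabilizing:]


def _rescue_one_survivor(
    population: Population,
    temperature_k: float,
    config: CaveConfig,
    effect_model: Mapping[VariantKey, float],
    rng: np.random.Generator,
    round_index: int,
) -> Population:
    """Sub-census selection outcome: draw one survivor ~ count x survival."""
    genos = list(population.genotypes.keys())
    weights = np.array(
        [
            count
            * genotype_survival_probability(
                geno,
                temperature_k,
                config.selection_minutes,
                effect_model,
                config.base_model,
            )
            for geno, count in population.genotypes.items()
        ]
    )
    total = weights.sum()
    if total <= 0.0:
        raise ExtinctionError(round_index)
    logger.info(
        "round %d: selection left <1 census lineage; rescuing one survivor",
        round_index,
    )
    pick = rng.choice(len(genos), p=weights / total)
    return Population({genos[pick]: 1})


def simulate_cave(
    config: CaveConfig,
    seed: Optional[int] = None,
    reference: Optional[str] = None,
    annotation: Optional[GenomeAnnotation] = None,
) -> CaveTrajectory:
    """Run the full mutate -> amplify -> select -> amplify campaign.

    Control flags: ``no_mutagenesis`` skips step 1; ``no_selection`` replaces
    selection with a pass-through (frequencies then change only by drift).

    The census (``population_size`` lineages) stands in for a much larger
    physical population, so a selection step that leaves zero census
    lineages usually means "fewer than one census unit survived", not true
    extinction.  In that case one surviving lineage is resampled with
    probability proportional to count x survival and regrown; a hard
    ExtinctionError is raised only when every genotype's survival
    probability is exactly zero.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    if reference is None or annotation is None:
        reference, annotation = generate_genome(
            config.genome_length,
            config.gc_fraction,
            config.n_genes,
            seed=rng,
        )
    genome_index = GenomeIndex(reference)

    stabilizing, neutral = _pick_designated_sites(
        reference, annotation, config.n_stabilizing, config.n_neutral_markers, rng
    )
    effect_model = {key: config.stabilizing_effect for key in stabilizing}

    lo, hi = config.background_freq_range
    background: dict[VariantKey, float] = {}
    if config.n_background_sites > 0:
        taken = set(stabilizing) | set(neutral)
        while len(background) < config.n_background_sites:
            pos = int(rng.integers(1, len(reference) + 1))
            ref_b = reference[pos - 1]
            alt_b = "ACGT"[(("ACGT".index(ref_b)) + 1) % 4]
            key = (pos, ref_b, alt_b)
            if key in taken or key in background:
                continue
            background[key] = float(rng.uniform(lo, hi))

    assay_t_k = 273.15 + config.assay_temperature_c

    def assay(pop: Population) -> tuple[float, float]:
        total = pop.size
        s = 0.0
        cache: dict[float, float] = {}
        for geno, count in pop.genotypes.items():
            delta = sum(effect_model.get(key, 0.0) for key in geno)
            p = cache.get(delta)
            if p is None:
                p = genotype_survival_probability(
                    geno, assay_t_k, config.assay_minutes, effect_model, config.base_model
                )
                cache[delta] = p
            s += count * p
        analytic = s / total if total else 0.0
        measured = float(rng.binomial(config.assay_n, analytic)) / config.assay_n
        return analytic, measured

    pop = Population.wild_type(config.population_size)
    a0, m0 = assay(pop)
    records = [
        RoundRecord(
            round_index=0,
            selection_temperature_c=None,
            realized_survival=None,
            assay_survival=a0,
            assay_survival_measured=m0,
            allele_frequencies={},
            n_genotypes=1,
        )
    ]

    for r in range(1, config.rounds + 1):
        if not config.no_mutagenesis:
            pop = mutagenize(
                pop, config.effective_mutation_rate, config.spectrum, genome_index, rng
            )
        pop = amplify(pop, config.population_size, rng, round_index=r)
        t_sel = config.selection_temperature_k(r)
        if config.no_selection:
            realized = None
        else:
            before_pop = pop
            before = pop.size
            pop = select_thermal(
                pop, t_sel, config.selection_minutes, effect_model, config.base_model, rng
            )
            realized = pop.size / before
            if pop.size == 0:
                pop = _rescue_one_survivor(
                    before_pop, t_sel, config, effect_model, rng, round_index=r
                )
        pop = amplify(pop, config.population_size, rng, round_index=r)
        a, m = assay(pop)
        records.append(
            RoundRecord(
                round_index=r,
                selection_temperature_c=t_sel - 273.15,
                realized_survival=realized,
                assay_survival=a,
                assay_survival_measured=m,
                allele_frequencies=pop.allele_frequencies(),
                n_genotypes=pop.n_genotypes,
            )
        )

    return CaveTrajectory(
        config=config,
        seed=seed,
        reference=reference,
        annotation=annotation,
        rounds=records,
        stabilizing_keys=stabilizing,
        neutral_keys=neutral,
        background=background,
    )
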