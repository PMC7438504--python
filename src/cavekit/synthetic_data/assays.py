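"""Simulated assay data: sequencing readouts, degradation time-courses and
spot tests, all with known ground truth."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from ..errors import DomainError
from ..kinetics import DegradationModel, TimeCourseSet, predict_titer
from ..mutation_analysis.io import write_variants
from ..mutation_analysis.types import VariantKey, VariantRecord, VariantTable
from ..titer import SpotTestSeries


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_sequencing(
    true_frequencies: Mapping[VariantKey, float],
    depth: int,
    error_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    sample: str = "sim",
    reference_id: str = "simref",
    vcf_path: Optional[str] = None,
    reference_length: Optional[int] = None,
) -> VariantTable:
    """Binomial sequencing readout of true allele frequencies.

    Observed allele count ~ Binomial(depth, f + error_rate * (1 - f));
    observed frequency = count / depth; sites with zero observed count are
    omitted.  Optionally writes an AF/DP-INFO VCF.
    """
    if depth < 1:
        raise DomainError("depth must be >= 1")
    rng = _as_rng(seed)
    table = VariantTable(sample=sample, reference_id=reference_id)
    for key in sorted(true_frequencies):
        f = true_frequencies[key]
        p = min(1.0, f + error_rate * (1.0 - f))
        count = int(rng.binomial(depth, p))
        if count == 0:
            continue
        pos, ref, alt = key
        table.add(
            VariantRecord(
                position=pos,
                ref=ref,
                alt=alt,
                frequency=count / depth,
                sample=sample,
            )
        )
    if vcf_path is not None:
        write_variants(table, vcf_path, reference_length=reference_length, depth=depth)
    return table


def simulate_degradation_course(
    model: DegradationModel,
    n0: float,
    temperatures_k: Sequence[float],
    timepoints_min: Sequence[float],
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 3,
) -> TimeCourseSet:
    """Titer time-courses: model prediction times mean-1 lognormal noise.

    ``noise_cv = 0`` reproduces the model exactly.  The generated set carries
    the exact initial titer per temperature group.
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    rng = _as_rng(seed)
    sigma = math.sqrt(math.log(1.0 + noise_cv**2))
    temps, times, titers, reps = [], [], [], []
    for t_k in temperatures_k:
        clean = predict_titer(model, n0, t_k, np.asarray(timepoints_min, dtype=float))
        for rep in range(n_replicates):
            if noise_cv > 0:
                mult = rng.lognormal(-0.5 * sigma**2, sigma, size=len(clean))
            else:
                mult = np.ones(len(clean))
            temps.extend([t_k] * len(clean))
            times.extend(timepoints_min)
            titers.extend(clean * mult)
            reps.extend([rep] * len(clean))
    return TimeCourseSet.from_records(
        temperature_k=temps,
        time_min=times,
        titer=titers,
        replicate=reps,
        initial_titer={t_k: n0 for t_k in temperatures_k},
    )


def simulate_spot_test(
    true_titer: float,
    dilution_fractions: Sequence[float],
    plated_volume_ml: float,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 1,
) -> SpotTestSeries:
    """Poisson plaque counts: count ~ Poisson(titer * dilution * volume)."""
    if true_titer < 0:
        raise DomainError("true_titer must be >= 0")
    rng = _as_rng(seed)
    dil, counts, reps = [], [], []
    for rep in range(n_replicates):
        for d in dilution_fractions:
            dil.append(d)
            counts.append(int(rng.poisson(true_titer * d * plated_volume_ml)))
            reps.append(rep)
    return SpotTestSeries.from_records(
        dil, counts, reps, plated_volume_ml=plated_volume_ml
    )
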