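"""Configuration for the directed-evolution process simulator."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

from ..errors import DomainError
from ..kinetics import DegradationModel, T_REF_DEFAULT_K

#: EMS-biased substitution spectrum: 0.9 mass on G>A / C>T transitions,
#: remainder spread evenly over the other ten substitution types.  The
#: alkylation bias is an assumption of the simulator, not a measured truth.
EMS_SPECTRUM: dict[tuple[str, str], float] = {}
for _ref in "ACGT":
    for _alt in "ACGT":
        if _ref != _alt:
            EMS_SPECTRUM[(_ref, _alt)] = 0.01
EMS_SPECTRUM[("G", "A")] = 0.45
EMS_SPECTRUM[("C", "T")] = 0.45


def default_base_model() -> DegradationModel:
    """Degradation model of the simulated wild-type phage.

    Chosen so that a 60 min incubation at the selection ramp's starting
    temperature is already strongly lethal to the wild type (survival ~1e-4)
    while carriers of a stabilizing allele survive well — the regime in which
    improvement is rapid in early rounds and plateaus later.
    """
    return DegradationModel(
        order_n=1.0,
        k_ref=0.30,
        activation_energy=5.0e4,
        t_ref=T_REF_DEFAULT_K,
    )


@dataclass
class CaveConfig:
    """Parameters of one simulated evolution campaign.

    The mutation ``dose`` knob scales the per-genome Poisson rate linearly;
    the low/high mutagen regimes differ 180-fold in dose with no claim of
    chemical realism.  Rounds and population are desk-scale defaults chosen
    to keep 20-seed property checks within a few CPU-minutes.
    """

    # genome
    genome_length: int = 12_000
    gc_fraction: float = 0.5
    n_genes: int = 8
    reference_fasta: Optional[str] = None
    annotation_gff3: Optional[str] = None
    # population process
    population_size: int = 100_000
    rounds: int = 12
    mutation_rate: float = 0.25  # per genome per round at dose 1.0
    dose: float = 1.0
    spectrum: dict = field(default_factory=lambda: dict(EMS_SPECTRUM))
    # selection schedule
    temp_start_c: float = 50.0
    temp_end_c: float = 68.0
    selection_minutes: float = 60.0
    # effect model
    base_model: DegradationModel = field(default_factory=default_base_model)
    n_stabilizing: int = 4
    stabilizing_effect: float = -6.0  # shift in ln k per allele
    n_neutral_markers: int = 4
    # control arms
    no_mutagenesis: bool = False
    no_selection: bool = False
    # sequencing / assays
    depth: int = 1000
    error_rate: float = 0.0
    n_background_sites: int = 25
    background_freq_range: tuple[float, float] = (0.002, 0.03)
    assay_temperature_c: float = 60.0
    assay_minutes: float = 60.0
    assay_n: int = 50  # plaque-count scale of the measured survival readout
    seed: int = 0

    def __post_init__(self):
        total = sum(self.spectrum.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9, abs_tol=1e-9):
            raise DomainError(f"substitution spectrum must sum to 1, sums to {total}")
        if self.rounds < 1:
            raise DomainError("rounds must be >= 1")
        if self.population_size < 100:
            raise DomainError("population_size must be >= 100")
        if self.genome_length < 1000:
            raise DomainError("genome_length must be >= 1000")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise DomainError("gc_fraction must be in [0, 1]")
        if self.mutation_rate < 0 or self.dose < 0:
            raise DomainError("mutation_rate and dose must be >= 0")

    @property
    def effective_mutation_rate(self) -> float:
        return self.mutation_rate * self.dose

    def selection_temperature_k(self, round_index: int) -> float:
        """Linear ramp from temp_start to temp_end over the campaign (K)."""
        if self.rounds == 1:
            frac = 0.0
        else:
            frac = (round_index - 1) / (self.rounds - 1)
        return 273.15 + self.temp_start_c + frac * (self.temp_end_c - self.temp_start_c)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_model"] = self.base_model.to_dict()
        d["spectrum"] = {f"{r}>{a}": p for (r, a), p in self.spectrum.items()}
        d["background_freq_range"] = list(self.background_freq_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CaveConfig":
        d = dict(d)
        if "base_model" in d and isinstance(d["base_model"], dict):
            d["base_model"] = DegradationModel.from_dict(d["base_model"])
        if "spectrum" in d and d["spectrum"] and isinstance(
            next(iter(d["spectrum"])), str
        ):
            d["spectrum"] = {
                (key.split(">")[0], key.split(">")[1]): float(p)
                for key, p in d["spectrum"].items()
            }
        if "background_freq_range" in d:
            d["background_freq_range"] = tuple(d["background_freq_range"])
        return cls(**d)

    @classmethod
    def from_toml(cls, path) -> "CaveConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))
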