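import numpy as np
import pytest

from cavekit.mutation_analysis import GeneFeature, GenomeAnnotation
from cavekit.synthetic_data import CaveConfig, simulate_cave

N_EVOLUTION_SEEDS = 20


@pytest.fixture(scope="session")
def evolution_arms():
    """20-seed campaigns for the full protocol and both control arms.

    Session-scoped: these back several property tests and the end-to-end
    acceptance criterion, and cost ~2 CPU-minutes together.
    """
    seeds = range(1, N_EVOLUTION_SEEDS + 1)
    return {
        "full": [simulate_cave(CaveConfig(), seed=s) for s in seeds],
        "no_selection": [
            simulate_cave(CaveConfig(no_selection=True), seed=s) for s in seeds
        ],
        "no_mutagenesis": [
            simulate_cave(CaveConfig(no_mutagenesis=True), seed=s) for s in seeds
        ],
    }


@pytest.fixture()
def toy_reference():
    # two genes: plus-strand at 11..40, minus-strand at 51..80, rest intergenic
    rng = np.random.default_rng(42)
    seq = list(rng.choice(list("ACGT"), size=100))
    seq[10:40] = list("ATGAAACCCGGGTTTACGTACGATCGATAA")
    seq[50:80] = list("TTACGATCGATCGTACGTAAACCCGGGCAT")
    return "".join(seq)


@pytest.fixture()
def toy_annotation():
    return GenomeAnnotation(
        [
            GeneFeature("geneA", 11, 40, "+", "structural"),
            GeneFeature("geneB", 51, 80, "-", "regulatory"),
        ],
        reference_id="toy",
        reference_length=100,
    )
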