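import numpy as np
import pytest

import techvar as tv


@pytest.fixture(scope="session")
def reference_table():
    """Published 9x9 replicate cross-classification (60,277 regions)."""
    return tv.load_reference_agreement_table()


@pytest.fixture(scope="session")
def small_experiment():
    """2000-gene library, two technical replicates of 50k reads, pileups."""
    library = tv.build_library(n_genes=2000, seed=11)
    reps = tv.simulate_experiment(library, 2, 50_000, base_seed=12)
    genome = tv.generate_genome(2000, seed=11)
    tracks = tv.generate_pileups(genome, reps, seed=13)
    quants = tv.quantify_experiment(tracks, genome.gene_regions)
    return {
        "library": library,
        "reps": reps,
        "genome": genome,
        "tracks": tracks,
        "quants": quants,
    }


def random_contingency(rng, k=None, n_max=100_000):
    """Random k x k count table for oracle comparisons."""
    if k is None:
        k = rng.integers(2, 10)
    n = rng.integers(k, n_max)
    probs = rng.dirichlet(np.ones(k * k))
    counts = rng.multinomial(n, probs).reshape(k, k)
    return tv.ContingencyTable(counts)
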