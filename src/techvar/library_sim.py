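"""Generative model of a sequencing library and its technical replicates.

A prepared RNA-seq library is a tube containing on the order of 10**12 cDNA
molecules, of which a single flow-cell lane sequences only a few tens of
millions — a sampling fraction around 1e-5.  This module models that
situation directly: a fixed pool of molecules distributed over genes, and
each technical replicate as an independent draw of ``n_reads`` molecules
from the pool.  Between-lane variation produced by this model is pure
sampling noise, which is exactly the null hypothesis the downstream
agreement statistics interrogate.

The expression profile over genes follows a gamma(shape=2, scale=1) density
evaluated at an integer "expression bin" drawn uniformly from 0..17 per
gene, so that most genes receive few molecules and a minority receive many.
A bin of 0 gives density 0: such genes are present in the annotation but
absent from the library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

AVOGADRO = 6.022e23

#: Study defaults: 20,000 genes, a 10 nM / 400 uL library (2.408e12
#: molecules), 30 million reads per lane.
DEFAULT_N_GENES = 20_000
DEFAULT_TOTAL_MOLECULES = 2_408_000_000_000
DEFAULT_N_READS = 30_000_000
DEFAULT_GAMMA_SHAPE = 2.0
DEFAULT_GAMMA_SCALE = 1.0
DEFAULT_SUPPORT_MAX = 17


@dataclass(frozen=True)
class ProtocolSpec:
    """Library-preparation protocol parameters.

    Parameters
    ----------
    concentration_nm : float
        Final library concentration in nmol/L.
    volume_ul : float
        Library volume in microliters.
    insert_size_bp : int
        Mean insert size in base pairs (descriptive only).
    starting_mass_ng : float
        Starting mRNA mass in nanograms (descriptive only).
    """

    concentration_nm: float = 10.0
    volume_ul: float = 400.0
    insert_size_bp: int = 250
    starting_mass_ng: float = 100.0

    def __post_init__(self) -> None:
        if self.concentration_nm < 0:
            raise ValueError("concentration must be non-negative")
        if self.volume_ul < 0:
            raise ValueError("volume must be non-negative")


@dataclass(frozen=True)
class LibraryModel:
    """A virtual molecule pool: per-gene molecule counts summing to Z."""

    n_genes: int
    support_values: np.ndarray
    densities: np.ndarray
    molecule_counts: np.ndarray
    total_molecules: int
    gamma_shape: float
    gamma_scale: float
    seed: int

    @property
    def proportions(self) -> np.ndarray:
        """Per-gene sampling probabilities g_i / Z."""
        return self.molecule_counts / self.total_molecules


@dataclass(frozen=True)
class ReplicateCounts:
    """Per-gene read tallies for one technical replicate (one lane)."""

    replicate_id: str
    read_counts: np.ndarray
    n_reads: int
    seed: int


def estimate_library_molecules(protocol: ProtocolSpec) -> float:
    """Number of molecules in the library tube.

    moles in tube = concentration (nmol/L) * volume (L) * 1e-9; multiplying
    by Avogadro's number gives the molecule count.  A 10 nM, 400 uL library
    holds 4 pmol, i.e. about 2.408e12 molecules.
    """
    moles = protocol.concentration_nm * 1e-9 * protocol.volume_ul * 1e-6
    return moles * AVOGADRO


def sampling_fraction(n_reads: int, n_molecules: float) -> float:
    """Fraction of the molecule pool sequenced in one lane.

    30 million reads from a 2.408e12-molecule library is ~1.3e-5 (0.0013%).
    """
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    if n_reads < 0 or n_reads > n_molecules:
        raise ValueError("n_reads must lie in [0, n_molecules]")
    return n_reads / n_molecules


def build_library(
    n_genes: int = DEFAULT_N_GENES,
    total_molecules: int = DEFAULT_TOTAL_MOLECULES,
    gamma_shape: float = DEFAULT_GAMMA_SHAPE,
    gamma_scale: float = DEFAULT_GAMMA_SCALE,
    support_max: int = DEFAULT_SUPPORT_MAX,
    seed: int = 0,
) -> LibraryModel:
    """Construct the virtual molecule pool.

    Each gene draws an integer expression bin S_i uniformly from
    {0, ..., support_max} (inclusive); its relative expression t_i is the
    gamma(shape, scale) density at S_i, and its molecule count is
    ``round(t_i / sum(t) * total_molecules)`` (round-half-to-even).  The
    realized total Z is the sum of rounded counts and therefore only
    approximately equals ``total_molecules``.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if total_molecules < 1:
        raise ValueError("total_molecules must be >= 1")
    if support_max < 1:
        raise ValueError("support_max must be >= 1")
    rng = np.random.default_rng(seed)
    support = rng.integers(0, support_max + 1, size=n_genes)
    densities = stats.gamma.pdf(support, a=gamma_shape, scale=gamma_scale)
    total_density = densities.sum()
    if total_density == 0:
        raise ValueError(
            "all gene densities are zero (every support draw hit a "
            "zero-density point); increase n_genes or reseed"
        )
    counts = np.rint(densities / total_density * total_molecules).astype(np.int64)
    z = int(counts.sum())
    return LibraryModel(
        n_genes=n_genes,
        support_values=support,
        densities=densities,
        molecule_counts=counts,
        total_molecules=z,
        gamma_shape=gamma_shape,
        gamma_scale=gamma_scale,
        seed=seed,
    )


def sample_replicate(
    library: LibraryModel, n_reads: int, seed: int, replicate_id: str = "rep"
) -> ReplicateCounts:
    """Draw one technical replicate from the pool.

    Sampling n_reads molecule labels uniformly from 1..Z and tallying per
    gene is distributionally a multinomial(n_reads, g/Z) draw, which is how
    the tally is computed.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if library.total_molecules <= 0:
        raise ValueError("library has no molecules")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, library.proportions)
    return ReplicateCounts(
        replicate_id=replicate_id,
        read_counts=counts.astype(np.int64),
        n_reads=n_reads,
        seed=seed,
    )


def simulate_experiment(
    library: LibraryModel,
    n_replicates: int,
    n_reads: int = DEFAULT_N_READS,
    base_seed: int = 0,
) -> list[ReplicateCounts]:
    """Independent technical replicates with seeds base_seed + index."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return [
        sample_replicate(
            library, n_reads, seed=base_seed + i, replicate_id=f"rep{i + 1}"
        )
        for i in range(n_replicates)
    ]
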