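"""Coalescent predictions of per-species nucleotide diversity.

Each species' forward-time history in the local community (abundance
trajectory, first colonization step, number of immigration arrivals) is
rescaled into a two-population coalescent model: a local deme that diverged
from its metacommunity source population at time ``tau`` and continues to
receive immigrants (backward-time migration) until the divergence.  Sequence
variation is simulated under an infinite-sites model with msprime and
summarised as per-site nucleotide diversity pi.

Rescaling conventions
---------------------
* Moran steps are converted to Wright--Fisher generations with the factor
  ``2 / J`` and multiplied by ``alpha`` (individuals per deme), so that times
  and sizes are consistent with a local census of ``J * alpha`` organisms.
* The local effective size is ``alpha`` times the harmonic mean of the
  recorded abundance trajectory -- the classical effective-size summary of a
  fluctuating population.
* The backward migration rate is the number of recorded immigration arrivals
  divided by the total elapsed time in generations; species born in situ get
  migration rate 0 and a divergence time at their speciation step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import msprime
import numpy as np

from ecoassembly.local_assembly import LocalCommunity, SpeciesHistory

__all__ = [
    "CoalescentSetup",
    "GeneticDiversityResult",
    "harmonic_mean_abundance",
    "rescale_history",
    "simulate_species_pi",
    "nucleotide_diversity",
    "community_genetic_diversities",
]

_MIN_TAU = 1e-6  # msprime split times must be strictly positive


@dataclass
class CoalescentSetup:
    """Demographic model for one species, in individuals and generations."""

    Ne_local: float
    Ne_source: float
    tau: float
    mig_rate: float
    n_samples: int = 10
    L: int = 570
    mu: float = 5e-7

    def __post_init__(self) -> None:
        if self.Ne_local < 1:
            raise ValueError("Ne_local must be >= 1")
        if self.Ne_source < 1:
            raise ValueError("Ne_source must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.mig_rate < 0:
            raise ValueError("mig_rate must be >= 0")
        if self.L < 1:
            raise ValueError("locus length L must be >= 1")
        if self.mu < 0:
            raise ValueError("mutation rate mu must be >= 0")


@dataclass
class GeneticDiversityResult:
    """Per-species sequence-diversity summary."""

    pi: float
    n_samples: int
    segregating_sites: int


def harmonic_mean_abundance(trajectory: Sequence[float] | np.ndarray) -> float:
    """Harmonic mean ``n / sum(1/x_i)`` of a positive abundance trajectory."""
    x = np.asarray(trajectory, dtype=float)
    if x.size == 0:
        raise ValueError("empty abundance trajectory")
    if np.any(x <= 0):
        raise ValueError("abundance trajectory must be strictly positive")
    return float(x.size / np.sum(1.0 / x))


def rescale_history(
    history: SpeciesHistory,
    J: int,
    alpha: int,
    meta_abundance: int,
    elapsed_steps: int,
    n_samples: int = 10,
    L: int = 570,
    mu: float = 5e-7,
) -> CoalescentSetup:
    """Convert a forward-time species history into a coalescent setup.

    ``tau`` is the time since first colonization (or in-situ speciation) in
    Wright--Fisher generations: forward Moran steps scaled by ``2 / J`` and
    by ``alpha``.  The migration rate is the recorded number of immigration
    arrivals per elapsed generation (zero for in-situ species).
    """
    step_to_gen = (2.0 / J) * alpha
    total_gens = max(elapsed_steps * step_to_gen, _MIN_TAU)
    ne_local = alpha * harmonic_mean_abundance(history.trajectory)
    if history.origin == "local_speciation":
        tau = (elapsed_steps - history.origin_step) * step_to_gen
        mig = 0.0
    else:
        tau = (elapsed_steps - history.first_colonization_step) * step_to_gen
        mig = history.colonization_count / total_gens
    return CoalescentSetup(
        Ne_local=max(ne_local, 1.0),
        Ne_source=max(alpha * meta_abundance, 1.0),
        tau=max(tau, _MIN_TAU),
        mig_rate=mig,
        n_samples=n_samples,
        L=L,
        mu=mu,
    )


def simulate_species_pi(
    setup: CoalescentSetup, seed: int | None = None
) -> GeneticDiversityResult:
    """Simulate one locus for one species and return its nucleotide diversity.

    The model is a local population of size ``Ne_local`` splitting from a
    source of size ``Ne_source`` at time ``tau``, with backward-time
    migration of local lineages into the source at rate ``mig_rate`` per
    lineage per generation.  Gene copies are haploid; mutations follow an
    infinite-sites model at per-site rate ``mu`` over ``L`` sites.
    """
    if setup.n_samples < 2:
        raise ValueError("n_samples must be >= 2 for pi to be defined")
    rng = np.random.default_rng(seed)
    s1, s2 = (int(s) for s in rng.integers(1, 2**31, size=2))

    dem = msprime.Demography()
    dem.add_population(name="local", initial_size=setup.Ne_local)
    dem.add_population(name="source", initial_size=setup.Ne_source)
    if setup.mig_rate > 0:
        # forward-time immigration source -> local; backwards in time local
        # lineages migrate into the source at this rate
        dem.set_migration_rate(source="source", dest="local", rate=setup.mig_rate)
    dem.add_population_split(time=setup.tau, derived=["local"], ancestral="source")
    ts = msprime.sim_ancestry(
        samples={"local": setup.n_samples},
        demography=dem,
        ploidy=1,
        sequence_length=setup.L,
        random_seed=s1,
    )
    ts = msprime.sim_mutations(ts, rate=setup.mu, random_seed=s2, discrete_genome=False)
    pi = float(ts.diversity(mode="site", span_normalise=True))
    return GeneticDiversityResult(
        pi=pi, n_samples=setup.n_samples, segregating_sites=int(ts.num_sites)
    )


def nucleotide_diversity(sequences: Iterable[str]) -> float:
    """Per-site pi of an alignment: mean pairwise Hamming distance / length.

    Accepts any iterable of equal-length strings (or objects with a string
    representation, e.g. Bio.Seq records' ``.seq``).
    """
    seqs = [str(s).upper() for s in sequences]
    n = len(seqs)
    if n < 2:
        raise ValueError("nucleotide diversity requires at least 2 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must all have equal length")
    if L == 0:
        raise ValueError("sequences must be non-empty")
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, L)
    total = 0
    for i in range(n - 1):
        total += int(np.sum(arr[i + 1 :] != arr[i]))
    n_pairs = n * (n - 1) // 2
    return total / n_pairs / L


def community_genetic_diversities(
    community: LocalCommunity,
    n_samples: int = 10,
    L: int = 570,
    mu: float = 5e-7,
    sampling_spec: Mapping[int, tuple[int, int]] | None = None,
    seed: int | None = None,
) -> dict[int, GeneticDiversityResult]:
    """Simulate pi for every species present in the final local community.

    ``sampling_spec`` optionally overrides ``(n_samples, L)`` per species id,
    mirroring the requirement that coalescent simulations match the observed
    per-species sample sizes.  Species whose census ``abundance * alpha`` is
    below the requested sample size are sampled at what is available; species
    with fewer than 2 available gene copies are skipped.
    """
    params = community.params
    alpha = params.alpha
    counts = community.species_counts()
    meta_abund = community.meta.abundance_array
    rng = np.random.default_rng(seed)

    results: dict[int, GeneticDiversityResult] = {}
    for sp in community.local_species():
        sp = int(sp)
        n_sp, L_sp = (n_samples, L)
        if sampling_spec is not None and sp in sampling_spec:
            n_sp, L_sp = sampling_spec[sp]
        available = int(counts[sp]) * alpha
        n_use = min(n_sp, available)
        if n_use < 2:
            continue
        hist = community.histories[sp]
        setup = rescale_history(
            hist,
            J=params.J,
            alpha=alpha,
            meta_abundance=int(meta_abund[_source_species(community, sp)]),
            elapsed_steps=community.step_count,
            n_samples=n_use,
            L=L_sp,
            mu=mu,
        )
        species_seed = int(rng.integers(1, 2**31))
        try:
            results[sp] = simulate_species_pi(setup, seed=species_seed)
        except Exception as err:  # surface offending species
            raise RuntimeError(
                f"coalescent simulation failed for species "
                f"{community.species_label(sp)}: {err}"
            ) from err
    return results


def _source_species(community: LocalCommunity, sp: int) -> int:
    """Metacommunity ancestor of a species (itself if not born in situ)."""
    while sp >= community.n_meta:
        parent = community.histories[sp].parent
        if parent is None:  # defensive; in-situ species always have parents
            return 0
        sp = parent
    return sp
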