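"""Forward-time individual-based assembly of the local community.

The local community holds a fixed number ``J`` of demes (cohorts of ``alpha``
identical individuals).  Assembly proceeds in discrete Moran steps: one deme
occupant dies and is immediately replaced, with probability ``m`` by an
immigrant drawn from the metacommunity in proportion to regional abundance,
otherwise by the offspring of a uniformly chosen surviving local individual.
Each birth (local or immigrant) triggers point-mutation speciation with
probability ``nu``: the newborn founds a new species at abundance 1 whose
trait is a Gaussian perturbation of the parent trait.

Death can be ecologically neutral (uniform) or trait-mediated:

* environmental filtering -- individuals far from a local trait optimum
  ``z_E`` die preferentially: raw weight ``1 - exp(-(z - z_E)^2 / s_E)``;
* competition -- individuals close to the local abundance-weighted mean
  trait die preferentially: raw weight ``exp(-(z - z_bar)^2 / s_E)``.

Progress toward dynamic equilibrium is tracked by ``Lambda``, the fraction of
demes that have experienced at least one replacement since initialization:
0 in the founder state, 1 once all initial information has been erased.
Abundance trajectories, colonization times and counts are recorded per
species; they are the forward-time inputs to the coalescent rescaling of the
:mod:`ecoassembly.popgen` module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecoassembly.metacommunity import Metacommunity

__all__ = [
    "AssemblyParams",
    "SpeciesHistory",
    "LocalCommunity",
    "NonconvergenceError",
    "run_assembly",
]

_MODELS = ("neutral", "filtering", "competition")
_INIT_MODES = ("metacommunity_sample", "monodominance")
_SPECIATION_MODES = ("none", "point_mutation")
_WEIGHT_FLOOR = 1e-12


class NonconvergenceError(RuntimeError):
    """Raised when the max-step guard fires before Lambda reaches its target."""

    def __init__(self, lambda_reached: float, target: float, steps: int):
        self.lambda_reached = lambda_reached
        super().__init__(
            f"assembly stopped after {steps} steps at Lambda="
            f"{lambda_reached:.4f} < target {target:.4f}"
        )


@dataclass
class AssemblyParams:
    """Parameters of the local forward-time process.

    ``s_E`` (ecological strength) and ``z_E`` (local trait optimum) are
    ignored under the neutral model; ``alpha`` (individuals per deme) is not
    consumed by the forward process itself but carried through to the
    coalescent rescaling.
    """

    J: int
    m: float
    nu: float = 0.0
    model: str = "neutral"
    s_E: float = 1.0
    z_E: float = 0.0
    Lambda_target: float = 0.75
    init_mode: str = "metacommunity_sample"
    speciation_mode: str = "point_mutation"
    alpha: int = 1000
    seed: int | None = None
    max_steps: int = 10**8

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("immigration probability m must be in [0, 1]")
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("speciation probability nu must be in [0, 1]")
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        if self.model != "neutral" and self.s_E <= 0:
            raise ValueError("s_E must be > 0 for non-neutral models")
        if not 0.0 <= self.Lambda_target <= 1.0:
            raise ValueError("Lambda_target must be in [0, 1]")
        if self.init_mode not in _INIT_MODES:
            raise ValueError(f"init_mode must be one of {_INIT_MODES}")
        if self.speciation_mode not in _SPECIATION_MODES:
            raise ValueError(f"speciation_mode must be one of {_SPECIATION_MODES}")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")


@dataclass
class SpeciesHistory:
    """Forward-time record for one locally observed species."""

    species: int
    origin: str  # "immigrant" | "local_speciation"
    first_colonization_step: int
    colonization_count: int = 0
    parent: int | None = None
    origin_step: int = 0
    trajectory: list[int] = field(default_factory=list)


class LocalCommunity:
    """Mutable state of the local Moran process.

    Species are integer indices: ``0 .. S_M-1`` are metacommunity species (in
    metacommunity label order), indices beyond that are in-situ species
    created by point-mutation speciation.  ``demes`` maps each of the ``J``
    demes to the species occupying it.
    """

    def __init__(
        self,
        meta: Metacommunity,
        params: AssemblyParams,
        rng: np.random.Generator | None = None,
    ):
        self.meta = meta
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)

        self.n_meta = meta.S_M
        meta_abund = meta.abundance_array.astype(float)
        self._meta_cum = np.cumsum(meta_abund)
        self._meta_total = self._meta_cum[-1]
        self.traits = meta.trait_array.copy()  # grows as species speciate

        mp = meta.params
        if mp is not None:
            self._spec_var = mp.sigma2_M / (mp.lam * (1.0 + mp.epsilon))
        else:
            self._spec_var = 1.0

        J = params.J
        if params.init_mode == "monodominance":
            dominant = int(np.argmax(meta_abund))
            self.demes = np.full(J, dominant, dtype=np.int64)
        else:
            u = self.rng.random(J) * self._meta_total
            self.demes = np.searchsorted(self._meta_cum, u).astype(np.int64)
        self.founder = np.ones(J, dtype=bool)
        self.step_count = 0
        self._replaced = 0
        self._record_every = max(J // 2, 1)

        self.histories: dict[int, SpeciesHistory] = {}
        self.phylo_records: list[tuple[int, int, int]] = []  # (child, parent, step)
        for sp in np.unique(self.demes):
            self.histories[int(sp)] = SpeciesHistory(
                species=int(sp),
                origin="immigrant",
                first_colonization_step=0,
                colonization_count=1,
            )
        self._record_trajectories()

    # ------------------------------------------------------------------
    @property
    def J(self) -> int:
        return self.params.J

    @property
    def Lambda(self) -> float:
        """Fraction of demes replaced at least once since initialization."""
        return self._replaced / self.J

    def species_counts(self) -> np.ndarray:
        return np.bincount(self.demes, minlength=len(self.traits))

    def richness(self) -> int:
        return int(np.count_nonzero(np.bincount(self.demes)))

    def local_species(self) -> np.ndarray:
        return np.unique(self.demes)

    def local_traits(self) -> np.ndarray:
        """Species-level trait values of the species currently present."""
        return self.traits[self.local_species()]

    # ------------------------------------------------------------------
    def death_weights(self) -> np.ndarray:
        """Per-deme death probabilities (length J, summing to 1)."""
        p = self.params
        J = p.J
        if p.model == "neutral":
            return np.full(J, 1.0 / J)
        z = self.traits[self.demes]
        if p.model == "filtering":
            raw = 1.0 - np.exp(-((z - p.z_E) ** 2) / p.s_E)
        else:  # competition
            z_bar = z.mean()  # abundance-weighted local mean trait
            raw = np.exp(-((z - z_bar) ** 2) / p.s_E)
        raw = np.maximum(raw, _WEIGHT_FLOOR)
        return raw / raw.sum()

    # ------------------------------------------------------------------
    def step(self) -> None:
        """One Moran replacement event (death + birth, possibly speciation)."""
        p = self.params
        rng = self.rng
        J = p.J

        if p.model == "neutral":
            dead = int(rng.integers(J))
        else:
            w = self.death_weights()
            c = np.cumsum(w)
            dead = int(np.searchsorted(c, rng.random() * c[-1]))
            dead = min(dead, J - 1)

        step_next = self.step_count + 1
        if rng.random() < p.m:
            # immigrant drawn in proportion to metacommunity abundance
            sp = int(
                np.searchsorted(self._meta_cum, rng.random() * self._meta_total)
            )
            hist = self.histories.get(sp)
            if hist is None:
                self.histories[sp] = SpeciesHistory(
                    species=sp,
                    origin="immigrant",
                    first_colonization_step=step_next,
                    colonization_count=1,
                )
            else:
                hist.colonization_count += 1
        else:
            # offspring of a surviving local individual (not the deceased)
            r = int(rng.integers(J - 1)) if J > 1 else 0
            if r >= dead:
                r += 1
            sp = int(self.demes[r])

        if p.speciation_mode == "point_mutation" and p.nu > 0 and rng.random() < p.nu:
            sp = self._speciate(sp, step_next)

        self.demes[dead] = sp
        if self.founder[dead]:
            self.founder[dead] = False
            self._replaced += 1
        self.step_count = step_next
        if self.step_count % self._record_every == 0:
            self._record_trajectories()

    def _speciate(self, parent: int, step: int) -> int:
        """Point-mutation speciation: found a new species from ``parent``.

        The new trait is Normal(parent trait, sigma2_M / (lam * (1 + eps))),
        the expected trait variance between parent and offspring species in
        the metacommunity diversification process.
        """
        new_id = len(self.traits)
        trait = self.rng.normal(self.traits[parent], np.sqrt(self._spec_var))
        self.traits = np.append(self.traits, trait)
        self.histories[new_id] = SpeciesHistory(
            species=new_id,
            origin="local_speciation",
            first_colonization_step=step,
            colonization_count=0,
            parent=parent,
            origin_step=step,
        )
        self.phylo_records.append((new_id, parent, step))
        return new_id

    def _record_trajectories(self) -> None:
        counts = np.bincount(self.demes, minlength=len(self.traits))
        for sp in np.nonzero(counts)[0]:
            self.histories[int(sp)].trajectory.append(int(counts[sp]))

    # ------------------------------------------------------------------
    def run(
        self,
        lambda_target: float | None = None,
        max_steps: int | None = None,
    ) -> "LocalCommunity":
        """Iterate :meth:`step` until ``Lambda`` reaches its target."""
        target = self.params.Lambda_target if lambda_target is None else lambda_target
        guard = self.params.max_steps if max_steps is None else max_steps
        while self.Lambda < target:
            if self.step_count >= guard:
                raise NonconvergenceError(self.Lambda, target, self.step_count)
            self.step()
        # close the record so every species present at the end has at least
        # one trajectory point, regardless of when it arrived
        if self.step_count % self._record_every != 0:
            self._record_trajectories()
        return self

    # ------------------------------------------------------------------
    def history_table(self) -> pd.DataFrame:
        """Per-species history as a tidy table (trajectory tab-joined)."""
        rows = []
        for sp in sorted(self.histories):
            h = self.histories[sp]
            rows.append(
                {
                    "species_id": self.species_label(sp),
                    "origin": h.origin,
                    "first_colonization_step": h.first_colonization_step,
                    "colonization_count": h.colonization_count,
                    "trajectory": ",".join(str(x) for x in h.trajectory),
                }
            )
        return pd.DataFrame(rows)

    def species_label(self, sp: int) -> str:
        if sp < self.n_meta:
            return self.meta.labels[sp]
        return f"x{sp}"

    def local_phylogeny_newick(self) -> str:
        """In-situ speciation records as a newick forest (one tree per
        immigrant clade, branch lengths in Moran steps)."""
        children: dict[int, list[tuple[int, int]]] = {}
        roots: set[int] = set()
        involved: set[int] = set()
        for child, parent, step in self.phylo_records:
            children.setdefault(parent, []).append((child, step))
            involved.add(child)
            involved.add(parent)
        for sp in involved:
            if sp < self.n_meta or self.histories[sp].parent is None:
                roots.add(sp)

        end = self.step_count

        def render(sp: int, born: int) -> str:
            kids = children.get(sp, [])
            label = self.species_label(sp)
            if not kids:
                return f"{label}:{end - born}"
            parts = [render(c, s) for c, s in kids]
            # the parent lineage itself continues alongside its descendants
            first_split = min(s for _, s in kids)
            parts.append(f"{label}:{end - first_split}")
            return f"({','.join(parts)}):{first_split - born}"

        return "\n".join(f"{render(r, 0)};" for r in sorted(roots))


def run_assembly(
    meta: Metacommunity, params: AssemblyParams
) -> tuple[LocalCommunity, dict[int, SpeciesHistory]]:
    """Assemble a local community to its Lambda target.

    Returns the final community state and the per-species forward-time
    histories (colonization steps/counts and abundance trajectories recorded
    once per generation, i.e. every J/2 Moran steps).
    """
    comm = LocalCommunity(meta, params)
    comm.run()
    return comm, comm.histories
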