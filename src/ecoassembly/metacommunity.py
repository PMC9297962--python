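"""The regional species pool: phylogeny, trait values and abundances.

The metacommunity is modelled as a very large, static regional pool.  It is
described by three coupled objects generated once per simulation and held
fixed on the timescale of local assembly:

* a rooted ultrametric phylogeny relating all ``S_M`` regional species,
  produced by a constant-rate birth--death process run until ``S_M`` extant
  lineages exist (conditioned on survival);
* one continuous trait per species, evolved along the phylogeny under
  Brownian motion with root state 0 and rate ``sigma2_M`` (trait variance per
  unit branch length);
* integer species abundances drawn from Fisher's log-series, rescaled to sum
  exactly to the regional community size ``J_M``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MetacommunityParams",
    "Metacommunity",
    "simulate_phylogeny",
    "tree_age",
    "evolve_traits",
    "fisher_alpha",
    "draw_logseries_abundances",
    "build_metacommunity",
]


@dataclass
class MetacommunityParams:
    """Parameters of the regional pool.

    Attributes
    ----------
    S_M : int
        Number of regional species (>= 2).
    J_M : int
        Total number of individuals in the region (>= ``S_M``).
    lam : float
        Per-lineage speciation rate of the birth--death process.  Time units
        are arbitrary; only ``sigma2_M`` per unit time and the speciation
        trait-variance ratio consume them.
    epsilon : float
        Extinction fraction in [0, 1); the extinction rate is
        ``lam * epsilon``.
    sigma2_M : float
        Brownian trait-evolution rate (variance per unit branch length).
    seed : int or None
        RNG seed for :func:`build_metacommunity`.
    """

    S_M: int
    J_M: int
    lam: float = 1.0
    epsilon: float = 0.0
    sigma2_M: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.S_M < 2:
            raise ValueError(f"S_M must be >= 2, got {self.S_M}")
        if self.J_M < self.S_M:
            raise ValueError(f"J_M ({self.J_M}) must be >= S_M ({self.S_M})")
        if self.lam <= 0:
            raise ValueError("speciation rate lam must be > 0")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("extinction fraction epsilon must be in [0, 1)")
        if self.sigma2_M < 0:
            raise ValueError("sigma2_M must be >= 0")


@dataclass
class Metacommunity:
    """A static regional pool: tree + per-species abundance and trait.

    Species are keyed by tip label (``t0 .. t{S_M-1}``, assigned in tip-visit
    order).  ``labels`` fixes the canonical species order used by the integer
    indices of the local-assembly module.
    """

    tree: dendropy.Tree
    abundances: dict[str, int]
    traits: dict[str, float]
    params: MetacommunityParams | None = None
    labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if set(self.labels) != set(self.abundances) or set(self.labels) != set(self.traits):
            raise ValueError("tree tips, abundances and traits must key the same species")

    @property
    def S_M(self) -> int:
        return len(self.labels)

    @property
    def J_M(self) -> int:
        return int(sum(self.abundances.values()))

    @property
    def abundance_array(self) -> np.ndarray:
        return np.array([self.abundances[s] for s in self.labels], dtype=np.int64)

    @property
    def trait_array(self) -> np.ndarray:
        return np.array([self.traits[s] for s in self.labels], dtype=float)

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)

    def species_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": self.labels,
                "abundance": [self.abundances[s] for s in self.labels],
                "trait": [self.traits[s] for s in self.labels],
            }
        )

    def to_files(self, tree_path, table_path) -> None:
        with open(tree_path, "w") as fh:
            fh.write(self.to_newick())
        self.species_table().to_csv(table_path, sep="\t", index=False)

    @classmethod
    def from_files(cls, tree_path, table_path) -> "Metacommunity":
        tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
        tab = pd.read_csv(table_path, sep="\t")
        abund = dict(zip(tab["species_id"], tab["abundance"].astype(int)))
        traits = dict(zip(tab["species_id"], tab["trait"].astype(float)))
        return cls(tree=tree, abundances=abund, traits=traits)


# ---------------------------------------------------------------------------
# Birth--death phylogeny
# ---------------------------------------------------------------------------


def simulate_phylogeny(
    params: MetacommunityParams,
    rng: np.random.Generator | None = None,
    max_tries: int = 10_000,
) -> dendropy.Tree:
    """Simulate a constant-rate birth--death tree with ``S_M`` extant tips.

    The process starts from a single lineage at time 0 with speciation rate
    ``lam`` and extinction rate ``lam * epsilon`` and stops the first time
    ``S_M`` lineages are simultaneously extant.  Runs that go fully extinct
    are discarded and resimulated (conditioning on survival).  Extinct side
    branches are pruned, so the returned tree is ultrametric with exactly
    ``S_M`` labelled tips; the root edge carries the time from the origin of
    the process to the most recent common ancestor of the extant tips, so
    :func:`tree_age` measures the full origin-to-present duration.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    lam, eps, S_M = params.lam, params.epsilon, params.S_M

    for _ in range(max_tries):
        # node record: [parent, t_start, t_end, child_a, child_b, extant]
        nodes: list[list] = [[-1, 0.0, None, -1, -1, False]]
        alive = [0]
        t = 0.0
        while 0 < len(alive) < S_M:
            k = len(alive)
            t += rng.exponential(1.0 / (k * lam * (1.0 + eps)))
            j = int(rng.integers(k))
            i = alive[j]
            nodes[i][2] = t
            alive[j] = alive[-1]
            alive.pop()
            if eps == 0.0 or rng.random() < 1.0 / (1.0 + eps):
                for _ in range(2):  # birth: bifurcation
                    nodes.append([i, t, None, -1, -1, False])
                    alive.append(len(nodes) - 1)
                nodes[i][3] = len(nodes) - 2
                nodes[i][4] = len(nodes) - 1
            # else: death, lineage just closed
        if len(alive) == S_M:
            # run the clock to just before the next event so terminal
            # branches have positive length (first-passage stop would leave
            # the youngest split at zero depth)
            t += rng.exponential(1.0 / (S_M * lam * (1.0 + eps)))
            for i in alive:
                nodes[i][2] = t
                nodes[i][5] = True
            return _build_tree(nodes, t)
    raise RuntimeError(
        f"birth-death simulation failed to reach {S_M} extant tips in {max_tries} tries"
    )


def _build_tree(nodes: list[list], T: float) -> dendropy.Tree:
    """Prune extinct lineages, suppress unifurcations, build a dendropy tree."""

    def prune(i: int, stem: float) -> tuple | None:
        parent, t0, t1, ca, cb, extant = nodes[i]
        bl = stem + (t1 - t0)
        if ca == -1:  # tip
            return ("tip", bl) if extant else None
        left = prune(ca, 0.0)
        right = prune(cb, 0.0)
        if left is None and right is None:
            return None
        if left is None or right is None:
            kind, sub_bl, *rest = left or right
            return (kind, bl + sub_bl, *rest)
        return ("node", bl, left, right)

    pruned = prune(0, 0.0)
    assert pruned is not None

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    counter = [0]

    def materialise(spec: tuple, node: dendropy.Node) -> None:
        kind, bl, *children = spec
        node.edge.length = bl
        if kind == "tip":
            label = f"t{counter[0]}"
            counter[0] += 1
            node.taxon = taxa.new_taxon(label)
        else:
            for child in children:
                materialise(child, node.new_child())

    materialise(pruned, tree.seed_node)
    return tree


def tree_age(tree: dendropy.Tree) -> float:
    """Origin-to-tip duration: root (stem) edge plus maximum root-to-tip depth."""
    stem = tree.seed_node.edge.length or 0.0
    depth = max(_depth_below(tree.seed_node, leaf) for leaf in tree.leaf_node_iter())
    return stem + depth


def _depth_below(root: dendropy.Node, leaf: dendropy.Node) -> float:
    total = 0.0
    node = leaf
    while node is not root:
        total += node.edge.length or 0.0
        node = node.parent_node
    return total


# ---------------------------------------------------------------------------
# Brownian trait evolution
# ---------------------------------------------------------------------------


def evolve_traits(
    tree: dendropy.Tree,
    sigma2_M: float,
    root_value: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Evolve one continuous trait per tip under Brownian motion.

    Each branch contributes an independent Gaussian increment with mean 0 and
    variance ``sigma2_M * branch_length``.  The state at the root node is
    ``root_value``; the root (stem) edge, if any, is not traversed.
    """
    if sigma2_M < 0:
        raise ValueError("sigma2_M must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    states: dict[int, float] = {id(tree.seed_node): root_value}
    traits: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            value = root_value
        else:
            bl = node.edge.length or 0.0
            value = states[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(sigma2_M * bl)
            )
        states[id(node)] = value
        if node.is_leaf():
            traits[node.taxon.label] = value
    return traits


# ---------------------------------------------------------------------------
# Log-series abundances
# ---------------------------------------------------------------------------


def fisher_alpha(S: int, J: int) -> float:
    """Solve Fisher's alpha from S = alpha * ln(1 + J / alpha).

    ``S(alpha)`` increases monotonically from 0 to ``J``, so a unique root
    exists whenever ``1 <= S < J``.
    """
    if not 1 <= S < J:
        raise ValueError("fisher_alpha requires 1 <= S < J")
    return optimize.brentq(lambda a: a * np.log1p(J / a) - S, 1e-12, 1e12)


def draw_logseries_abundances(
    S_M: int, J_M: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``S_M`` positive integer abundances summing exactly to ``J_M``.

    Fisher's alpha is solved from the (S_M, J_M) pair, ``S_M`` variates are
    drawn from the log-series with parameter ``x = J_M / (J_M + alpha)`` and
    the draw is rescaled to the exact total by largest-remainder rounding
    (every species keeps at least one individual).
    """
    if S_M < 1:
        raise ValueError("S_M must be >= 1")
    if J_M < S_M:
        raise ValueError(f"J_M ({J_M}) must be >= S_M ({S_M})")
    if rng is None:
        rng = np.random.default_rng()
    if S_M == J_M:
        return np.ones(S_M, dtype=np.int64)
    if S_M == 1:
        return np.array([J_M], dtype=np.int64)

    alpha = fisher_alpha(S_M, J_M)
    x = J_M / (J_M + alpha)
    draws = stats.logser.rvs(x, size=S_M, random_state=rng).astype(float)
    return _rescale_to_sum(draws, J_M)


def _rescale_to_sum(values: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder rescaling to an exact integer total, min 1 each."""
    S = len(values)
    scaled = values * (total / values.sum())
    base = np.maximum(np.floor(scaled).astype(np.int64), 1)
    deficit = total - int(base.sum())
    if deficit > 0:
        order = np.argsort(-(scaled - np.floor(scaled)), kind="stable")
        i = 0
        while deficit > 0:
            base[order[i % S]] += 1
            deficit -= 1
            i += 1
    elif deficit < 0:
        order = np.argsort(-base, kind="stable")
        i = 0
        while deficit < 0:
            j = order[i % S]
            if base[j] > 1:
                base[j] -= 1
                deficit += 1
            i += 1
    return base


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------


def build_metacommunity(params: MetacommunityParams) -> Metacommunity:
    """Generate a full, internally consistent regional pool from parameters."""
    rng = np.random.default_rng(params.seed)
    tree = simulate_phylogeny(params, rng=rng)
    traits = evolve_traits(tree, params.sigma2_M, root_value=0.0, rng=rng)
    abund = draw_logseries_abundances(params.S_M, params.J_M, rng=rng)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    return Metacommunity(
        tree=tree,
        abundances=dict(zip(labels, (int(a) for a in abund))),
        traits={s: float(traits[s]) for s in labels},
        params=params,
    )
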