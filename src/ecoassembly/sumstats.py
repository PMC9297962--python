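"""Hierarchical community summary statistics.

Per-species values on up to three data axes (abundance, nucleotide diversity
pi, trait) are aggregated into one fixed-order community summary vector:

* species richness ``S``;
* the first four moments (mean, sd, skewness, excess kurtosis) of each axis;
* generalized Hill numbers of orders q = 1..4 per axis -- ``qD`` on
  abundance proportions, ``qGD`` on normalized pi values, and the attribute
  (functional) diversity ``qFD`` on pairwise trait distances;
* Spearman rank correlations between axes, where the trait variable is the
  absolute deviation of a species' trait from the local trait mean;
* the regional-minus-local differences in trait mean and sd
  (``delta_mu_trait``, ``delta_sigma_trait``).

Axes may be absent.  Statistics touching an absent axis carry NaN, and an
explicit availability mask travels with the vector so that the inference
layer can apply identical masking at training and prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "STAT_NAMES",
    "STAT_AXES",
    "SummaryVector",
    "hill_number",
    "genetic_hill",
    "functional_hill",
    "moments",
    "trait_deltas",
    "rank_correlations",
    "assemble_summary_vector",
]

HILL_ORDERS = (1, 2, 3, 4)

#: Canonical field order of the summary vector.
STAT_NAMES: list[str] = (
    ["S"]
    + [f"abund_{m}" for m in ("mean", "std", "skew", "kurt")]
    + [f"pi_{m}" for m in ("mean", "std", "skew", "kurt")]
    + [f"trait_{m}" for m in ("mean", "std", "skew", "kurt")]
    + [f"abund_hill_{q}" for q in HILL_ORDERS]
    + [f"pi_hill_{q}" for q in HILL_ORDERS]
    + [f"trait_hill_{q}" for q in HILL_ORDERS]
    + ["rho_abund_pi", "rho_abund_trait", "rho_pi_trait"]
    + ["delta_mu_trait", "delta_sigma_trait"]
)

#: Which axes each statistic consumes (used for masking).
STAT_AXES: dict[str, frozenset[str]] = {}
for _name in STAT_NAMES:
    if _name == "S":
        _axes: set[str] = set()
    elif _name.startswith("abund_"):
        _axes = {"abundance"}
    elif _name.startswith("pi_"):
        _axes = {"pi"}
    elif _name.startswith("trait_hill"):
        _axes = {"trait"}  # falls back to equal weights without abundances
    elif _name.startswith("trait_") or _name.startswith("delta_"):
        _axes = {"trait"}
    elif _name == "rho_abund_pi":
        _axes = {"abundance", "pi"}
    elif _name == "rho_abund_trait":
        _axes = {"abundance", "trait"}
    elif _name == "rho_pi_trait":
        _axes = {"pi", "trait"}
    STAT_AXES[_name] = frozenset(_axes)


class UndefinedStatisticError(ValueError):
    """A statistic is mathematically undefined for the given input."""


def hill_number(proportions: Sequence[float] | np.ndarray, q: float) -> float:
    """Hill number of order q: the effective number of equally common types.

    ``(sum p_i^q)^(1/(1-q))`` for q != 1 and ``exp(-sum p_i ln p_i)`` in the
    q -> 1 limit.  Zero entries are dropped; input must lie on the simplex.
    """
    p = np.asarray(proportions, dtype=float)
    if q < 0:
        raise ValueError("Hill order q must be >= 0")
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    p = p[p > 0]
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def genetic_hill(pi_values: Sequence[float] | np.ndarray, q: float) -> float:
    """Hill number of the community pi distribution (pi normalized to 1)."""
    pi = np.asarray(pi_values, dtype=float)
    if np.any(pi < 0):
        raise ValueError("pi values must be >= 0")
    total = pi.sum()
    if total <= 0:
        raise UndefinedStatisticError("genetic Hill number undefined: all pi are 0")
    return hill_number(pi / total, q)


def functional_hill(
    traits: Sequence[float] | np.ndarray,
    abundances: Sequence[float] | np.ndarray | None,
    q: float,
) -> float:
    """Attribute-diversity (functional) Hill number of order q.

    With pairwise trait distances ``d_ij = |t_i - t_j|``, proportions ``p``
    and Rao's ``Q = sum_ij d_ij p_i p_j``::

        qFD = [ sum_ij (d_ij / Q) (p_i p_j)^q ] ^ (1 / (2 (1 - q)))

    with the analogous limit form at q = 1.  The ``d_ij / Q`` normalization
    makes the statistic invariant to rescaling all traits by a constant.  If
    ``abundances`` is None species are weighted equally.
    """
    t = np.asarray(traits, dtype=float)
    if t.size < 2:
        raise UndefinedStatisticError("functional Hill number needs >= 2 species")
    if abundances is None:
        p = np.full(t.size, 1.0 / t.size)
    else:
        a = np.asarray(abundances, dtype=float)
        if a.size != t.size:
            raise ValueError("traits and abundances must have equal length")
        p = a / a.sum()
    d = np.abs(t[:, None] - t[None, :])
    pp = p[:, None] * p[None, :]
    Q = float(np.sum(d * pp))
    if Q <= 0:
        raise UndefinedStatisticError(
            "functional Hill number undefined: all trait values identical"
        )
    a_ij = d / Q
    if q == 1:
        mask = pp > 0
        val = -0.5 * np.sum(a_ij[mask] * pp[mask] * np.log(pp[mask]))
        return float(np.exp(val))
    return float(np.sum(a_ij * pp**q) ** (1.0 / (2.0 * (1.0 - q))))


def moments(values: Sequence[float] | np.ndarray) -> tuple[float, float, float, float]:
    """Mean, population sd, Fisher skewness and excess kurtosis.

    Skewness and kurtosis of a constant vector are defined as 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("moments of an empty vector are undefined")
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    if sd == 0:
        return mean, 0.0, 0.0, 0.0
    return (
        mean,
        sd,
        float(stats.skew(x, bias=True)),
        float(stats.kurtosis(x, fisher=True, bias=True)),
    )


def trait_deltas(
    local_traits: Sequence[float] | np.ndarray,
    local_abundances: Sequence[float] | np.ndarray | None,
    meta_traits: Sequence[float] | np.ndarray,
) -> tuple[float, float]:
    """Regional-minus-local trait mean and sd differences.

    Local statistics are unweighted across species (``local_abundances`` is
    accepted for interface symmetry but not used): positive
    ``delta_sigma_trait`` means less trait variation locally than regionally,
    the signature of environmental filtering.
    """
    local = np.asarray(local_traits, dtype=float)
    meta = np.asarray(meta_traits, dtype=float)
    if local.size == 0 or meta.size == 0:
        raise ValueError("trait sets must be nonempty")
    d_mu = float(meta.mean() - local.mean())
    d_sigma = float(meta.std(ddof=0) - local.std(ddof=0))
    return d_mu, d_sigma


def rank_correlations(
    abundance: Sequence[float] | np.ndarray | None,
    pi: Sequence[float] | np.ndarray | None,
    traits: Sequence[float] | np.ndarray | None,
    local_trait_mean: float | None = None,
) -> tuple[float, float, float]:
    """Spearman rank correlations among the three data axes.

    The trait variable is ``|t_i - local trait mean|`` (distance from the
    local mean).  Each correlation needs >= 3 species with both axes present;
    otherwise NaN is returned for that pair.  Ties receive average ranks.
    """
    trait_dist = None
    if traits is not None:
        t = np.asarray(traits, dtype=float)
        centre = float(t.mean()) if local_trait_mean is None else local_trait_mean
        trait_dist = np.abs(t - centre)

    def rho(x, y) -> float:
        if x is None or y is None:
            return np.nan
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != y.size or x.size < 3:
            return np.nan
        if np.all(x == x[0]) or np.all(y == y[0]):
            return np.nan
        return float(stats.spearmanr(x, y).statistic)

    return (
        rho(abundance, pi),
        rho(abundance, trait_dist),
        rho(pi, trait_dist),
    )


@dataclass
class SummaryVector:
    """Fixed-order named summary statistics with an axis-availability mask."""

    values: pd.Series
    mask: dict[str, bool] = field(
        default_factory=lambda: {"abundance": False, "pi": False, "trait": False}
    )

    def __post_init__(self) -> None:
        self.values = self.values.reindex(STAT_NAMES).astype(float)

    @property
    def available_stats(self) -> list[str]:
        """Statistic names whose constituent axes are all available."""
        return [
            name
            for name in STAT_NAMES
            if all(self.mask.get(ax, False) for ax in STAT_AXES[name])
        ]

    def __getitem__(self, name: str) -> float:
        return float(self.values[name])

    def to_frame(self) -> pd.DataFrame:
        return self.values.to_frame().T


def assemble_summary_vector(
    abundances: Sequence[float] | np.ndarray | None = None,
    pis: Sequence[float] | np.ndarray | None = None,
    traits: Sequence[float] | np.ndarray | None = None,
    meta_traits: Sequence[float] | np.ndarray | None = None,
) -> SummaryVector:
    """Build the canonical summary vector from whatever axes are present.

    Statistics on absent axes (and statistics that are mathematically
    undefined for the given data, e.g. ``qGD`` when all pi are 0) carry NaN.
    ``meta_traits`` is only needed for the regional-local trait deltas.
    At least one axis must be supplied.
    """
    axes: dict[str, np.ndarray | None] = {
        "abundance": None if abundances is None else np.asarray(abundances, float),
        "pi": None if pis is None else np.asarray(pis, float),
        "trait": None if traits is None else np.asarray(traits, float),
    }
    present = {k: v is not None for k, v in axes.items()}
    if not any(present.values()):
        raise ValueError("at least one data axis must be present")
    sizes = {v.size for v in axes.values() if v is not None}
    if len(sizes) > 1:
        raise ValueError(f"axes disagree on species count: {sizes}")
    S = sizes.pop()

    out: dict[str, float] = {name: np.nan for name in STAT_NAMES}
    out["S"] = float(S)

    for axis, prefix in (("abundance", "abund"), ("pi", "pi"), ("trait", "trait")):
        v = axes[axis]
        if v is None:
            continue
        mean, sd, skew, kurt = moments(v)
        out[f"{prefix}_mean"] = mean
        out[f"{prefix}_std"] = sd
        out[f"{prefix}_skew"] = skew
        out[f"{prefix}_kurt"] = kurt

    ab = axes["abundance"]
    if ab is not None and ab.sum() > 0:
        p = ab / ab.sum()
        for q in HILL_ORDERS:
            out[f"abund_hill_{q}"] = hill_number(p, q)
    pi = axes["pi"]
    if pi is not None:
        for q in HILL_ORDERS:
            try:
                out[f"pi_hill_{q}"] = genetic_hill(pi, q)
            except UndefinedStatisticError:
                pass
    tr = axes["trait"]
    if tr is not None:
        for q in HILL_ORDERS:
            try:
                out[f"trait_hill_{q}"] = functional_hill(tr, ab, q)
            except UndefinedStatisticError:
                pass
        if meta_traits is not None:
            d_mu, d_sigma = trait_deltas(tr, ab, meta_traits)
            out["delta_mu_trait"] = d_mu
            out["delta_sigma_trait"] = d_sigma

    r_ap, r_at, r_pt = rank_correlations(ab, pi, tr)
    out["rho_abund_pi"] = r_ap
    out["rho_abund_trait"] = r_at
    out["rho_pi_trait"] = r_pt

    return SummaryVector(values=pd.Series(out), mask=present)
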