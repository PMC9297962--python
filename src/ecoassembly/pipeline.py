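"""Simulation pipeline: priors, parameter draws and training tables.

One simulation = draw parameters from priors, build a metacommunity, run
local assembly to its Lambda target, simulate per-species nucleotide
diversity, and reduce everything to the canonical summary vector.  Rows of
(parameter draw, summary vector) accumulate into the training table consumed
by :mod:`ecoassembly.inference`.

Default priors (all overridable through the config):

===========  ==============================  =========================
parameter    prior                           meaning
===========  ==============================  =========================
model        categorical over 3 classes      assembly model
J            uniform integer [500, 10000]    local community size (demes)
alpha        log-uniform [10, 10000]         individuals per deme
m            log-uniform [1e-4, 1e-1]        immigration probability
nu           uniform [0, 5e-3]               speciation probability
s_E          log-uniform [0.01, 100]         ecological strength
Lambda       uniform [0, 1]                  target equilibrium fraction
===========  ==============================  =========================

Fixed metacommunity defaults: S_M=500, J_M=500000, lam=1, epsilon=0,
sigma2_M=2, z_E=0; sequence sampling n=10 gene copies, L=570 bp, mu=5e-7.
"""

from __future__ import annotations

import sys
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ecoassembly.local_assembly import AssemblyParams, run_assembly
from ecoassembly.metacommunity import MetacommunityParams, build_metacommunity
from ecoassembly.popgen import community_genetic_diversities
from ecoassembly.inference import TrainingTable
from ecoassembly.sumstats import STAT_NAMES, SummaryVector, assemble_summary_vector

__all__ = [
    "Prior",
    "RunConfig",
    "DEFAULT_PRIORS",
    "PARAM_COLUMNS",
    "simulate_community",
    "run_simulations",
    "load_config",
    "table_from_tsv",
]

PARAM_COLUMNS = ["model", "J", "alpha", "m", "nu", "s_E", "Lambda"]


@dataclass(frozen=True)
class Prior:
    """A prior for one parameter: uniform, log-uniform, fixed or categorical."""

    kind: str  # "uniform" | "log_uniform" | "fixed" | "categorical"
    low: float | None = None
    high: float | None = None
    value: object | None = None
    choices: tuple | None = None
    integer: bool = False

    def __post_init__(self) -> None:
        if self.kind in ("uniform", "log_uniform"):
            if self.low is None or self.high is None:
                raise ValueError(f"{self.kind} prior needs finite bounds")
            if not (np.isfinite(self.low) and np.isfinite(self.high)):
                raise ValueError("prior bounds must be finite")
            if self.kind == "log_uniform" and self.low <= 0:
                raise ValueError("log-uniform bounds must be > 0")
        elif self.kind == "fixed":
            if self.value is None:
                raise ValueError("fixed prior needs a value")
        elif self.kind == "categorical":
            if not self.choices:
                raise ValueError("categorical prior needs choices")
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")

    def sample(self, rng: np.random.Generator):
        if self.kind == "fixed":
            return self.value
        if self.kind == "categorical":
            return self.choices[int(rng.integers(len(self.choices)))]
        if self.kind == "uniform":
            x = rng.uniform(self.low, self.high)
        else:
            x = float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return int(round(x)) if self.integer else float(x)


DEFAULT_PRIORS: dict[str, Prior] = {
    "model": Prior(kind="categorical", choices=("neutral", "filtering", "competition")),
    "J": Prior(kind="uniform", low=500, high=10_000, integer=True),
    "alpha": Prior(kind="log_uniform", low=10, high=10_000, integer=True),
    "m": Prior(kind="log_uniform", low=1e-4, high=1e-1),
    "nu": Prior(kind="uniform", low=0.0, high=5e-3),
    "s_E": Prior(kind="log_uniform", low=0.01, high=100.0),
    "Lambda": Prior(kind="uniform", low=0.0, high=1.0),
}


@dataclass
class RunConfig:
    """Everything needed to generate a training table."""

    priors: dict[str, Prior] = field(default_factory=lambda: dict(DEFAULT_PRIORS))
    nsims: int = 100
    S_M: int = 500
    J_M: int = 500_000
    lam: float = 1.0
    epsilon: float = 0.0
    sigma2_M: float = 2.0
    z_E: float = 0.0
    init_mode: str = "metacommunity_sample"
    n_samples: int = 10
    L: int = 570
    mu: float = 5e-7
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = [p for p in PARAM_COLUMNS if p not in self.priors]
        if missing:
            raise ValueError(f"every free parameter needs a prior; missing {missing}")


def _row_seed(master: int | None, index: int) -> int:
    """Deterministic per-row seed below 2**31, independent of resume point."""
    ss = np.random.SeedSequence([0 if master is None else int(master), index])
    return int(ss.generate_state(1)[0] % 2**31)


def simulate_community(theta: dict, config: RunConfig, seed: int) -> SummaryVector:
    """Run one full simulation at parameters ``theta`` and summarise it."""
    rng = np.random.default_rng(seed)
    mp = MetacommunityParams(
        S_M=config.S_M,
        J_M=config.J_M,
        lam=config.lam,
        epsilon=config.epsilon,
        sigma2_M=config.sigma2_M,
        seed=int(rng.integers(2**31)),
    )
    meta = build_metacommunity(mp)
    ap = AssemblyParams(
        J=int(theta["J"]),
        m=float(theta["m"]),
        nu=float(theta["nu"]),
        model=str(theta["model"]),
        s_E=float(theta["s_E"]),
        z_E=config.z_E,
        Lambda_target=float(theta["Lambda"]),
        init_mode=config.init_mode,
        alpha=int(theta["alpha"]),
        seed=int(rng.integers(2**31)),
    )
    comm, _ = run_assembly(meta, ap)
    pis = community_genetic_diversities(
        comm,
        n_samples=config.n_samples,
        L=config.L,
        mu=config.mu,
        seed=int(rng.integers(2**31)),
    )
    species = sorted(pis)
    counts = comm.species_counts()
    return assemble_summary_vector(
        abundances=[int(counts[s]) for s in species],
        pis=[pis[s].pi for s in species],
        traits=[float(comm.traits[s]) for s in species],
        meta_traits=meta.trait_array,
    )


def run_simulations(
    config: RunConfig,
    out: str | Path | None = None,
    progress: bool = False,
) -> TrainingTable:
    """Draw ``nsims`` parameter sets and simulate each one.

    If ``out`` is given, rows are appended to the TSV as they complete; an
    existing file is resumed from its current row count (append-safe), and
    per-row seeds depend only on (master seed, row index), so resumed and
    one-shot runs produce identical tables.  Failed simulations are skipped
    with a note on stderr.
    """
    columns = PARAM_COLUMNS + STAT_NAMES
    out_path = Path(out) if out is not None else None
    done = 0
    rows: list[dict] = []
    if out_path is not None and out_path.exists():
        existing = pd.read_csv(out_path, sep="\t")
        if list(existing.columns) != columns:
            raise ValueError(f"existing table {out_path} has unexpected columns")
        rows = existing.to_dict("records")
        done = len(rows)
    elif out_path is not None:
        out_path.parent.mkdir(parents=True, exist_ok=True)
        out_path.write_text("\t".join(columns) + "\n")

    failures = 0
    mask = {"abundance": True, "pi": True, "trait": True}
    for i in range(done, config.nsims):
        seed_i = _row_seed(config.seed, i)
        rng = np.random.default_rng(seed_i)
        theta = {p: config.priors[p].sample(rng) for p in PARAM_COLUMNS}
        try:
            sv = simulate_community(theta, config, seed=int(rng.integers(2**31)))
        except Exception as err:
            failures += 1
            print(f"simulation {i} failed ({err}); skipping", file=sys.stderr)
            continue
        row = {**theta, **sv.values.to_dict()}
        rows.append(row)
        if out_path is not None:
            pd.DataFrame([row], columns=columns).to_csv(
                out_path, sep="\t", index=False, header=False, mode="a"
            )
        if progress and (i + 1) % 50 == 0:
            print(f"{i + 1}/{config.nsims} simulations done", file=sys.stderr)
    if failures:
        print(f"{failures} of {config.nsims} simulations failed", file=sys.stderr)
    frame = pd.DataFrame(rows, columns=columns)
    return TrainingTable(frame=frame, mask=mask)


def table_from_tsv(path: str | Path, mask: dict[str, bool] | None = None) -> TrainingTable:
    """Load a previously written training table."""
    frame = pd.read_csv(path, sep="\t")
    if mask is None:
        mask = {"abundance": True, "pi": True, "trait": True}
    return TrainingTable(frame=frame, mask=mask)


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_PRIOR_KEYS = {p: f"prior_{p}" for p in PARAM_COLUMNS}


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat TOML config into a :class:`RunConfig`.

    Scalar keys (``nsims``, ``seed``, ``S_M``, ``J_M``, ``lam``, ``epsilon``,
    ``sigma2_M``, ``z_E``, ``init_mode``, ``n_samples``, ``L``, ``mu``)
    override the defaults.  Priors are given as ``prior_<name>`` entries:
    a scalar fixes the parameter, a two-element array is a uniform range,
    and ``{kind = "log_uniform", low = ..., high = ...}`` spells out the
    distribution.  ``prior_model`` takes a list of class names.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = RunConfig()
    scalars = {
        "nsims", "S_M", "J_M", "lam", "epsilon", "sigma2_M", "z_E",
        "init_mode", "n_samples", "L", "mu", "seed",
    }
    updates = {k: raw[k] for k in scalars if k in raw}
    priors = dict(cfg.priors)
    for p, key in _PRIOR_KEYS.items():
        if key not in raw:
            continue
        spec = raw[key]
        integer = p in ("J", "alpha")
        if p == "model":
            choices = tuple(spec) if isinstance(spec, list) else (spec,)
            priors[p] = Prior(kind="categorical", choices=choices)
        elif isinstance(spec, (int, float)):
            priors[p] = Prior(kind="fixed", value=int(spec) if integer else float(spec))
        elif isinstance(spec, list) and len(spec) == 2:
            priors[p] = Prior(kind="uniform", low=float(spec[0]),
                              high=float(spec[1]), integer=integer)
        elif isinstance(spec, dict):
            priors[p] = Prior(
                kind=spec.get("kind", "uniform"),
                low=spec.get("low"),
                high=spec.get("high"),
                value=spec.get("value"),
                choices=tuple(spec["choices"]) if "choices" in spec else None,
                integer=integer,
            )
        else:
            raise ValueError(f"cannot interpret prior spec for {p!r}: {spec!r}")
    return replace(cfg, priors=priors, **updates)
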