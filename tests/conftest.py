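"""Shared fixtures: small regional pools and session-scoped simulation tables.

The heavier fixtures (training tables of a few hundred simulations) are
session-scoped and lazily built so their cost is paid once per test run.
Problem sizes are scaled-down study conditions chosen for desk-scale runs;
docs/methods.md records them.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecoassembly import (
    AssemblyParams,
    MetacommunityParams,
    build_metacommunity,
    run_assembly,
)
from ecoassembly import pipeline
from ecoassembly.pipeline import Prior, RunConfig


@pytest.fixture(scope="session")
def small_meta():
    """An 80-species regional pool shared by read-only tests."""
    return build_metacommunity(
        MetacommunityParams(S_M=80, J_M=30_000, sigma2_M=2.0, seed=42)
    )


@pytest.fixture(scope="session")
def tiny_meta():
    return build_metacommunity(MetacommunityParams(S_M=10, J_M=1_000, seed=7))


def run_neutral(meta, J=300, m=0.01, nu=0.0, Lambda=0.75, seed=0, **kw):
    params = AssemblyParams(
        J=J, m=m, nu=nu, model="neutral", Lambda_target=Lambda, seed=seed, **kw
    )
    comm, hist = run_assembly(meta, params)
    return comm, hist


# ---------------------------------------------------------------------------
# session-scoped simulation tables for the statistical acceptance checks
# ---------------------------------------------------------------------------

CLASS_PER_CLASS = 150  # classification experiment, per model class
NEUTRAL_SIMS = 600  # parameter-recovery experiment
MIXED_NONNEUTRAL = 150  # per non-neutral class, end-to-end experiment

_SMALL_DIMS = dict(S_M=100, J_M=50_000)

VARIED_PRIORS = {
    "J": Prior(kind="uniform", low=500, high=1500, integer=True),
    "alpha": Prior(kind="log_uniform", low=10, high=3000, integer=True),
    "m": Prior(kind="log_uniform", low=1e-4, high=1e-1),
    "nu": Prior(kind="uniform", low=0.0, high=5e-3),
    "s_E": Prior(kind="log_uniform", low=0.01, high=100.0),
    "Lambda": Prior(kind="uniform", low=0.0, high=1.0),
}


def _fixed_class_config(model: str, seed: int) -> RunConfig:
    """Classification experiment: intermediate values fixed, J and nu vary.

    s_E = 3 puts the two niche models at comparable moderate strength under
    the Gaussian death kernels (docs/methods.md discusses the choice).
    """
    priors = {
        "model": Prior(kind="fixed", value=model),
        "J": Prior(kind="uniform", low=500, high=2000, integer=True),
        "alpha": Prior(kind="fixed", value=300),
        "m": Prior(kind="fixed", value=0.003),
        "nu": Prior(kind="categorical", choices=(0.0, 5e-4, 5e-3)),
        "s_E": Prior(kind="fixed", value=3.0),
        "Lambda": Prior(kind="fixed", value=0.75),
    }
    return RunConfig(priors=priors, nsims=CLASS_PER_CLASS, seed=seed, **_SMALL_DIMS)


def _varied_config(model: str, nsims: int, seed: int) -> RunConfig:
    priors = {"model": Prior(kind="fixed", value=model), **VARIED_PRIORS}
    return RunConfig(priors=priors, nsims=nsims, seed=seed, **_SMALL_DIMS)


@pytest.fixture(scope="session")
def classification_table():
    """Three model classes at matched intermediate parameters, Lambda=0.75."""
    import pandas as pd

    frames = []
    for i, model in enumerate(("neutral", "filtering", "competition")):
        tab = pipeline.run_simulations(_fixed_class_config(model, seed=1000 + i))
        frames.append(tab.frame)
    frame = pd.concat(frames, ignore_index=True)
    return pipeline.TrainingTable(
        frame=frame, mask={"abundance": True, "pi": True, "trait": True}
    )


@pytest.fixture(scope="session")
def neutral_table():
    """Neutral simulations with all free parameters drawn from priors."""
    return pipeline.run_simulations(_varied_config("neutral", NEUTRAL_SIMS, seed=2000))


@pytest.fixture(scope="session")
def mixed_table(neutral_table):
    """Three classes with varied parameters (neutral rows reused)."""
    import pandas as pd

    frames = [neutral_table.frame.iloc[: 2 * MIXED_NONNEUTRAL]]
    for i, model in enumerate(("filtering", "competition")):
        tab = pipeline.run_simulations(
            _varied_config(model, MIXED_NONNEUTRAL, seed=3000 + i)
        )
        frames.append(tab.frame)
    frame = pd.concat(frames, ignore_index=True)
    return pipeline.TrainingTable(
        frame=frame, mask={"abundance": True, "pi": True, "trait": True}
    )
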