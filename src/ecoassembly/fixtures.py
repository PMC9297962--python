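"""Synthetic empirical-format communities with known generating parameters.

``generate_fixture`` simulates one community under a chosen assembly model,
exports it in the empirical TSV format understood by
:func:`ecoassembly.io.read_empirical`, and writes the true parameter draw
alongside (``truth.json``) so that inference round-trips can be scored.
These synthetic fixtures stand in for field datasets (abundance + sequence +
trait surveys) in tests and examples; they are simulator output, not real
observations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from ecoassembly.local_assembly import AssemblyParams, run_assembly
from ecoassembly.metacommunity import MetacommunityParams, build_metacommunity
from ecoassembly.popgen import community_genetic_diversities

__all__ = ["FIXTURE_SIZES", "generate_fixture"]

#: Problem sizes for fixtures: (S_M, J_M, J, alpha).
FIXTURE_SIZES = {
    "tiny": {"S_M": 50, "J_M": 20_000, "J": 200, "alpha": 100},
    "small": {"S_M": 100, "J_M": 50_000, "J": 500, "alpha": 300},
}


def generate_fixture(
    scenario: str,
    size: str = "tiny",
    seed: int | None = None,
    outdir: str | Path = ".",
    theta: dict | None = None,
    n_samples: int = 10,
    L: int = 570,
    mu: float = 5e-7,
) -> tuple[Path, Path]:
    """Simulate one community and write (community.tsv, truth.json).

    ``scenario`` is the assembly model (neutral / filtering / competition);
    ``theta`` may override any generating parameter (J, alpha, m, nu, s_E,
    Lambda).  Returns the two written paths.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"size must be one of {sorted(FIXTURE_SIZES)}")
    dims = FIXTURE_SIZES[size]
    rng = np.random.default_rng(seed)
    params = {
        "model": scenario,
        "J": dims["J"],
        "alpha": dims["alpha"],
        "m": 0.003,
        "nu": 5e-4,
        "s_E": 10.0,
        "Lambda": 0.75,
    }
    if theta:
        params.update(theta)

    meta = build_metacommunity(
        MetacommunityParams(
            S_M=dims["S_M"], J_M=dims["J_M"], seed=int(rng.integers(2**31))
        )
    )
    ap = AssemblyParams(
        J=int(params["J"]),
        m=float(params["m"]),
        nu=float(params["nu"]),
        model=str(params["model"]),
        s_E=float(params["s_E"]),
        Lambda_target=float(params["Lambda"]),
        alpha=int(params["alpha"]),
        seed=int(rng.integers(2**31)),
    )
    comm, _ = run_assembly(meta, ap)
    pis = community_genetic_diversities(
        comm, n_samples=n_samples, L=L, mu=mu, seed=int(rng.integers(2**31))
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_path = outdir / "community.tsv"
    truth_path = outdir / "truth.json"

    counts = comm.species_counts()
    meta_tr = meta.trait_array
    with open(table_path, "w") as fh:
        fh.write(f"# meta_trait_mean = {float(meta_tr.mean())!r}\n")
        fh.write(f"# meta_trait_sd = {float(meta_tr.std(ddof=0))!r}\n")
        fh.write("species_id\tabundance\ttrait\tpi\n")
        for sp in sorted(pis):
            fh.write(
                f"{comm.species_label(sp)}\t{int(counts[sp])}\t"
                f"{float(comm.traits[sp])!r}\t{float(pis[sp].pi)!r}\n"
            )
    truth = {**params, "seed": seed, "size": size,
             "n_samples": n_samples, "L": L, "mu": mu}
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    return table_path, truth_path
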