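"""Reading observed community tables and sequence data.

The empirical input format is a TSV with one row per species and columns
``species_id`` (required) plus any of ``abundance``, ``trait`` and ``pi``.
Nucleotide diversity can instead be computed from per-species FASTA
alignments of a single locus (one file ``<species_id>.fasta`` per species in
a directory).  Comment lines starting with ``#`` may carry community
metadata; ``# meta_trait_mean = x`` and ``# meta_trait_sd = x`` supply the
regional trait moments needed for the regional-local trait deltas (absent in
most field datasets, in which case the deltas are masked).

Multivariate traits must be reduced to a single column by the user (e.g. the
position of each species along the first principal component).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ecoassembly.popgen import nucleotide_diversity
from ecoassembly.sumstats import SummaryVector, assemble_summary_vector

__all__ = ["EmpiricalTable", "read_empirical_table", "read_empirical"]


class EmpiricalTableError(ValueError):
    """Malformed empirical community table."""


class EmpiricalTable:
    """A parsed per-species community table with optional metadata."""

    def __init__(self, frame: pd.DataFrame, metadata: dict[str, float]):
        if "species_id" not in frame.columns:
            raise EmpiricalTableError("table must have a species_id column")
        if frame["species_id"].duplicated().any():
            dupes = frame.loc[frame["species_id"].duplicated(), "species_id"].tolist()
            raise EmpiricalTableError(f"duplicate species ids: {dupes}")
        axes = [c for c in ("abundance", "trait", "pi") if c in frame.columns]
        if not axes:
            raise EmpiricalTableError(
                "at least one of abundance / trait / pi must be present"
            )
        self.frame = frame
        self.metadata = metadata

    @property
    def axes(self) -> list[str]:
        return [c for c in ("abundance", "trait", "pi") if c in self.frame.columns]


def read_empirical_table(path: str | Path) -> EmpiricalTable:
    """Parse the TSV and its ``#`` metadata header."""
    path = Path(path)
    metadata: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith("#"):
            break
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, val = body.partition("=")
            try:
                metadata[key.strip()] = float(val.strip())
            except ValueError as err:
                raise EmpiricalTableError(
                    f"{path}:{lineno}: cannot parse metadata line {line!r}"
                ) from err
    try:
        frame = pd.read_csv(path, sep="\t", comment="#")
    except Exception as err:
        raise EmpiricalTableError(f"{path}: cannot parse TSV: {err}") from err
    return EmpiricalTable(frame=frame, metadata=metadata)


def _pi_from_fasta(path: Path) -> float:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise EmpiricalTableError(
            f"{path}: need >= 2 sequences to compute pi, found {len(records)}"
        )
    return nucleotide_diversity(str(r.seq) for r in records)


def read_empirical(
    table_path: str | Path, fasta_dir: str | Path | None = None
) -> tuple[SummaryVector, dict[str, bool]]:
    """Observed community table -> summary vector + availability mask.

    When ``fasta_dir`` is given, per-species alignments ``<species_id>.fasta``
    supply pi for species without a ``pi`` column entry.  The pi axis counts
    as available only if every species has a value (partial sequence data
    would bias the community pi distribution).
    """
    table = read_empirical_table(table_path)
    frame = table.frame

    abund = frame["abundance"].to_numpy(float) if "abundance" in frame else None
    traits = frame["trait"].to_numpy(float) if "trait" in frame else None

    pis = None
    pi_col = frame["pi"].to_numpy(float) if "pi" in frame else np.full(len(frame), np.nan)
    if fasta_dir is not None:
        fasta_dir = Path(fasta_dir)
        for i, sp in enumerate(frame["species_id"]):
            if np.isnan(pi_col[i]):
                fasta = fasta_dir / f"{sp}.fasta"
                if fasta.exists():
                    pi_col[i] = _pi_from_fasta(fasta)
    if not np.any(np.isnan(pi_col)):
        pis = pi_col

    meta_traits = None
    if traits is not None and {"meta_trait_mean", "meta_trait_sd"} <= set(table.metadata):
        # two-point surrogate with the recorded regional mean and sd, enough
        # to reconstruct the delta statistics exactly
        mu_m = table.metadata["meta_trait_mean"]
        sd_m = table.metadata["meta_trait_sd"]
        meta_traits = np.array([mu_m - sd_m, mu_m + sd_m])

    sv = assemble_summary_vector(
        abundances=abund, pis=pis, traits=traits, meta_traits=meta_traits
    )
    return sv, sv.mask
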