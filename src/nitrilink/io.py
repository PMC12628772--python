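"""Readers and writers for the plain-text formats used across the pipeline.

All tables are UTF-8 with "." as the decimal separator.  Count tables are
samples-as-rows TSV with a header row of taxon identifiers and the sample
identifier in the first column.  Network edge lists are TSV with columns
(taxon_a, taxon_b, rho, p) and taxon_a < taxon_b lexicographically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

log = logging.getLogger("nitrilink")

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an on-disk file violates a format contract."""


class ConfigError(ValueError):
    """Raised when a configuration value violates its invariants."""


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved parameters for a full analysis run.

    Defaults follow the published workflow: rarefaction 100 times at a depth
    of 36,103 reads, association cutoffs 0.1-0.9 in steps of 0.1 at a
    significance level of 0.01, regressions on the first three principal
    coordinates, time lags of 2/4/6/8 days, and 1,000 regression trees.
    """

    rarefaction_depth: int = 36103
    rarefaction_reps: int = 100
    cutoffs: tuple = tuple(round(0.1 * k, 1) for k in range(1, 10))
    significance_alpha: float = 0.01
    n_pcoa_axes: int = 3
    lags_days: tuple = (2, 4, 6, 8)
    rf_trees: int = 1000
    n_draws: int = 20
    n_permutations: int = 100
    exclusion_threshold: float = 0.1
    max_exclusions: int = 10
    absolute_rho: bool = True
    seed: int = 0

    def __post_init__(self):
        if not all(0.0 < c < 1.0 for c in self.cutoffs):
            raise ConfigError("cutoffs must lie in the open interval (0, 1)")
        if not 0.0 < self.significance_alpha < 1.0:
            raise ConfigError("significance_alpha must lie in (0, 1)")
        if self.n_pcoa_axes < 1:
            raise ConfigError("n_pcoa_axes must be >= 1")
        if self.rarefaction_depth < 1:
            raise ConfigError("rarefaction_depth must be >= 1")
        if self.rarefaction_reps < 1:
            raise ConfigError("rarefaction_reps must be >= 1")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cutoffs", "lags_days"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["cutoffs"] = list(self.cutoffs)
        out["lags_days"] = list(self.lags_days)
        return out


def atomic_write_text(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temporary file and atomic rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    os.replace(tmp, path)


def read_count_table(path) -> pd.DataFrame:
    """Read a samples-by-taxa TSV count table.

    Raises
    ------
    FormatError
        On duplicate sample or taxon identifiers, negative values, or a
        non-numeric body.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"count table not found: {path}")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    taxa = header[1:]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise FormatError(f"duplicate taxon columns: {dupes}")
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.index.has_duplicates:
        raise FormatError("duplicate sample identifiers")
    body = table.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise FormatError("count table body must be numeric")
    if np.any(body < 0):
        raise FormatError("count table contains negative values")
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    return table


def write_count_table(table: pd.DataFrame, path) -> None:
    """Write a count table with lexicographically sorted taxon columns."""
    out = table.loc[:, sorted(table.columns)]
    atomic_write_text(path, out.to_csv(sep="\t", index_label="sample_id"))


def read_fasta(path) -> list:
    """Read FASTA into an ordered list of ``(id, sequence)`` tuples.

    Sequences are upper-cased and must be over the alphabet {A,C,G,T,N}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {rec.id!r} has non-IUPAC-DNA characters: {sorted(bad)}"
            )
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    atomic_write_text(
        path, "".join(f">{name}\n{seq}\n" for name, seq in records)
    )


def write_edge_list(edges: pd.DataFrame, path) -> None:
    """Write an association edge list (taxon_a < taxon_b, sorted rows)."""
    required = ["taxon_a", "taxon_b", "rho", "p"]
    missing = [c for c in required if c not in edges.columns]
    if missing:
        raise FormatError(f"edge list missing columns: {missing}")
    out = edges.loc[:, required].sort_values(["taxon_a", "taxon_b"])
    atomic_write_text(path, out.to_csv(sep="\t", index=False))


def read_edge_list(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read the per-sample metadata CSV (sample_id index, ISO dates)."""
    meta = pd.read_csv(path, index_col=0)
    meta.index = meta.index.astype(str)
    if "date" in meta.columns:
        meta["date"] = pd.to_datetime(meta["date"])
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    atomic_write_text(path, out.to_csv(index_label="sample_id"))


def read_annotation(path) -> pd.DataFrame:
    """Read the per-taxon annotation CSV (lineage + gene flags)."""
    ann = pd.read_csv(path, index_col=0)
    ann.index = ann.index.astype(str)
    for col in ("amo", "nxr"):
        if col in ann.columns:
            ann[col] = ann[col].astype(bool)
    return ann


def write_run_manifest(outdir, command: str, config: dict) -> None:
    """Record the resolved configuration and library versions for a CLI run."""
    import scipy
    import sklearn

    manifest = {
        "command": command,
        "argv": sys.argv,
        "config": config,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    atomic_write_text(
        Path(outdir) / "run_manifest.json", json.dumps(manifest, indent=2)
    )
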