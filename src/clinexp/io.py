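"""Tabular I/O: counts, metadata, gene sets (GMT), tissue profiles, allele counts.

All tabular formats are TSV with a header row; transcripts are rows.
Readers validate structure and raise descriptive errors; ``read(write(x))``
round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

METADATA_COLUMNS = ["sample_id", "population", "latitude", "cage", "dataset", "timepoint"]


@dataclass
class CountMatrix:
    """Transcript x sample non-negative integer counts.

    ``counts`` is a DataFrame indexed by transcript id with sample-id
    columns; ``library_sizes`` are the column sums.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.counts.index
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dupes[:5]}")
        cols = self.counts.columns
        if cols.duplicated().any():
            raise ValueError(f"duplicate sample ids: {cols[cols.duplicated()].tolist()}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def transcript_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass
class NormalizedMatrix:
    """TMM-adjusted counts-per-million with the per-sample factors.

    Factors are positive and have geometric mean one (edgeR convention),
    so normalized values are comparable across runs.
    """

    values: pd.DataFrame
    factors: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.factors is not None:
            f = self.factors.to_numpy(float)
            if (f <= 0).any():
                raise ValueError("normalization factors must be positive")
            if abs(np.exp(np.mean(np.log(f))) - 1.0) > 1e-9:
                raise ValueError("factors must have geometric mean 1")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a transcript x sample count TSV (first column: transcript id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: no sample columns found")
    try:
        return CountMatrix(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t")


def read_metadata(path: str | Path, sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Read sample metadata; optionally check it covers the given samples."""
    meta = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"{path}: metadata missing columns {missing_cols}")
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    if sample_ids is not None:
        uncovered = sorted(set(sample_ids) - set(meta["sample_id"]))
        if uncovered:
            raise ValueError(f"{path}: metadata missing samples {uncovered}")
    return meta


def write_table(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write any result table as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    """Read a result/truth TSV written by this package.

    Only empty fields are treated as missing: the model label ``null``
    must survive the round trip as a string, so pandas' default NA
    vocabulary is disabled.
    """
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       keep_default_na=False, na_values=[""])


def read_gene_sets(path: str | Path) -> list:
    """Read gene sets from GMT (name <tab> description <tab> members...)."""
    from .enrich import GeneSet

    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed GMT line {line!r}")
        sets.append(GeneSet(parts[0], set(parts[2:]), provenance=parts[1]))
    return sets


def write_gene_sets(gene_sets: list, path: str | Path) -> None:
    lines = [
        "\t".join([gs.name, gs.provenance or gs.name, *sorted(gs.members)])
        for gs in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tissue_profiles(path: str | Path) -> pd.DataFrame:
    """Read a transcript x tissue expression TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: tissue profiles need at least 2 tissues")
    if (df.to_numpy(float) < 0).any() or not np.isfinite(df.to_numpy(float)).all():
        raise ValueError(f"{path}: tissue expression must be finite and non-negative")
    return df


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read per-sample allele counts at one biallelic site."""
    df = pd.read_csv(path, sep="\t")
    required = ["sample_id", "site", "count_A", "count_other"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: allele-count table missing columns {missing}")
    if (df[["count_A", "count_other"]].to_numpy() < 0).any():
        raise ValueError(f"{path}: negative allele counts")
    return df
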