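"""Plain-text readers/writers for the pipeline's tabular formats.

Everything is TSV (counts, lengths, metadata, annotation, PPI edges, miRNA
tables, Ct plates) or GMT (genesets, handled in :mod:`mitoscreen.genesets`).
A small YAML column-mapping block lets heterogeneous metadata sheets be
renamed to the canonical schema on load.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .types import CountMatrix

META_COLUMNS = ("sample_id", "dataset", "region_detail", "age", "sex_reported", "pmi", "braak")


def read_counts(counts_path: str | Path, lengths_path: str | Path | None = None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0) if lengths_path else None
    return CountMatrix(counts=counts, lengths=lengths)


def write_counts(cm: CountMatrix, counts_path: str | Path, lengths_path: str | Path | None = None) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    if lengths_path and cm.lengths is not None:
        cm.lengths.round(2).to_csv(lengths_path, sep="\t")


def read_metadata(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    meta = pd.read_csv(path, sep=sep)
    if column_map:
        meta = meta.rename(columns=column_map)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    return meta


def read_column_map(path: str | Path) -> dict[str, str]:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return dict(cfg.get("columns", cfg))


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t")
    if "gene_id" not in annot.columns or "chromosome" not in annot.columns:
        raise ValueError("annotation needs gene_id and chromosome columns")
    return annot.set_index("gene_id")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
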