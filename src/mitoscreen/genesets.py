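"""Keyword-driven geneset focusing.

Rather than enrichment testing, the screen narrows DEGs to a biological
theme by name: genesets whose names contain any of the focus keywords
(default: mitophagy, lysosome, phagosome) are collected across catalogs,
their members are pooled into a non-redundant union, and the union is
intersected with the per-sex DEG lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

DEFAULT_KEYWORDS = ("mitophagy", "lysosome", "phagosome")


@dataclass(frozen=True)
class GenesetEntry:
    set_name: str
    source_db: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"geneset {self.set_name!r} has no members")


def read_gmt(path: str | Path, source_db: str | None = None) -> list[GenesetEntry]:
    """Read a GMT file (tab-separated: name, description, members...).

    The description column is used as the source database tag unless
    ``source_db`` overrides it.
    """
    entries = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        name, desc, members = parts[0], parts[1], [g for g in parts[2:] if g]
        entries.append(GenesetEntry(name, source_db or desc or "unknown", tuple(members)))
    return entries


def write_gmt(entries: list[GenesetEntry], path: str | Path) -> None:
    lines = ["\t".join([e.set_name, e.source_db, *e.members]) for e in entries]
    Path(path).write_text("\n".join(lines) + "\n")


def select_genesets(catalog: list[GenesetEntry], keywords=DEFAULT_KEYWORDS) -> list[GenesetEntry]:
    """Case-insensitive substring match of any keyword against set names.

    Matching considers names only, never member lists.  Monotone in the
    keyword list: adding a keyword can only add matches.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    if not catalog:
        raise ValueError("geneset catalog is empty")
    keys = [k.lower() for k in keywords]
    return [e for e in catalog if any(k in e.set_name.lower() for k in keys)]


def union_members(matched: list[GenesetEntry]) -> list[str]:
    """Order-stable deduplicated union of member genes."""
    seen: dict[str, None] = {}
    for entry in matched:
        for g in entry.members:
            seen.setdefault(g, None)
    return list(seen)


def intersect_degs(union_genes: list[str], degs: pd.DataFrame) -> pd.DataFrame:
    """Restrict a flagged DE table to union members that are DEGs.

    Returns the DEG rows (with direction) whose gene_id is in the union.
    Raises when both inputs are non-empty but share no identifiers at all,
    which almost always means a symbol-vs-Ensembl namespace mismatch.
    """
    deg_rows = degs[degs["is_deg"]]
    if union_genes and len(degs) and not (set(union_genes) & set(degs["gene_id"])):
        raise ValueError(
            "no overlap between geneset members and the DE table gene ids; "
            "check identifier namespaces (gene symbols vs Ensembl ids)"
        )
    return deg_rows[deg_rows["gene_id"].isin(set(union_genes))].copy()


def selection_report(matched: list[GenesetEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [e.set_name for e in matched],
            "source_db": [e.source_db for e in matched],
            "n_members": [len(e.members) for e in matched],
        }
    )
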