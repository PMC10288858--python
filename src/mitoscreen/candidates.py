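"""Candidate key-gene selection from down-regulated DEGs.

Three automatic criteria, applied with inclusive thresholds exactly as
stated:

1. PPI degree >= 20 in the male or female network (max over the networks
   the gene appears in);
2. targeted by at least 10 up-regulated miRNAs;
3. the number of down-regulated miRNAs targeting the gene must not exceed
   one third of the up-regulated count.

A fourth, literature-based criterion is inherently manual: it is carried as
an annotation column and never computed, and it never demotes a gene
automatically.  Genes failing exactly one automatic criterion are reported
as near misses — the mechanism by which a gene like ACTB (down/up miRNA
ratio narrowly violated) still surfaces for manual literature review
instead of vanishing silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEGREE_MIN = 20
UP_MIRNA_MIN = 10
RATIO_MAX = 1.0 / 3.0

_VERDICT_ORDER = {"selected": 0, "near_miss": 1, "rejected": 2}


@dataclass
class CandidateDecision:
    gene_id: str
    direction: str
    degree_ok: bool
    up_mirna_ok: bool
    ratio_ok: bool
    verdict: str
    failed_criteria: list[str] = field(default_factory=list)
    literature_flag: str = "unreviewed"
    max_degree: float = float("nan")
    n_up_mirna: int = 0
    n_down_mirna: int = 0


def evaluate_gene(
    stats: pd.Series | dict,
    direction: str,
    degree_min: int = DEGREE_MIN,
    up_mirna_min: int = UP_MIRNA_MIN,
    ratio_max: float = RATIO_MAX,
) -> CandidateDecision:
    """Apply the three automatic criteria to one gene's network statistics.

    ``stats`` must provide n_up_mirna, n_down_mirna and at least one of
    degree_male / degree_female (a gene absent from both networks is an
    error).  Only down-regulated genes are eligible; others are rejected
    with the reason "direction".
    """
    s = dict(stats)
    degrees = [
        float(s[k])
        for k in ("degree_male", "degree_female")
        if k in s and s[k] is not None and np.isfinite(float(s[k]))
    ]
    if not degrees:
        raise ValueError(f"gene {s.get('gene_id')}: absent from both PPI networks")
    max_degree = max(degrees)
    n_up = int(s["n_up_mirna"])
    n_down = int(s["n_down_mirna"])
    gene_id = str(s.get("gene_id", ""))

    if direction != "down":
        return CandidateDecision(
            gene_id=gene_id, direction=direction,
            degree_ok=False, up_mirna_ok=False, ratio_ok=False,
            verdict="rejected", failed_criteria=["direction"],
            max_degree=max_degree, n_up_mirna=n_up, n_down_mirna=n_down,
        )

    degree_ok = max_degree >= degree_min
    up_ok = n_up >= up_mirna_min
    ratio_ok = n_down <= ratio_max * n_up
    failed = [
        name
        for name, ok in (("degree", degree_ok), ("up_mirna", up_ok), ("ratio", ratio_ok))
        if not ok
    ]
    verdict = "selected" if not failed else ("near_miss" if len(failed) == 1 else "rejected")
    return CandidateDecision(
        gene_id=gene_id, direction=direction,
        degree_ok=degree_ok, up_mirna_ok=up_ok, ratio_ok=ratio_ok,
        verdict=verdict, failed_criteria=failed,
        max_degree=max_degree, n_up_mirna=n_up, n_down_mirna=n_down,
    )


def screen(
    all_stats: pd.DataFrame,
    de_results: dict[str, pd.DataFrame],
    degree_min: int = DEGREE_MIN,
    up_mirna_min: int = UP_MIRNA_MIN,
    ratio_max: float = RATIO_MAX,
    literature: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Evaluate every network gene and emit the ranked candidate report.

    A gene counts as down-regulated when it is a DEG with direction "down"
    in at least one sex stratum.  The report is sorted by (verdict,
    max degree desc, up-miRNA count desc, gene_id) so ordering is fully
    deterministic; near misses form their own tier for manual review.
    """
    down_genes: set[str] = set()
    up_only: set[str] = set()
    for df in de_results.values():
        deg = df[df["is_deg"]]
        down_genes |= set(deg.loc[deg["direction"] == "down", "gene_id"])
        up_only |= set(deg.loc[deg["direction"] == "up", "gene_id"])
    up_only -= down_genes

    lit = {}
    if literature is not None:
        lit = dict(zip(literature["gene_id"], literature["flag"]))

    rows = []
    for _, srow in all_stats.iterrows():
        gid = srow["gene_id"]
        direction = "down" if gid in down_genes else ("up" if gid in up_only else "none")
        d = evaluate_gene(srow, direction, degree_min, up_mirna_min, ratio_max)
        d.literature_flag = lit.get(gid, "unreviewed")
        rows.append(
            {
                "gene_id": d.gene_id,
                "direction": d.direction,
                "degree_male": srow.get("degree_male", np.nan),
                "degree_female": srow.get("degree_female", np.nan),
                "max_degree": d.max_degree,
                "n_up_mirna": d.n_up_mirna,
                "n_down_mirna": d.n_down_mirna,
                "degree_ok": d.degree_ok,
                "up_mirna_ok": d.up_mirna_ok,
                "ratio_ok": d.ratio_ok,
                "failed_criteria": ",".join(d.failed_criteria),
                "literature_flag": d.literature_flag,
                "verdict": d.verdict,
            }
        )
    report = pd.DataFrame(rows)
    if report.empty:
        return report
    report["_v"] = report["verdict"].map(_VERDICT_ORDER)
    report = (
        report.sort_values(
            ["_v", "max_degree", "n_up_mirna", "gene_id"],
            ascending=[True, False, False, True],
            kind="mergesort",
        )
        .drop(columns="_v")
        .reset_index(drop=True)
    )
    return report


def selected_genes(report: pd.DataFrame) -> list[str]:
    if report.empty:
        return []
    return report.loc[report["verdict"] == "selected", "gene_id"].tolist()
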