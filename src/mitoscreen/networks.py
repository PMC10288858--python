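"""PPI subnetworks and the miRNA-mRNA corroboration network.

Per sex, the protein-protein interaction subnetwork is induced on the
keyword-focused DEGs ("member" nodes), augmented with DEGs outside the
genesets that interact with at least ``augment_k`` member genes ("candidate
new member" nodes).  Node degrees from this final augmented subgraph feed
the candidate criteria.

The miRNA side rests on the regulatory logic that an up-regulated miRNA
suppresses its targets: a down-regulated gene predominantly targeted by
up-regulated miRNAs has corroborated differential expression.  Each miRNA's
direction is resolved by majority over its up/down literature-report
counts; ties (including 0-0) are excluded entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class PPINetwork:
    graph: nx.Graph
    sex_stratum: str | None = None

    @property
    def node_table(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": n,
                "membership": d.get("membership"),
                "log2fc": d.get("log2fc", np.nan),
                "direction": d.get("direction", "none"),
                "degree": self.graph.degree(n),
            }
            for n, d in self.graph.nodes(data=True)
        ]
        return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)

    @property
    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), name="degree").sort_index()


def clean_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Normalise a PPI edge table.

    Scores above 1 are assumed to be on the 0-1000 combined-score scale and
    are rescaled.  Self-loops are dropped; duplicate unordered pairs keep
    the maximum score.
    """
    df = edges.rename(columns={df_c: df_c.lower() for df_c in edges.columns}).copy()
    required = {"gene_a", "gene_b", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    df["score"] = pd.to_numeric(df["score"])
    if (df["score"] > 1.0).any():
        df["score"] = df["score"] / 1000.0
    df = df[df["gene_a"] != df["gene_b"]]
    pairs = [tuple(sorted((str(a), str(b)))) for a, b in zip(df["gene_a"], df["gene_b"])]
    df = df.assign(
        gene_a=[p[0] for p in pairs],
        gene_b=[p[1] for p in pairs],
    )
    return (
        df.groupby(["gene_a", "gene_b"], as_index=False)["score"].max()
    )


def build_ppi(
    edges: pd.DataFrame,
    selected_degs: list[str],
    all_degs: pd.DataFrame,
    score_min: float = 0.4,
    augment_k: int = 20,
    iterate: bool = False,
    sex_stratum: str | None = None,
) -> PPINetwork:
    """Build the augmented PPI subnetwork for one sex.

    1. drop edges below ``score_min``;
    2. member nodes = ``selected_degs`` (keyword-geneset DEGs);
    3. every other DEG interacting with >= ``augment_k`` distinct member
       nodes joins as a candidate new member (single pass by default; with
       ``iterate=True`` the rule is applied to members + previously added
       nodes until a fixpoint);
    4. the network is the induced subgraph on members plus added nodes, and
       degrees are computed within it.
    """
    if not selected_degs:
        raise ValueError("selected_degs is empty; nothing to build a network on")
    e = clean_edges(edges)
    e = e[e["score"] >= score_min]
    members = set(selected_degs)
    deg_ids = set(all_degs.loc[all_degs["is_deg"], "gene_id"])
    outsiders = deg_ids - members

    adj: dict[str, set[str]] = {}
    for ga, gb in e[["gene_a", "gene_b"]].itertuples(index=False):
        adj.setdefault(ga, set()).add(gb)
        adj.setdefault(gb, set()).add(ga)

    anchor = set(members)
    added: set[str] = set()
    while True:
        new = {
            g
            for g in outsiders - added
            if len(adj.get(g, set()) & anchor) >= augment_k
        }
        added |= new
        if not iterate or not new:
            break
        anchor |= new

    nodes = members | added
    G = nx.Graph()
    G.add_nodes_from(nodes)
    sub = e[e["gene_a"].isin(nodes) & e["gene_b"].isin(nodes)]
    G.add_weighted_edges_from(sub.itertuples(index=False, name=None), weight="score")
    info = all_degs.set_index("gene_id")
    for n in nodes:
        G.nodes[n]["membership"] = "geneset_member" if n in members else "candidate_new_member"
        if n in info.index:
            G.nodes[n]["log2fc"] = float(info.at[n, "log2fc"])
            G.nodes[n]["direction"] = str(info.at[n, "direction"])
    return PPINetwork(graph=G, sex_stratum=sex_stratum)


def resolve_mirna_directions(reports: pd.DataFrame) -> pd.Series:
    """Majority-vote direction per miRNA; equal report counts are excluded.

    ``reports`` columns: mirna, n_up_reports, n_down_reports.  A 0-0 row is
    a tie and is excluded like any other.
    """
    up = reports["n_up_reports"].to_numpy()
    down = reports["n_down_reports"].to_numpy()
    if (up < 0).any() or (down < 0).any():
        raise ValueError("report counts must be non-negative")
    direction = np.where(up > down, "up", np.where(down > up, "down", "excluded"))
    return pd.Series(direction, index=reports["mirna"].to_numpy(), name="direction")


def tally_mirna_targets(
    targets: pd.DataFrame,
    directions: pd.Series,
    genes: list[str],
) -> pd.DataFrame:
    """Count distinct up/down-regulated miRNAs targeting each gene.

    ``targets`` columns: mirna, gene.  Duplicate pairs (the same interaction
    from two source databases) count once; miRNAs resolved as excluded
    contribute to neither tally.
    """
    t = targets[["mirna", "gene"]].drop_duplicates()
    t = t[t["gene"].isin(set(genes))]
    t = t.assign(direction=t["mirna"].map(directions))
    t = t[t["direction"].isin(["up", "down"])]
    counts = (
        t.groupby(["gene", "direction"])["mirna"].nunique().unstack(fill_value=0)
    )
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["n_up_mirna"] = counts["up"].reindex(out.index).fillna(0).astype(int) if "up" in counts else 0
    out["n_down_mirna"] = counts["down"].reindex(out.index).fillna(0).astype(int) if "down" in counts else 0
    return out.reset_index()


def gene_net_stats(
    networks: dict[str, PPINetwork],
    targets: pd.DataFrame,
    reports: pd.DataFrame,
) -> pd.DataFrame:
    """Combine per-sex PPI degrees with miRNA tallies into one table.

    One row per gene present in at least one network; absent degrees are
    left missing (NaN).
    """
    genes: dict[str, None] = {}
    for net in networks.values():
        for n in net.graph.nodes:
            genes.setdefault(n, None)
    gene_list = list(genes)
    stats = pd.DataFrame({"gene_id": gene_list})
    for sex, net in networks.items():
        deg = net.degrees
        stats[f"degree_{sex}"] = deg.reindex(gene_list).to_numpy()
    directions = resolve_mirna_directions(reports)
    tallies = tally_mirna_targets(targets, directions, gene_list)
    return stats.merge(tallies, on="gene_id", how="left")


def export_network(
    network: PPINetwork,
    outdir: str | Path,
    prefix: str = "ppi",
    mirna_targets: pd.DataFrame | None = None,
    mirna_directions: pd.Series | None = None,
    focus_genes: list[str] | None = None,
) -> dict[str, Path]:
    """Write node/edge/SIF tables, plus an optional focused bipartite
    miRNA-mRNA edge table restricted to ``focus_genes``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    nodes = network.node_table
    paths["nodes"] = outdir / f"{prefix}_nodes.tsv"
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edge_rows = [
        {"gene_a": a, "gene_b": b, "score": d.get("score", np.nan)}
        for a, b, d in network.graph.edges(data=True)
    ]
    edges = pd.DataFrame(edge_rows, columns=["gene_a", "gene_b", "score"])
    paths["edges"] = outdir / f"{prefix}_edges.tsv"
    edges.to_csv(paths["edges"], sep="\t", index=False)
    paths["sif"] = outdir / f"{prefix}.sif"
    with open(paths["sif"], "w") as fh:
        for r in edge_rows:
            fh.write(f"{r['gene_a']}\tpp\t{r['gene_b']}\n")
    if mirna_targets is not None and mirna_directions is not None:
        t = mirna_targets[["mirna", "gene"]].drop_duplicates()
        if focus_genes is not None:
            t = t[t["gene"].isin(set(focus_genes))]
        t = t.assign(direction=t["mirna"].map(mirna_directions))
        t = t[t["direction"].isin(["up", "down"])]
        paths["mirna_edges"] = outdir / f"{prefix}_mirna_edges.tsv"
        t.to_csv(paths["mirna_edges"], sep="\t", index=False)
    return paths


def import_network(nodes_path: str | Path, edges_path: str | Path, sex_stratum: str | None = None) -> PPINetwork:
    """Rebuild a network from exported node/edge tables (round-trip)."""
    nodes = pd.read_csv(nodes_path, sep="\t")
    edges = pd.read_csv(edges_path, sep="\t")
    G = nx.Graph()
    for row in nodes.itertuples(index=False):
        G.add_node(
            row.gene_id,
            membership=row.membership,
            log2fc=row.log2fc,
            direction=row.direction,
        )
    for row in edges.itertuples(index=False):
        G.add_edge(row.gene_a, row.gene_b, score=row.score)
    return PPINetwork(graph=G, sex_stratum=sex_stratum)
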