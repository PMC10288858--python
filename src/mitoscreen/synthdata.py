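"""Synthetic cohorts, networks, genesets and qPCR plates with known truth.

The generator emulates the statistical structure the screening pipeline
assumes, so that every downstream stage is testable without controlled-
access consortium data:

* counts are negative-binomially distributed (Var = mu + alpha mu^2) with
  per-gene baseline means, per-sample library sizes, per-dataset gene-wise
  multiplicative batch effects, and average-transcript-length offsets with
  small per-sample jitter;
* differential expression is planted per sex with configurable effect size
  and fraction, some of it sex-specific;
* chrY-assigned genes are essentially silent in true-female samples, giving
  the orders-of-magnitude Y/X ratio separation the sex check exploits, and
  a small fraction of samples carries a deliberately mislabeled sex;
* metadata includes ages that straddle the >65 inclusion boundary, PMI,
  Braak stages including the ambiguous stage III, and a mostly-frontal mix
  of region names;
* companion network tables wire the planted candidate genes so that they —
  and only they — satisfy all three automatic selection criteria, while
  decoy genes fail exactly one criterion each and one miRNA carries tied
  up/down report counts to exercise the tie-exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GenesetEntry
from .types import CountMatrix, GroundTruth

_GROUP_KEYS = ("ad_male", "ad_female", "control_male", "control_female")


@dataclass
class SimConfig:
    """Study conditions for a simulated multi-dataset cohort.

    Defaults describe a modest two-dataset pooled brain cohort: 2,000 genes,
    15 samples per disease x sex cell per dataset, 10% planted DEGs at
    |log2FC| = 1, per-gene NB dispersion around 0.05, mild per-dataset
    gene-wise batch effects (log-SD 0.1) and library sizes within ±30%.
    """

    n_genes: int = 2000
    n_datasets: int = 2
    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {k: 15 for k in _GROUP_KEYS}
    )
    frac_deg: float = 0.1
    lfc_magnitude: float = 1.0
    dispersion_base: float = 0.05
    batch_sd: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.3)
    frac_sexlinked: float = 0.02
    seed: int = 0
    # secondary knobs
    frac_sex_specific: float = 0.2
    sex_mislabel_rate: float = 0.02
    frac_sex_missing: float = 0.02
    frac_braak3: float = 0.05
    frac_nonfrontal: float = 0.05
    age_range: tuple[float, float] = (60.0, 95.0)
    chrx_female_factor: float = 2.0  # X-inactivation-escape style chrX boost
    batch_confounding: float = 0.0
    n_candidates: int = 3
    n_hubs: int = 2
    n_support: int = 40
    base_log_mean: float = 4.0
    base_log_sd: float = 1.0
    length_jitter_sd: float = 0.01

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_datasets <= 0:
            raise ValueError("n_genes and n_datasets must be positive")
        for key in _GROUP_KEYS:
            if key not in self.samples_per_group or self.samples_per_group[key] < 0:
                raise ValueError(f"samples_per_group must give a non-negative count for {key!r}")
        for name in ("frac_deg", "frac_sexlinked", "frac_sex_specific", "sex_mislabel_rate",
                     "frac_sex_missing", "frac_braak3", "frac_nonfrontal", "batch_confounding"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lfc_magnitude < 0 or self.dispersion_base <= 0 or self.batch_sd < 0:
            raise ValueError("lfc_magnitude >= 0, dispersion_base > 0, batch_sd >= 0 required")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValueError("libsize_range must be positive with low <= high")


_FRONTAL_NAMES = (
    "dorsolateral prefrontal cortex",
    "superior frontal gyrus",
    "frontal cortex",
)
_BRAAK_CONTROL = ("0", "I", "II")
_BRAAK_AD = ("IV", "V", "VI")


def _build_samples(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample sheet with true condition/sex and dataset assignments."""
    rows = []
    for d in range(config.n_datasets):
        dataset = f"DS{d + 1}"
        for key in _GROUP_KEYS:
            condition = "AD" if key.startswith("ad") else "control"
            sex = "male" if key.endswith("male") and not key.endswith("female") else "female"
            n = config.samples_per_group[key]
            # partial confounding: skew AD towards the first dataset and
            # controls towards the last
            if config.batch_confounding > 0 and config.n_datasets > 1:
                first = d == 0
                c = config.batch_confounding
                if condition == "AD":
                    n = int(round(n * (1 + c))) if first else int(round(n * (1 - c)))
                else:
                    n = int(round(n * (1 - c))) if first else int(round(n * (1 + c)))
            rows.extend(
                {"dataset": dataset, "condition": condition, "true_sex": sex}
                for _ in range(n)
            )
    df = pd.DataFrame(rows)
    df.insert(0, "sample_id", [f"S{i + 1:04d}" for i in range(len(df))])
    return df


def simulate_cohort(config: SimConfig):
    """Generate (CountMatrix, metadata, gene annotation, GroundTruth).

    Counts are drawn gamma-Poisson with mean
    mu_gs = libsize_s * lengthnorm_gs * base_g * batch_gd * 2^(lfc * I[AD])
    (times a near-zero factor for chrY genes in true-female samples) and
    per-gene dispersion jittered around ``dispersion_base``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    gene_index = pd.Index(genes)

    # chromosome assignment
    n_sex = int(round(config.frac_sexlinked * config.n_genes))
    n_y = max(n_sex // 3, 1) if n_sex else 0
    sex_idx = rng.choice(config.n_genes, size=n_sex, replace=False) if n_sex else np.array([], int)
    chrom = np.array([f"chr{(i % 22) + 1}" for i in range(config.n_genes)], dtype=object)
    chrom[sex_idx[:n_y]] = "chrY"
    chrom[sex_idx[n_y:]] = "chrX"
    annotation = pd.DataFrame({"gene_id": genes, "chromosome": chrom}).set_index("gene_id")

    base = np.exp(rng.normal(config.base_log_mean, config.base_log_sd, config.n_genes))
    alpha = config.dispersion_base * np.exp(rng.normal(0.0, 0.3, config.n_genes))

    # plant DEGs on autosomal genes
    lfc = pd.DataFrame(0.0, index=gene_index, columns=["male", "female"])
    labels = pd.DataFrame("null", index=gene_index, columns=["male", "female"])
    autosomal = np.setdiff1d(np.arange(config.n_genes), sex_idx)
    n_deg = int(round(config.frac_deg * config.n_genes))
    deg_idx = rng.choice(autosomal, size=min(n_deg, len(autosomal)), replace=False)
    signs = rng.choice([-1.0, 1.0], size=len(deg_idx))
    patterns = rng.choice(
        ["both", "male", "female"],
        size=len(deg_idx),
        p=[1 - config.frac_sex_specific, config.frac_sex_specific / 2, config.frac_sex_specific / 2],
    )
    for i, sgn, pat in zip(deg_idx, signs, patterns):
        g = genes[i]
        for sex in ("male", "female"):
            if pat in ("both", sex):
                lfc.loc[g, sex] = sgn * config.lfc_magnitude
                labels.loc[g, sex] = "up" if sgn > 0 else "down"

    # anchor genes for the network stage: candidates (down in both sexes),
    # support members (both-sex DEGs) and hubs (both-sex DEGs kept out of
    # the genesets); anchors get boosted baselines so DE recovers them
    both = (labels["male"] != "null") & (labels["female"] != "null")
    both_down = list(labels.index[both & (labels["male"] == "down")])
    both_any = list(labels.index[both])
    cands = both_down[: config.n_candidates]
    remaining = [g for g in both_any if g not in cands]
    support = remaining[: config.n_support]
    hubs = [g for g in remaining[config.n_support:] if g not in support][: config.n_hubs]
    anchors = cands + support + hubs
    if anchors:
        pos = gene_index.get_indexer(anchors)
        base[pos] = np.exp(rng.uniform(np.log(50.0), np.log(300.0), len(pos)))

    samples = _build_samples(config, rng)
    n_samples = len(samples)
    if n_samples == 0:
        raise ValueError("configuration yields zero samples")

    # metadata fields
    age = rng.uniform(config.age_range[0], config.age_range[1], n_samples)
    pmi = rng.uniform(2.0, 40.0, n_samples)
    braak = np.where(
        samples["condition"] == "AD",
        rng.choice(_BRAAK_AD, n_samples),
        rng.choice(_BRAAK_CONTROL, n_samples),
    ).astype(object)
    n_b3 = int(round(config.frac_braak3 * n_samples))
    if n_b3:
        braak[rng.choice(n_samples, n_b3, replace=False)] = "III"
    region = rng.choice(_FRONTAL_NAMES, n_samples).astype(object)
    n_nf = int(round(config.frac_nonfrontal * n_samples))
    if n_nf:
        region[rng.choice(n_samples, n_nf, replace=False)] = "cerebellum"

    reported = samples["true_sex"].to_numpy(dtype=object).copy()
    mislabeled: list[str] = []
    n_mis = int(round(config.sex_mislabel_rate * n_samples))
    if n_mis:
        flip = rng.choice(n_samples, n_mis, replace=False)
        for i in flip:
            reported[i] = "female" if reported[i] == "male" else "male"
        mislabeled = samples["sample_id"].iloc[flip].tolist()
    n_missing = int(round(config.frac_sex_missing * n_samples))
    if n_missing:
        unk = rng.choice(
            np.setdiff1d(np.arange(n_samples), [samples.index[samples["sample_id"] == s][0] for s in mislabeled]),
            n_missing,
            replace=False,
        )
        reported[unk] = "unknown"

    meta = pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "dataset": samples["dataset"],
            "region_detail": region,
            "age": np.round(age, 1),
            "sex_reported": reported,
            "pmi": np.round(pmi, 1),
            "braak": braak,
        }
    )

    # mean model
    libsize = rng.uniform(config.libsize_range[0], config.libsize_range[1], n_samples)
    lengths_g = np.exp(rng.normal(np.log(2000.0), 0.5, config.n_genes))
    jitter = np.exp(rng.normal(0.0, config.length_jitter_sd, (config.n_genes, n_samples)))
    lengths = lengths_g[:, None] * jitter
    lengthnorm = lengths / np.exp(np.log(lengths).mean(axis=1, keepdims=True))

    batch = np.exp(rng.normal(0.0, config.batch_sd, (config.n_genes, config.n_datasets)))
    ds_index = samples["dataset"].map({f"DS{d + 1}": d for d in range(config.n_datasets)}).to_numpy()

    is_ad = (samples["condition"] == "AD").to_numpy()
    sex_col = samples["true_sex"].to_numpy()
    lfc_per_sample = np.where(sex_col == "male", 1, 0)
    lfc_mat = np.where(
        lfc_per_sample[None, :] == 1,
        lfc["male"].to_numpy()[:, None],
        lfc["female"].to_numpy()[:, None],
    )
    mu = (
        libsize[None, :]
        * lengthnorm
        * base[:, None]
        * batch[:, ds_index]
        * np.power(2.0, lfc_mat * is_ad[None, :])
    )
    ymask = chrom == "chrY"
    xmask = chrom == "chrX"
    female = sex_col == "female"
    mu[np.ix_(ymask, female)] *= 1e-3
    mu[np.ix_(xmask, female)] *= config.chrx_female_factor

    lam = rng.gamma(shape=1.0 / alpha[:, None], scale=alpha[:, None] * mu)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_index, columns=meta["sample_id"]),
        lengths=pd.DataFrame(lengths, index=gene_index, columns=meta["sample_id"]),
    )
    truth = GroundTruth(
        deg_labels=labels,
        true_lfc=lfc,
        batch_assignments=pd.Series(samples["dataset"].to_numpy(), index=meta["sample_id"]),
        true_sex=pd.Series(sex_col, index=meta["sample_id"]),
        planted_hubs=hubs,
        planted_candidates=cands,
        support_genes=support,
        mislabeled_samples=mislabeled,
    )
    return cm, meta, annotation, truth


# ---------------------------------------------------------------------------
# networks / genesets / miRNA tables
# ---------------------------------------------------------------------------

def simulate_networks(
    truth: GroundTruth,
    config: SimConfig,
    augment_k: int = 20,
):
    """Generate (PPI edges, geneset catalog, miRNA targets, miRNA reports).

    Planted candidates are wired to >= ``augment_k`` + 5 geneset-member DEGs
    with high-confidence scores and given >= 10 up-regulated targeting
    miRNAs with at most a third as many down-regulated ones, so they pass
    all three automatic criteria by construction.  Two decoys each fail
    exactly one criterion; hubs sit outside the genesets but meet the
    augmentation threshold; one miRNA carries tied report counts.
    """
    genes = list(truth.deg_labels.index)
    if not genes:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng(config.seed + 104729)  # fixed offset stream

    cands = list(truth.planted_candidates)
    support = list(truth.support_genes)
    hubs = list(truth.planted_hubs)
    if len(support) < augment_k + 5:
        raise ValueError(
            f"need at least {augment_k + 5} support genes to wire candidates; got {len(support)}"
        )

    # geneset catalog: members = candidates + support + some null genes
    special = set(cands) | set(support) | set(hubs)
    null_pool = [g for g in genes if g not in special and truth.deg_labels.loc[g, "male"] == "null"]
    null_members = list(rng.choice(null_pool, size=min(30, len(null_pool)), replace=False))
    members = cands + support + null_members

    def pick(pool, n):
        return list(rng.choice(pool, size=min(n, len(pool)), replace=False))

    catalog = [
        GenesetEntry("GO_MITOPHAGY", "GO", tuple(sorted(set(cands + pick(support, 20) + pick(null_members, 8))))),
        GenesetEntry("KEGG_LYSOSOME", "KEGG", tuple(sorted(set(pick(cands, 2) + pick(support, 25) + pick(null_members, 10))))),
        GenesetEntry("GO_PHAGOSOME_MATURATION", "GO", tuple(sorted(set(pick(support, 15) + pick(null_members, 6))))),
        GenesetEntry("REACTOME_RECEPTOR_MEDIATED_MITOPHAGY", "Reactome", tuple(sorted(set(cands + pick(support, 10))))),
        GenesetEntry("KEGG_APOPTOSIS", "KEGG", tuple(sorted(pick(null_pool, 25)))),
        GenesetEntry("GO_AXON_GUIDANCE", "GO", tuple(sorted(pick(null_pool, 20)))),
    ]
    # guarantee every support gene is a member of some keyword set
    missing = [g for g in support if not any(g in e.members for e in catalog[:4])]
    if missing:
        catalog[0] = GenesetEntry(
            "GO_MITOPHAGY", "GO", tuple(sorted(set(catalog[0].members) | set(missing)))
        )

    # PPI edges
    edges: list[tuple[str, str, float]] = []
    down_support = [g for g in support if truth.deg_labels.loc[g, "male"] == "down"]
    decoy_pool = [g for g in down_support if g not in cands]
    decoy_degree = decoy_pool[0] if decoy_pool else None      # fails only the up-miRNA count
    decoy_ratio = decoy_pool[1] if len(decoy_pool) > 1 else None  # fails only the down/up ratio

    def wire(g, n, score_lo=0.7):
        partners = pick([s for s in support if s != g], n)
        for p in partners:
            edges.append((g, p, float(rng.uniform(score_lo, 0.99))))

    for g in cands:
        wire(g, augment_k + 5)
    for g in hubs:
        wire(g, augment_k + 2)
    for g in (decoy_degree, decoy_ratio):
        if g is not None:
            wire(g, augment_k + 2)
    # sparse background among members, some edges below the score cutoff
    for _ in range(len(members)):
        a, b = pick(members, 2) if len(members) > 1 else (None, None)
        if a and b and a != b:
            edges.append((a, b, float(rng.uniform(0.4, 0.95))))
    for _ in range(10):
        a, b = pick(members, 2) if len(members) > 1 else (None, None)
        if a and b and a != b:
            edges.append((a, b, float(rng.uniform(0.05, 0.35))))
    ppi = pd.DataFrame(edges, columns=["gene_a", "gene_b", "score"])

    # miRNA pools and reports
    up_pool = [f"hsa-miR-{i:03d}-5p" for i in range(1, 61)]
    down_pool = [f"hsa-miR-{i:03d}-3p" for i in range(61, 81)]
    tied = "hsa-miR-999-5p"
    report_rows = []
    for m in up_pool:
        n_up = int(rng.integers(1, 6))
        report_rows.append((m, n_up, int(rng.integers(0, n_up))))
    for m in down_pool:
        n_down = int(rng.integers(1, 6))
        report_rows.append((m, int(rng.integers(0, n_down)), n_down))
    report_rows.append((tied, 2, 2))
    reports = pd.DataFrame(report_rows, columns=["mirna", "n_up_reports", "n_down_reports"])

    target_rows: list[tuple[str, str]] = []

    def target(gene, n_up, n_down):
        for m in pick(up_pool, n_up):
            target_rows.append((m, gene))
        for m in pick(down_pool, n_down):
            target_rows.append((m, gene))

    for g in cands:
        n_up = 12
        target(g, n_up, int(rng.integers(0, n_up // 3 + 1)))  # <= floor(up/3)
        target_rows.append((tied, g))  # excluded miRNA: must not count
    if decoy_degree is not None:
        target(decoy_degree, 3, 0)      # high degree, too few up-miRNAs
    if decoy_ratio is not None:
        target(decoy_ratio, 12, 6)      # 6 > 12/3: ratio criterion fails
    for g in support:
        if g in (decoy_degree, decoy_ratio):
            continue
        target(g, int(rng.integers(0, 5)), int(rng.integers(0, 5)))
    # duplicated rows exercise distinct-miRNA counting
    if target_rows:
        target_rows.extend(target_rows[:3])
    targets = pd.DataFrame(target_rows, columns=["mirna", "gene"])
    return ppi, catalog, targets, reports


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

REFERENCE_GENES = ("HPRT1", "RPL13A")
_REF_BASE_CT = {"HPRT1": 20.0, "RPL13A": 22.0}
_TARGET_BASE_CT = 25.0


def simulate_qpcr(
    n_pairs: int,
    true_log2fc: float | dict[str, float],
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    target: str = "VCP",
) -> pd.DataFrame:
    """Simulate a long-format Ct table for target + two reference genes.

    ``n_pairs`` control/AD sample pairs are generated (sexes alternate
    between pairs).  In AD samples the target Ct is shifted by
    -true_log2fc, so the downstream relative quantity recovers
    2^true_log2fc exactly when ``ct_noise_sd`` is zero.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be non-negative")
    lfc_map = true_log2fc if isinstance(true_log2fc, dict) else {target: float(true_log2fc)}
    rng = np.random.default_rng(seed)
    rows = []
    sid = 0
    for i in range(n_pairs):
        sex = "male" if i % 2 == 0 else "female"
        for group in ("control", "AD"):
            sid += 1
            sample = f"Q{sid:03d}"
            for ref, ct0 in _REF_BASE_CT.items():
                rows.append((sample, group, sex, ref, ct0 + rng.normal(0, ct_noise_sd) if ct_noise_sd else ct0))
            for gene, lfc in lfc_map.items():
                ct = _TARGET_BASE_CT
                if group == "AD":
                    ct = ct - lfc  # lower expression -> higher Ct
                if ct_noise_sd:
                    ct += rng.normal(0, ct_noise_sd)
                rows.append((sample, group, sex, gene, ct))
    return pd.DataFrame(rows, columns=["sample_id", "group", "sex", "gene", "ct"])
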