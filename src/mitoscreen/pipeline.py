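"""End-to-end screen: counts + metadata + network tables -> candidate report.

Stages: metadata preparation and inclusion filtering; expression-based sex
prediction (used for stratification by default, so unlabeled or mislabeled
samples are handled); per-sex surrogate-variable estimation and NB-Wald
differential expression; keyword geneset focusing; per-sex PPI networks
with candidate-new-member augmentation; miRNA direction resolution and
tallies; candidate criteria.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import candidates as candidates_mod
from . import cohort as cohort_mod
from . import de as de_mod
from . import genesets as genesets_mod
from . import networks as networks_mod
from . import sexcheck as sexcheck_mod
from .types import CountMatrix, DesignSpec

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    report: pd.DataFrame
    selected: list[str]
    de_results: dict[str, pd.DataFrame]
    networks: dict[str, networks_mod.PPINetwork]
    stats: pd.DataFrame
    sex_calls: pd.DataFrame
    exclusion_log: pd.DataFrame
    degs_in_union: dict[str, list[str]] = field(default_factory=dict)


def run_de_stratum(
    cm: CountMatrix,
    meta: pd.DataFrame,
    sex: str,
    sex_column: str = "sex",
    k_svs: int = 2,
    covariate_columns: tuple[str, ...] = ("age", "pmi"),
) -> pd.DataFrame:
    """Run the NB-Wald DE model on one sex stratum."""
    sub = meta[meta[sex_column] == sex]
    usable = sub["diagnosis"].isin(["AD", "control"])
    if (~usable).any():
        logger.info("dropping %d samples without AD/control diagnosis", int((~usable).sum()))
        sub = sub[usable]
    if sub.empty:
        raise ValueError(f"no samples in sex stratum {sex!r}")
    sub_cm = cm.subset_samples(sub["sample_id"].tolist())
    condition = pd.Series(
        sub["diagnosis"].to_numpy(), index=sub["sample_id"].to_numpy(), name="condition"
    )
    covs = sub.set_index("sample_id")[list(covariate_columns)].astype(float)
    design = DesignSpec(condition=condition, covariates=covs, sex_stratum=sex)
    if k_svs > 0:
        svs = de_mod.estimate_svs(sub_cm, design, k=k_svs)
        design = DesignSpec(
            condition=condition, covariates=covs, surrogate_variables=svs, sex_stratum=sex
        )
    return de_mod.fit_de(sub_cm, design)


def run_screen(
    cm: CountMatrix,
    meta: pd.DataFrame,
    annotation: pd.DataFrame,
    catalog,
    ppi_edges: pd.DataFrame,
    mirna_targets: pd.DataFrame,
    mirna_reports: pd.DataFrame,
    keywords=genesets_mod.DEFAULT_KEYWORDS,
    min_age: float = 65.0,
    lobe: str = "frontal",
    k_svs: int = 2,
    use_predicted_sex: bool = True,
    score_min: float = 0.4,
    augment_k: int = 20,
    degree_min: int = candidates_mod.DEGREE_MIN,
    up_mirna_min: int = candidates_mod.UP_MIRNA_MIN,
    ratio_max: float = candidates_mod.RATIO_MAX,
    literature: pd.DataFrame | None = None,
) -> ScreenResult:
    prepared = cohort_mod.prepare_metadata(meta)
    included, exclusion_log = cohort_mod.apply_inclusion(prepared, min_age=min_age, lobe=lobe)
    logger.info("cohort: %d included, %d excluded", len(included), len(exclusion_log))

    sub_cm = cm.subset_samples(included["sample_id"].tolist())
    calls = sexcheck_mod.predict_sex(
        sub_cm, annotation, reported=included.set_index("sample_id")["sex_reported"]
    )
    call_map = calls.frame.set_index("sample_id")["predicted"]
    included = included.assign(
        sex=call_map.reindex(included["sample_id"]).to_numpy()
        if use_predicted_sex
        else included["sex_reported"].to_numpy()
    )

    matched = genesets_mod.select_genesets(catalog, keywords)
    union = genesets_mod.union_members(matched)

    de_results: dict[str, pd.DataFrame] = {}
    nets: dict[str, networks_mod.PPINetwork] = {}
    degs_in_union: dict[str, list[str]] = {}
    for sex in ("male", "female"):
        res = run_de_stratum(sub_cm, included, sex, k_svs=k_svs)
        de_results[sex] = res
        selected = genesets_mod.intersect_degs(union, res)
        degs_in_union[sex] = selected["gene_id"].tolist()
        nets[sex] = networks_mod.build_ppi(
            ppi_edges,
            degs_in_union[sex],
            res,
            score_min=score_min,
            augment_k=augment_k,
            sex_stratum=sex,
        )

    stats = networks_mod.gene_net_stats(nets, mirna_targets, mirna_reports)
    report = candidates_mod.screen(
        stats,
        de_results,
        degree_min=degree_min,
        up_mirna_min=up_mirna_min,
        ratio_max=ratio_max,
        literature=literature,
    )
    return ScreenResult(
        report=report,
        selected=candidates_mod.selected_genes(report),
        de_results=de_results,
        networks=nets,
        stats=stats,
        sex_calls=calls.frame,
        exclusion_log=exclusion_log,
        degs_in_union=degs_in_union,
    )
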