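"""Expression-based sex prediction from chrY/chrX read-count ratios plus PCA.

Post-mortem metadata sheets frequently lack or mislabel sex.  Because chrY
genes are essentially silent in female samples, the log10 ratio of total
chrY to total chrX counts is strongly bimodal and separates the sexes by
orders of magnitude.  We call sex by a largest-gap split of the sorted
ratios (deterministic, seed-free, equivalent to 2-means for bimodal 1-D
data) and corroborate the calls with a PCA on sex-chromosome gene
expression.  Mismatches with the reported sex are flagged, never silently
corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class SexCallTable:
    """Per-sample sex calls. ``frame`` columns: sample_id, yx_log_ratio,
    predicted, pca_concordant, mismatch_with_reported."""

    frame: pd.DataFrame
    gap: float
    used_fallback: bool


def _chrom_masks(counts: pd.DataFrame, annotation: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    chrom = annotation.reindex(counts.index)["chromosome"].astype(str).str.lower()
    y = chrom.isin(["chry", "y"]).to_numpy()
    x = chrom.isin(["chrx", "x"]).to_numpy()
    for mask, name in ((x, "chrX"), (y, "chrY")):
        if not mask.any():
            raise ValueError(f"no {name} genes in the annotation; cannot compute Y/X ratio")
    return y, x


def yx_ratio(cm: CountMatrix, annotation: pd.DataFrame, pseudocount: float = 1.0) -> pd.Series:
    """log10((total chrY counts + pc) / (total chrX counts + pc)) per sample."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    ymask, xmask = _chrom_masks(cm.counts, annotation)
    arr = cm.counts.to_numpy(dtype=float)
    ysum = arr[ymask].sum(axis=0)
    xsum = arr[xmask].sum(axis=0)
    return pd.Series(np.log10((ysum + pseudocount) / (xsum + pseudocount)), index=cm.sample_ids)


def call_sex(
    ratios: pd.Series,
    reported: pd.Series | None = None,
    min_separation: float = 1.0,
    fallback_threshold: float = -1.0,
) -> SexCallTable:
    """Split samples into female (low ratio) / male (high ratio).

    Uses the largest gap in the sorted ratios as the split point; if that
    gap is below ``min_separation`` (log10 units) the cohort is likely
    single-sex or degenerate, so a fixed threshold is applied instead and a
    warning logged.
    """
    vals = ratios.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("ratios must be finite")
    used_fallback = False
    if len(vals) < 2:
        logger.warning("single sample: falling back to fixed ratio threshold")
        cut, used_fallback = fallback_threshold, True
    else:
        order = np.argsort(vals)
        svals = vals[order]
        gaps = np.diff(svals)
        i = int(np.argmax(gaps))
        if gaps[i] < min_separation:
            logger.warning(
                "largest ratio gap %.3f < %.3f; falling back to threshold %.2f",
                gaps[i], min_separation, fallback_threshold,
            )
            cut, used_fallback = fallback_threshold, True
        else:
            cut = (svals[i] + svals[i + 1]) / 2.0
    predicted = np.where(vals > cut, "male", "female")
    gap = float(np.max(np.diff(np.sort(vals)))) if len(vals) > 1 else 0.0
    frame = pd.DataFrame(
        {
            "sample_id": ratios.index,
            "yx_log_ratio": vals,
            "predicted": predicted,
            "pca_concordant": pd.array([None] * len(vals), dtype="boolean"),
        }
    )
    if reported is not None:
        rep = reported.reindex(ratios.index).astype(str).str.lower()
        frame["mismatch_with_reported"] = (
            rep.isin(["male", "female"]).to_numpy() & (rep.to_numpy() != predicted)
        )
    else:
        frame["mismatch_with_reported"] = False
    return SexCallTable(frame=frame, gap=gap, used_fallback=used_fallback)


def pca_concordance(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    calls: SexCallTable,
    min_genes: int = 3,
) -> SexCallTable:
    """Check ratio-based calls against PC1 of sex-chromosome expression.

    Expression is CPM-normalised and log-transformed, restricted to chrX/chrY
    genes, then gene-standardised (zero mean, unit variance) before the SVD
    — the correlation-PCA scaling stops the enormous on/off variance of chrY
    genes from drowning out the milder chrX sex signal, which is exactly
    what lets the check catch a sample whose chrY counts disagree with its
    chrX pattern.  Each sample's side of PC1 is compared with its call;
    sides are oriented by the mean PC1 coordinate of each called group.
    Degenerate decompositions (fewer than ``min_genes`` sex-chromosome
    genes, or PC1 variance ~ 0) leave the concordance flag unknown rather
    than failing.
    """
    frame = calls.frame.copy()
    ymask, xmask = _chrom_masks(cm.counts, annotation)
    sexmask = ymask | xmask
    if sexmask.sum() < min_genes:
        logger.warning("fewer than %d sex-chromosome genes; PCA concordance skipped", min_genes)
        return SexCallTable(frame, calls.gap, calls.used_fallback)
    arr = cm.counts.to_numpy(dtype=float)
    depth = arr.sum(axis=0)
    depth[depth == 0] = 1.0
    expr = np.log2(arr[sexmask] / depth * 1e6 + 1.0)
    centred = expr - expr.mean(axis=1, keepdims=True)
    sd = centred.std(axis=1, keepdims=True)
    centred = np.divide(centred, sd, out=np.zeros_like(centred), where=sd > 0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 1e-10:
        logger.warning("degenerate PCA (no variance); concordance left unknown")
        return SexCallTable(frame, calls.gap, calls.used_fallback)
    pc1 = vt[0]
    male = frame["predicted"].to_numpy() == "male"
    if male.any() and (~male).any():
        orient = np.sign(pc1[male].mean() - pc1[~male].mean()) or 1.0
        side_male = orient * pc1 > 0
        frame["pca_concordant"] = pd.array(side_male == male, dtype="boolean")
    else:
        # single predicted sex: PC1 side carries no between-group information
        frame["pca_concordant"] = pd.array([None] * len(frame), dtype="boolean")
    return SexCallTable(frame, calls.gap, calls.used_fallback)


def predict_sex(
    cm: CountMatrix,
    annotation: pd.DataFrame,
    reported: pd.Series | None = None,
    pseudocount: float = 1.0,
    min_separation: float = 1.0,
) -> SexCallTable:
    """Convenience wrapper: ratio -> calls -> PCA concordance."""
    ratios = yx_ratio(cm, annotation, pseudocount)
    calls = call_sex(ratios, reported=reported, min_separation=min_separation)
    return pca_concordance(cm, annotation, calls)
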