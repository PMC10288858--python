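"""qPCR relative quantification (2^-ddCt) and group testing.

ΔCt normalises the target's Ct against the arithmetic mean of the
reference-gene Cts (equivalent to geometric-mean normalisation on the
linear scale); ΔΔCt calibrates against the mean control ΔCt within each
stratum; the relative quantity is 2^-ΔΔCt, so the control-group mean RQ is
~1 by construction.  Group comparisons are two-sample t-tests run on ΔCt
— the log scale, where approximate normality is plausible — with
Bonferroni correction across the comparison family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: significance stars at conventional figure thresholds
STAR_THRESHOLDS = ((0.0001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


def delta_ct(table: pd.DataFrame, target: str, references: list[str]) -> pd.DataFrame:
    """Per-sample ΔCt = Ct(target) - mean Ct(references).

    ``table`` is long format with columns sample_id, group, sex, gene, ct.
    Samples missing the target or all references are dropped with a log
    line.
    """
    if not references:
        raise ValueError("at least one reference gene is required")
    rows = []
    for (sid, group, sex), sub in table.groupby(["sample_id", "group", "sex"], sort=False):
        cts = dict(zip(sub["gene"], sub["ct"]))
        refs = [cts[r] for r in references if r in cts]
        if target not in cts or not refs:
            logger.info("sample %s dropped: missing target or all reference Cts", sid)
            continue
        rows.append(
            {
                "sample_id": sid,
                "group": group,
                "sex": sex,
                "gene": target,
                "delta_ct": cts[target] - float(np.mean(refs)),
            }
        )
    return pd.DataFrame(rows)


def rq_2ddct(delta: pd.DataFrame, stratify_by_sex: bool = True) -> pd.DataFrame:
    """Relative quantities by the 2^-ΔΔCt method.

    Within each (sex) stratum, ΔΔCt is the sample's ΔCt minus the mean ΔCt
    of that stratum's control samples; RQ = 2^-ΔΔCt.  A stratum without
    controls is an error naming the stratum.
    """
    keys = ["sex"] if stratify_by_sex else []
    out = []
    groups = delta.groupby(keys, sort=False) if keys else [((), delta)]
    for key, sub in groups:
        ctrl = sub.loc[sub["group"] == "control", "delta_ct"]
        if ctrl.empty:
            raise ValueError(f"stratum {key!r} has no control samples to calibrate against")
        cal = float(ctrl.mean())
        s = sub.copy()
        s["ddct"] = s["delta_ct"] - cal
        s["rq"] = 2.0 ** (-s["ddct"])
        out.append(s)
    return pd.concat(out, ignore_index=True)


def _stars(p: float) -> str:
    for cut, mark in STAR_THRESHOLDS:
        if p < cut:
            return mark
    return "ns"


def group_test(
    delta: pd.DataFrame,
    stratify_by_sex: bool = True,
    paired: bool = False,
) -> pd.DataFrame:
    """AD-vs-control t-tests on ΔCt per stratum, Bonferroni-adjusted.

    The Bonferroni factor is the number of comparisons in the family (one
    per stratum).  Returns per-comparison raw and adjusted p, significance
    stars, and mean ± SD of the relative quantities per group.
    """
    rq = rq_2ddct(delta, stratify_by_sex=stratify_by_sex)
    keys = ["sex"] if stratify_by_sex else []
    comparisons = list(rq.groupby(keys, sort=False)) if keys else [((), rq)]
    m = len(comparisons)
    rows = []
    for key, sub in comparisons:
        ad = sub[sub["group"] == "AD"]
        ctrl = sub[sub["group"] == "control"]
        if len(ad) < 2 or len(ctrl) < 2:
            raise ValueError(f"stratum {key!r} needs >= 2 samples per group")
        a = ad["delta_ct"].to_numpy()
        c = ctrl["delta_ct"].to_numpy()
        if np.ptp(a) == 0 and np.ptp(c) == 0 and np.isclose(a.mean(), c.mean()):
            p = 1.0
        elif paired:
            if len(a) != len(c):
                raise ValueError("paired test requires equal group sizes")
            p = float(stats.ttest_rel(a, c).pvalue)
        else:
            p = float(stats.ttest_ind(a, c).pvalue)
        p_adj = min(p * m, 1.0)
        label = key[0] if isinstance(key, tuple) and key else "all"
        rows.append(
            {
                "comparison": f"AD_vs_control[{label}]",
                "n_ad": len(ad),
                "n_control": len(ctrl),
                "mean_rq_ad": float(ad["rq"].mean()),
                "sd_rq_ad": float(ad["rq"].std(ddof=1)),
                "mean_rq_control": float(ctrl["rq"].mean()),
                "sd_rq_control": float(ctrl["rq"].std(ddof=1)),
                "p_raw": p,
                "p_bonferroni": p_adj,
                "stars": _stars(p_adj),
            }
        )
    return pd.DataFrame(rows)
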