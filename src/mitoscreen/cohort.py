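"""Cohort definition: region mapping, Braak-based diagnosis, inclusion filters.

The analysis cohort pools post-mortem brain samples from several datasets.
A sample enters the differential-expression cohort only if it comes from the
target lobe (frontal by default), the donor was strictly older than the
minimum age (late-onset disease only), and the Braak stage yields an
unambiguous diagnosis: stages 0/I/II are controls, IV/V/VI are AD, and the
intermediate stage III is excluded outright.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

#: Default synonym table mapping detailed region names to lobes.  Matching is
#: case-insensitive on the normalised string; unrecognised regions map to
#: "other" rather than raising.
REGION_SYNONYMS: dict[str, tuple[str, ...]] = {
    "frontal": (
        "frontal lobe",
        "frontal cortex",
        "frontal pole",
        "prefrontal cortex",
        "dorsolateral prefrontal cortex",
        "superior frontal gyrus",
        "inferior frontal gyrus",
        "anterior prefrontal cortex",
    ),
    "temporal": (
        "temporal lobe",
        "temporal cortex",
        "superior temporal gyrus",
        "middle temporal gyrus",
        "parahippocampal gyrus",
        "fusiform gyrus",
    ),
    "parietal": ("parietal lobe", "parietal cortex", "angular gyrus", "precuneus"),
    "occipital": ("occipital lobe", "occipital cortex", "primary visual cortex"),
    "cerebellum": ("cerebellum", "cerebellar cortex", "cerebellar hemisphere"),
}

_BRAAK_ALIASES = {
    "0": 0, "O": 0,
    "I": 1, "1": 1,
    "II": 2, "2": 2,
    "III": 3, "3": 3,
    "IV": 4, "4": 4,
    "V": 5, "5": 5,
    "VI": 6, "6": 6,
}
_ROMAN = ["0", "I", "II", "III", "IV", "V", "VI"]


def map_brain_region(region_detail: str, synonyms: dict[str, tuple[str, ...]] | None = None) -> str:
    """Map a detailed brain-region name to a lobe label.

    Total function: any string not found in the synonym table returns
    ``"other"``.
    """
    if synonyms is None:
        synonyms = REGION_SYNONYMS
    key = str(region_detail).strip().lower()
    for lobe, names in synonyms.items():
        if key == lobe or key in (n.lower() for n in names):
            return lobe
    return "other"


def parse_braak(value) -> int | None:
    """Normalise a Braak stage (roman numeral, digit, or int) to 0..6.

    Missing / unparseable values return None.
    """
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, (int,)) and 0 <= value <= 6:
        return int(value)
    s = str(value).strip().upper()
    if s in ("", "NA", "NAN", "NONE"):
        return None
    if s in _BRAAK_ALIASES:
        return _BRAAK_ALIASES[s]
    try:
        f = float(s)
        if f.is_integer() and 0 <= f <= 6:
            return int(f)
    except ValueError:
        pass
    return None


def classify_braak(braak) -> str:
    """Diagnosis from Braak stage: 0/I/II control, IV/V/VI AD, III excluded.

    A missing stage yields ``"missing"`` — deliberately distinct from
    ``"excluded"`` so that samples dropped for absent pathology data are
    never conflated with the ambiguous stage-III group.
    """
    stage = parse_braak(braak)
    if stage is None:
        return "missing"
    if stage <= 2:
        return "control"
    if stage == 3:
        return "excluded"
    return "AD"


def parse_age(value) -> tuple[float | None, bool]:
    """Parse an age field; censored entries like ``"90+"`` become (90.0, True)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None, False
    s = str(value).strip()
    censored = s.endswith("+")
    if censored:
        s = s[:-1]
    try:
        age = float(s)
    except ValueError:
        return None, False
    if age < 0:
        raise ValueError(f"negative age: {value!r}")
    return age, censored


def prepare_metadata(meta: pd.DataFrame, synonyms: dict[str, tuple[str, ...]] | None = None) -> pd.DataFrame:
    """Normalise a raw metadata sheet in place of ad-hoc per-dataset munging.

    Adds: ``region_lobe``, numeric ``age`` (+ ``age_censored``), ``diagnosis``
    from the Braak stage, and a median-imputed ``pmi`` (+ ``pmi_imputed``
    flag).  The input frame is not modified.
    """
    out = meta.copy()
    out["region_lobe"] = out["region_detail"].map(lambda r: map_brain_region(r, synonyms))
    parsed = out["age"].map(parse_age)
    out["age"] = [p[0] for p in parsed]
    out["age_censored"] = [p[1] for p in parsed]
    out["diagnosis"] = out["braak"].map(classify_braak)
    pmi = pd.to_numeric(out.get("pmi"), errors="coerce")
    missing = pmi.isna()
    if missing.any():
        med = pmi.median()
        pmi = pmi.fillna(med)
        logger.info("imputed PMI for %d samples with cohort median %.2f", int(missing.sum()), med)
    out["pmi"] = pmi
    out["pmi_imputed"] = missing.to_numpy()
    return out


def apply_inclusion(
    meta: pd.DataFrame,
    min_age: float = 65.0,
    lobe: str = "frontal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the cohort inclusion filters.

    Keeps samples whose lobe matches, whose age is strictly above
    ``min_age``, and whose diagnosis is AD or control.  Returns the included
    frame and an exclusion log with one reason code per dropped sample; when
    a sample fails several rules the first failing rule in the fixed order
    region -> age -> braak is recorded, keeping logs deterministic.
    """
    if meta.empty:
        logger.warning("apply_inclusion called on an empty metadata frame")
        return meta.copy(), pd.DataFrame(columns=["sample_id", "reason"])
    if "diagnosis" not in meta.columns or "region_lobe" not in meta.columns:
        raise ValueError("metadata must be run through prepare_metadata first")

    reasons: list[tuple[str, str]] = []
    keep: list[bool] = []
    for _, row in meta.iterrows():
        reason = None
        if row["region_lobe"] != lobe:
            reason = "region"
        elif row["age"] is None or pd.isna(row["age"]) or not row["age"] > min_age:
            reason = "age"
        elif row["diagnosis"] == "excluded":
            reason = "braak_ambiguous"
        elif row["diagnosis"] == "missing":
            reason = "braak_missing"
        keep.append(reason is None)
        if reason is not None:
            reasons.append((row["sample_id"], reason))
    included = meta.loc[keep].copy()
    log = pd.DataFrame(reasons, columns=["sample_id", "reason"])
    return included, log
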