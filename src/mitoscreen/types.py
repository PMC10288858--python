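"""Shared in-memory containers for the screening pipeline.

The pipeline's tabular data live in pandas objects throughout; the small
dataclasses here only bundle matrices that must travel together (raw counts
with their per-gene-per-sample average transcript lengths) or attach
semantics that a bare frame would lose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene x sample raw counts with optional average transcript lengths.

    ``counts`` holds non-negative integers (genes in rows, samples in
    columns).  ``lengths``, when present, has the same shape and carries the
    average transcript length of each gene in each sample, as produced by
    transcript-level quantification summarised to gene level; it feeds the
    length-aware normalisation offsets.
    """

    counts: pd.DataFrame
    lengths: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.ndim != 2 or c.shape[0] == 0 or c.shape[1] == 0:
            raise ValueError("count matrix must be non-empty and 2-dimensional")
        arr = c.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        if self.lengths is not None:
            if self.lengths.shape != c.shape:
                raise ValueError("lengths must match the count matrix shape")
            if not self.lengths.index.equals(c.index) or not self.lengths.columns.equals(c.columns):
                raise ValueError("lengths must share the count matrix index/columns")
            if np.any(self.lengths.to_numpy() <= 0):
                raise ValueError("average transcript lengths must be strictly positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        """Return a new matrix restricted to ``sample_ids`` (order kept)."""
        cols = [s for s in sample_ids if s in self.counts.columns]
        lengths = self.lengths[cols] if self.lengths is not None else None
        return CountMatrix(self.counts[cols], lengths)


@dataclass
class DesignSpec:
    """Design for one sex stratum of the differential-expression model.

    ``condition`` is a per-sample series with levels {"AD", "control"};
    the AD-vs-control contrast is always the last, tested coefficient.
    ``covariates`` (age, PMI, ...) and ``surrogate_variables`` are optional
    per-sample numeric frames aligned to the same samples.
    """

    condition: pd.Series
    covariates: pd.DataFrame | None = None
    surrogate_variables: pd.DataFrame | None = None
    sex_stratum: str | None = None

    def __post_init__(self) -> None:
        levels = set(self.condition.unique())
        if not levels <= {"AD", "control"}:
            raise ValueError(f"condition levels must be AD/control, got {levels}")
        for extra in (self.covariates, self.surrogate_variables):
            if extra is not None and not extra.index.equals(self.condition.index):
                raise ValueError("covariates/SVs must be aligned to condition samples")

    @property
    def sample_ids(self) -> pd.Index:
        return self.condition.index

    def matrix(self) -> pd.DataFrame:
        """Full design matrix: intercept, covariates, SVs, condition last.

        Numeric covariates are centred and scaled to unit variance (constant
        columns are left at zero) so the intercept stays interpretable and
        the IRLS solve is well conditioned.
        """
        cols: dict[str, np.ndarray] = {"intercept": np.ones(len(self.condition))}
        for frame, tag in ((self.covariates, "cov"), (self.surrogate_variables, "sv")):
            if frame is None:
                continue
            for name in frame.columns:
                v = frame[name].to_numpy(dtype=float)
                sd = v.std()
                cols[f"{tag}_{name}"] = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
        cols["condition_AD"] = (self.condition == "AD").to_numpy(dtype=float)
        X = pd.DataFrame(cols, index=self.condition.index)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("design matrix is rank-deficient (collinear columns)")
        return X


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort.

    ``deg_labels`` / ``true_lfc`` are gene x {male, female} frames with
    values in {up, down, null} and the planted log2 fold changes.
    ``planted_candidates`` satisfy the candidate-selection criteria by
    construction once the matching network tables are generated;
    ``planted_hubs`` are DEGs outside the genesets wired to enough member
    genes to be pulled in as candidate new members.
    """

    deg_labels: pd.DataFrame
    true_lfc: pd.DataFrame
    batch_assignments: pd.Series
    true_sex: pd.Series
    planted_hubs: list[str] = field(default_factory=list)
    planted_candidates: list[str] = field(default_factory=list)
    support_genes: list[str] = field(default_factory=list)
    mislabeled_samples: list[str] = field(default_factory=list)
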