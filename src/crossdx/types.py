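"""Core in-memory containers shared across the pipeline.

All tabular data are pandas objects: counts and normalized expression are
gene x sample DataFrames (gene ids as index, sample ids as columns), sample
metadata is one row per sample, and per-gene results are DataFrames indexed
by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DISORDERS = ("AUT", "SCZ", "BPD")

#: metadata columns every study must carry
REQUIRED_META = ("diagnosis", "subject_id", "site", "brain_region", "age", "sex")


@dataclass
class EffectProfile:
    """Ground-truth per-gene log2 fold-changes for the three disorders.

    ``beta`` is a gene x disorder DataFrame (columns AUT, SCZ, BPD, log2
    units); ``is_null`` marks gene/disorder cells with exactly zero effect;
    ``rho`` is the 3x3 target correlation of non-null effects.
    """

    beta: pd.DataFrame
    is_null: pd.DataFrame
    rho: np.ndarray

    @property
    def gene_ids(self) -> pd.Index:
        return self.beta.index

    def __post_init__(self) -> None:
        if list(self.beta.columns) != list(DISORDERS):
            raise ValueError(f"beta columns must be {DISORDERS}")
        if not np.isfinite(self.beta.to_numpy()).all():
            raise ValueError("beta contains non-finite values")
        if (self.beta.to_numpy()[self.is_null.to_numpy()] != 0).any():
            raise ValueError("is_null genes must have beta exactly 0")


@dataclass
class CountStudy:
    """Raw counts plus gene annotation and sample metadata for one study."""

    counts: pd.DataFrame          # genes x samples, non-negative integers
    gene_length: pd.Series        # bp, indexed by gene
    gene_gc: pd.Series            # fraction in (0, 1), indexed by gene
    sample_meta: pd.DataFrame     # one row per sample, index = sample id
    design_kind: str              # "repeated_multisite" | "shared_control"

    def __post_init__(self) -> None:
        if self.design_kind not in ("repeated_multisite", "shared_control"):
            raise ValueError(f"unknown design_kind {self.design_kind!r}")
        c = self.counts.to_numpy()
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            c = self.counts.to_numpy()
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.equals(self.sample_meta.index):
            raise ValueError("counts columns must match sample_meta index")
        for col in ("diagnosis", "subject_id"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta missing required column {col!r}")
        gc = self.gene_gc.reindex(self.counts.index)
        ln = self.gene_length.reindex(self.counts.index)
        if gc.isna().any() or ln.isna().any():
            raise ValueError("gene annotation missing for some genes in counts")
        if ((gc <= 0) | (gc >= 1)).any():
            raise ValueError("gene_gc must lie strictly in (0, 1)")
        if (ln < 1).any():
            raise ValueError("gene_length must be >= 1")
        if self.design_kind == "shared_control":
            if self.sample_meta["subject_id"].duplicated().any():
                raise ValueError("shared_control design requires unique subject ids")
        else:
            labels = self.sample_meta.groupby("subject_id")["diagnosis"].nunique()
            if (labels > 1).any():
                bad = labels[labels > 1].index.tolist()
                raise ValueError(f"subjects with discordant diagnoses: {bad}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountStudy":
        idx = pd.Index(gene_ids, name=self.counts.index.name)
        return CountStudy(
            counts=self.counts.loc[idx],
            gene_length=self.gene_length.loc[idx],
            gene_gc=self.gene_gc.loc[idx],
            sample_meta=self.sample_meta,
            design_kind=self.design_kind,
        )


@dataclass
class NormalizedMatrix:
    """Gene x sample log2 expression with masked entries stored as NaN.

    ``values`` holds normalized expression; NaN marks entries excluded from
    every downstream computation (per-gene outlier masking). ``provenance``
    records the filter and normalization parameters applied.
    """

    values: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def mask(self) -> pd.DataFrame:
        """True where the entry is available (unmasked)."""
        return self.values.notna()

    def n_unmasked(self) -> pd.Series:
        return self.values.notna().sum(axis=1)

    def usable_genes(self, min_unmasked: int) -> pd.Index:
        ok = self.n_unmasked() >= min_unmasked
        return self.values.index[ok]


@dataclass
class ModelSpec:
    """Per-gene differential expression model specification.

    ``covariates`` name sample-metadata columns entered as fixed effects;
    categorical columns (object/category dtype) are dummy-coded. ``n_sv``
    surrogate variables are estimated from the expression residuals and
    appended as fixed covariates. ``random_intercept`` names a grouping
    column (subject_id) for the repeated-measures mixed model, or None for
    ordinary least squares.
    """

    covariates: Sequence[str]
    n_sv: int = 0
    random_intercept: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_sv < 0:
            raise ValueError("n_sv must be >= 0")


# Per-gene tables -----------------------------------------------------------

DGEA_COLUMNS = ("effect", "se", "z", "p", "n_used", "flag")


def DgeaTable(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-gene differential expression table.

    Columns: effect (log2, case minus control), se, z = effect/se, p
    (two-sided), n_used, flag (empty string when the fit is clean).
    """
    missing = [c for c in DGEA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"DgeaTable missing columns {missing}")
    ok = frame["flag"] == ""
    z = frame.loc[ok, "z"]
    if not np.isfinite(z).all():
        raise ValueError("non-finite Z for unflagged genes")
    return frame


@dataclass
class NullEnsemble:
    """Z vectors from B label-permutation reruns of one contrast.

    ``z`` is a B x genes DataFrame (one row per permutation). Extreme
    statistics for cutoffs are derived downstream so the same ensemble can
    serve the pairwise, three-way and correlation analyses.
    """

    z: pd.DataFrame
    strata: Sequence[str]
    unit: str
    seed: int

    @property
    def B(self) -> int:
        return self.z.shape[0]

    @property
    def gene_ids(self) -> pd.Index:
        return self.z.columns


@dataclass
class SplitControlResult:
    """Median Z over random control halvings, per case group.

    ``median_z`` maps case label -> per-gene median Z across ``n_splits``
    runs; ``z_runs`` maps case label -> n_splits x genes DataFrame;
    ``assignments`` is an n_splits x n_controls boolean DataFrame (True =
    control placed in the first half, i.e. compared with the first case
    group).
    """

    median_z: dict
    z_runs: dict
    assignments: pd.DataFrame
    n_splits: int
    seed: int
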