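"""Expression filtering, GC/length normalization and outlier masking.

The normalization removes smooth per-sample trends in GC content and
log-length from log2 counts-per-million, standing in for conditional
quantile normalization: downstream statistics depend only on the trend
removal, which the spline-residual scheme achieves deterministically.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from patsy import dmatrix

from .types import CountStudy, NormalizedMatrix

log = logging.getLogger(__name__)


def filter_low_expression(
    study: CountStudy, min_reads: int = 10, min_frac: float = 0.75
) -> CountStudy:
    """Keep genes observed at >= ``min_reads`` in >= ``min_frac`` of samples.

    A gene is kept iff the number of samples with count >= ``min_reads`` is
    at least ``ceil(min_frac * n_samples)``. The sample set is unchanged;
    idempotent.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must lie in (0, 1]")
    need = math.ceil(min_frac * study.n_samples)
    n_ok = (study.counts >= min_reads).sum(axis=1)
    keep = study.counts.index[n_ok >= need]
    if len(keep) == 0:
        raise ValueError(
            f"no gene passes the expression filter (min_reads={min_reads}, "
            f"min_frac={min_frac}); review thresholds"
        )
    return study.subset_genes(keep)


def _log2_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """log2 counts-per-million with a library-size-scaled pseudocount.

    The pseudocount 0.5 * (library size / mean library size) makes the
    transform exactly invariant to overall sequencing depth: samples that
    are scalar multiples of one another map to identical values.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        bad = counts.columns[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {bad}")
    rel = lib / lib.mean()
    x = np.log2((counts.to_numpy(dtype=float) + 0.5 * rel[None, :]) / lib[None, :] * 1e6)
    return pd.DataFrame(x, index=counts.index, columns=counts.columns)


def _spline_basis(values: np.ndarray, df: int = 5) -> np.ndarray:
    """Natural cubic regression spline basis with knots at quantiles."""
    return np.asarray(dmatrix("cr(x, df=df) - 1", {"x": values, "df": df}))


def normalize_gc_length(study: CountStudy, spline_df: int = 5) -> NormalizedMatrix:
    """Remove per-sample GC and log-length trends from log2-CPM expression.

    Each sample's log2-CPM vector is regressed on natural cubic spline bases
    of GC fraction and log2 gene length (``spline_df`` functions each, knots
    at quantiles); the fitted trend, centered within the sample, is
    subtracted, so per-sample means — and hence per-gene mean offsets — are
    preserved while the covariate trends are removed. Deterministic; a
    constant GC or length vector skips that covariate with a warning.
    """
    x = _log2_cpm(study.counts)
    gc = study.gene_gc.loc[x.index].to_numpy(dtype=float)
    loglen = np.log2(study.gene_length.loc[x.index].to_numpy(dtype=float))

    blocks = [np.ones((len(gc), 1))]
    for name, v in (("gc", gc), ("log-length", loglen)):
        if np.ptp(v) == 0:
            log.warning("constant %s vector; skipping that covariate", name)
            continue
        blocks.append(_spline_basis(v, df=spline_df))
    basis = np.hstack(blocks)

    X = x.to_numpy()
    # one least-squares fit per sample, shared basis across samples
    coef, *_ = np.linalg.lstsq(basis, X, rcond=None)
    fitted = basis @ coef
    normalized = X - (fitted - fitted.mean(axis=0, keepdims=True))
    values = pd.DataFrame(normalized, index=x.index, columns=x.columns)
    return NormalizedMatrix(
        values=values,
        provenance={
            "normalization": "log2-CPM, per-sample spline residual",
            "spline_df": spline_df,
            "design_kind": study.design_kind,
        },
    )


def mask_outliers(norm: NormalizedMatrix, k: float = 2.7) -> NormalizedMatrix:
    """Mask per-gene entries more than ``k`` sample s.d. from the gene mean.

    Means and standard deviations (n-1 denominator) are computed once over
    each gene's currently unmasked entries — a single pass, never iterated —
    and the mask is monotone: entries already masked stay masked. Genes with
    zero or undefined s.d. mask nothing.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    X = norm.values.to_numpy(copy=True)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, ddof=1, keepdims=True)
        far = np.abs(X - mean) > k * sd
    far &= np.isfinite(X) & (sd > 0)
    X[far] = np.nan
    prov = dict(norm.provenance)
    prov["outlier_k"] = k
    prov["n_masked"] = int(far.sum())
    return NormalizedMatrix(
        values=pd.DataFrame(X, index=norm.values.index, columns=norm.values.columns),
        provenance=prov,
    )
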