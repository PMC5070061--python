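"""Enrichment of differential expression at GWAS-suggestive genes.

Gene-based GWAS p-values (computed externally) select a suggestive gene set;
the differential expression p-values at those genes are compared against the
uniform expectation (QQ coordinates) and against the same computation on
permutation null ensembles. The visual QQ comparison is made quantitative
through the median-based inflation factor lambda, judged against the null
ensembles' 95th percentile.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)  # ~0.4549


def pointwise_empirical_p(obs: pd.Series, null_z: pd.DataFrame) -> pd.Series:
    """Per-gene pointwise empirical p of |observed| against its own null
    column, with the add-one convention: (1 + #{|null| >= |obs|}) / (B + 1)."""
    common = obs.index.intersection(null_z.columns)
    o = np.abs(obs.loc[common].to_numpy(dtype=float))
    N = np.abs(null_z[common].to_numpy(dtype=float))
    B = N.shape[0]
    p = (1 + (N >= o[None, :]).sum(axis=0)) / (B + 1)
    return pd.Series(p, index=common, name="empirical_p")


def null_pointwise_p(null_z: pd.DataFrame) -> pd.DataFrame:
    """Empirical p for each permutation's |Z| ranked within the ensemble.

    Row b, gene g gets p = #{b': |z_{b'g}| >= |z_{bg}|} / B (self included,
    so the minimum is 1/B) — the null analogue of
    :func:`pointwise_empirical_p` for QQ null bands.
    """
    N = np.abs(null_z.to_numpy(dtype=float))
    B = N.shape[0]
    # rank within each column, descending: p = rank / B
    order = np.argsort(np.argsort(-N, axis=0, kind="stable"), axis=0)
    p = (order + 1) / B
    return pd.DataFrame(p, index=null_z.index, columns=null_z.columns)


def _lambda(p: np.ndarray) -> float:
    """Median-based genomic inflation: median chi2(1) quantile of the
    observed p over the chi2(1) median."""
    chi = stats.chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), 1)
    return float(np.median(chi) / _CHI2_MEDIAN)


def qq_enrichment(
    dgea_p: pd.Series,
    gwas: pd.DataFrame,
    p_cutoff: float,
    null_p: pd.DataFrame,
    n_null: Optional[int] = None,
) -> dict:
    """QQ comparison of DGEA p at GWAS-suggestive genes versus null bands.

    Restricts to genes with GWAS p < ``p_cutoff`` (``p_cutoff=1`` keeps the
    whole universe), emits sorted observed -log10 p against uniform expected
    quantiles i/(n+1), computes lambda for the observation and for each of
    ``n_null`` permutation-derived p vectors, and calls "enriched" iff the
    observed lambda exceeds the null 95th percentile. Fewer than 10
    selected genes flags the result underpowered.
    """
    if not (0 < p_cutoff <= 1):
        raise ValueError("p_cutoff must lie in (0, 1]")
    if "p" not in gwas.columns:
        raise ValueError("gwas table must have a 'p' column indexed by gene_id")
    universe = dgea_p.index.intersection(gwas.index).intersection(null_p.columns)
    sel = universe[gwas.loc[universe, "p"] < p_cutoff] if p_cutoff < 1 else universe
    underpowered = len(sel) < 10
    if len(sel) == 0:
        return {
            "qq": pd.DataFrame(
                {"expected_neglog10": [], "observed_neglog10": []}
            ),
            "lambda": float("nan"),
            "null_lambda": np.array([]),
            "null_lambda_95": float("nan"),
            "enriched": False,
            "n_genes": 0,
            "p_cutoff": p_cutoff,
            "underpowered": True,
        }

    obs = dgea_p.loc[sel].to_numpy(dtype=float)
    n = len(obs)
    expected = np.arange(1, n + 1) / (n + 1)
    qq = pd.DataFrame(
        {
            "expected_neglog10": -np.log10(expected),
            "observed_neglog10": -np.log10(np.sort(obs)),
        }
    )

    nul = null_p[sel].to_numpy(dtype=float)
    if n_null is not None:
        if n_null > nul.shape[0]:
            raise ValueError(
                f"n_null={n_null} exceeds available permutations ({nul.shape[0]})"
            )
        nul = nul[:n_null]
    lam_obs = _lambda(obs)
    lam_null = np.array([_lambda(row) for row in nul])
    crit = float(np.quantile(lam_null, 0.95))
    return {
        "qq": qq,
        "lambda": lam_obs,
        "null_lambda": lam_null,
        "null_lambda_95": crit,
        "enriched": bool(lam_obs > crit),
        "n_genes": n,
        "p_cutoff": p_cutoff,
        "underpowered": underpowered,
    }


def cutoff_sweep(
    dgea_p: pd.Series,
    gwas: pd.DataFrame,
    null_p: pd.DataFrame,
    cutoffs: Sequence[float] = (0.01, 0.05, 0.1, 1.0),
    n_null: Optional[int] = None,
) -> pd.DataFrame:
    """Run :func:`qq_enrichment` at several GWAS cutoffs; one report."""
    rows = []
    for c in cutoffs:
        res = qq_enrichment(dgea_p, gwas, c, null_p, n_null=n_null)
        rows.append(
            {
                "p_cutoff": c,
                "n_genes": res["n_genes"],
                "lambda": res["lambda"],
                "null_lambda_95": res["null_lambda_95"],
                "enriched": res["enriched"],
                "underpowered": res["underpowered"],
            }
        )
    return pd.DataFrame(rows).set_index("p_cutoff")
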