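"""Gene-set enrichment of cross-disorder differential expression.

Two complementary routes: (1) a threshold-free set statistic built by
Stouffer-combining per-disorder Z-scores per gene and then per set, with
empirical permutation significance and a study-wide max-over-sets threshold;
(2) classical over-representation of thresholded DEG lists via the
hypergeometric test with Benjamini-Hochberg or Bonferroni correction.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .crossdisorder import empirical_cutoff
from .types import NullEnsemble

log = logging.getLogger(__name__)


def stouffer_combine(z_vectors: Sequence[pd.Series]) -> pd.Series:
    """Stouffer combination across disorders: Z_comb = (sum Z_i) / sqrt(k).

    Preserves unit variance for independent standard-normal inputs. Vectors
    are intersected on gene id (with a warning when sets differ); order of
    the first vector's surviving genes is preserved.
    """
    if len(z_vectors) < 2:
        raise ValueError("need >= 2 Z vectors to combine")
    common = z_vectors[0].index
    for z in z_vectors[1:]:
        common = common.intersection(z.index)
    if len(common) == 0:
        raise ValueError("empty gene intersection across Z vectors")
    if any(len(z) != len(common) for z in z_vectors):
        log.warning("Z vectors had unequal gene sets; intersected to %d", len(common))
    common = z_vectors[0].index[z_vectors[0].index.isin(common)]
    total = sum(z.loc[common] for z in z_vectors)
    return total / np.sqrt(len(z_vectors))


def _set_stat(z: np.ndarray, idx: np.ndarray) -> float:
    """U_S = |sum of combined Z over the set| / sqrt(|S|)."""
    return abs(z[idx].sum()) / np.sqrt(len(idx))


def set_enrichment_empirical(
    combined: pd.Series,
    sets: Dict[str, Sequence[str]],
    null_combined: pd.DataFrame,
    alpha: float = 0.05,
    min_size: int = 5,
) -> pd.DataFrame:
    """Empirical set enrichment of combined Z against permutation nulls.

    Each set's statistic is the absolute set-level Stouffer value of the
    per-gene combined Z, U_S = |sum_{g in S} Z_comb,g| / sqrt(|S|); the same
    statistic is computed from every permutation's combined Z (rows of
    ``null_combined``). Per-set empirical p uses the add-one convention; the
    study-wide threshold is the (1 - alpha) empirical quantile of the
    per-permutation maximum U over sets. Sets with fewer than ``min_size``
    genes after intersection with the universe are dropped.
    """
    if not sets:
        raise ValueError("empty set collection")
    universe = combined.index
    z = combined.to_numpy(dtype=float)
    nul = null_combined[universe].to_numpy(dtype=float)
    B = nul.shape[0]

    kept = {}
    for name, members in sets.items():
        idx = universe.get_indexer(pd.Index(members).intersection(universe))
        if len(idx) >= min_size:
            kept[name] = np.sort(idx)
    if not kept:
        raise ValueError(f"no set has >= {min_size} genes in the universe")

    names = list(kept)
    u_obs = np.array([_set_stat(z, kept[n]) for n in names])
    u_null = np.empty((B, len(names)))
    for j, n in enumerate(names):
        idx = kept[n]
        u_null[:, j] = np.abs(nul[:, idx].sum(axis=1)) / np.sqrt(len(idx))

    p = (1 + (u_null >= u_obs[None, :]).sum(axis=0)) / (B + 1)
    threshold = empirical_cutoff(u_null.max(axis=1), alpha)
    out = pd.DataFrame(
        {
            "size": [len(kept[n]) for n in names],
            "U": u_obs,
            "empirical_p": p,
            "study_wide_threshold": threshold,
            "study_wide_significant": u_obs > threshold,
        },
        index=pd.Index(names, name="set"),
    )
    return out.sort_values("empirical_p")


def select_deg_lists(
    zA: pd.Series,
    zB: pd.Series,
    threshold: Optional[float] = 2.2,
    fixed_n: Optional[int] = None,
) -> pd.DataFrame:
    """Genes differentially expressed in both disorders, split by direction.

    Threshold mode keeps genes with |zA| > t and |zB| > t; fixed-size mode
    keeps the top ``fixed_n`` genes by min(|zA|, |zB|), ties broken by gene
    id. The result partitions into up/up, down/down and discordant.
    """
    common = zA.index.intersection(zB.index)
    a, b = zA.loc[common], zB.loc[common]
    df = pd.DataFrame({"z_a": a, "z_b": b})
    if fixed_n is not None:
        if fixed_n > len(df):
            raise ValueError(f"fixed_n={fixed_n} exceeds universe of {len(df)}")
        score = np.minimum(df["z_a"].abs(), df["z_b"].abs())
        order = pd.DataFrame({"score": -score, "gene": df.index}).sort_values(
            ["score", "gene"]
        )
        df = df.loc[order.index[:fixed_n]]
    else:
        if threshold is None or threshold <= 0:
            raise ValueError("threshold must be positive when fixed_n is None")
        df = df[(df["z_a"].abs() > threshold) & (df["z_b"].abs() > threshold)]
    sa, sb = np.sign(df["z_a"]), np.sign(df["z_b"])
    df = df.copy()
    df["direction"] = np.where(
        sa != sb, "discordant", np.where(sa > 0, "up", "down")
    )
    df.index.name = "gene_id"
    return df


def hypergeometric_enrichment(
    gene_list: Sequence[str],
    universe: Sequence[str],
    sets: Dict[str, Sequence[str]],
    correction: str = "BH",
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene list.

    For each set, p = P(X >= observed overlap) with X hypergeometric on
    (|universe|, |set ∩ universe|, |list|). ``correction`` is "BH"
    (Benjamini-Hochberg step-up) or "bonferroni". Sets disjoint from the
    universe are skipped with a warning.
    """
    uni = pd.Index(universe)
    lst = pd.Index(gene_list)
    if not lst.isin(uni).all():
        raise ValueError("gene_list must be a subset of the universe")
    M, n = len(uni), len(lst)
    rows = []
    for name, members in sets.items():
        inset = pd.Index(members).intersection(uni)
        if len(inset) == 0:
            log.warning("set %s disjoint from universe; skipped", name)
            continue
        k = len(lst.intersection(inset))
        p = float(stats.hypergeom.sf(k - 1, M, len(inset), n))
        rows.append((name, len(inset), k, p))
    if not rows:
        raise ValueError("no set overlaps the universe")
    out = pd.DataFrame(
        rows, columns=["set", "set_in_universe", "overlap", "p"]
    ).set_index("set")
    out["list_size"] = n
    out["universe_size"] = M
    if correction.upper() == "BH":
        out["adjusted_p"] = multipletests(out["p"], method="fdr_bh")[1]
    elif correction.lower() == "bonferroni":
        out["adjusted_p"] = np.minimum(1.0, out["p"] * len(out))
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return out.sort_values("p")


def concordance_table(deg: pd.DataFrame) -> dict:
    """Counts of up/up, down/down and discordant DEGs with the discordant
    percentage (one decimal). ``deg`` is the output of
    :func:`select_deg_lists`; an empty list yields zeros."""
    total = len(deg)
    if total == 0:
        return {"total": 0, "up": 0, "down": 0, "discordant": 0, "discordant_pct": 0.0}
    counts = deg["direction"].value_counts()
    up = int(counts.get("up", 0))
    down = int(counts.get("down", 0))
    disc = int(counts.get("discordant", 0))
    return {
        "total": total,
        "up": up,
        "down": down,
        "discordant": disc,
        "discordant_pct": round(100.0 * disc / total, 1),
    }
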