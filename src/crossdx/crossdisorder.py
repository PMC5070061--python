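"""Cross-disorder Z products, empirical cutoffs and transcriptome correlation.

The joint statistic for a gene is the product of its per-disorder Z-scores;
family-wise significance comes from the per-permutation maximum |product|
over genes ("most extreme" read as maximum absolute value, with sign
concordance reported separately). Shared control arms are handled by
split-control resampling: controls are halved at random so the two case
groups never face the same controls, repeated n_splits times and summarized
by the per-gene median Z.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dgea import run_dgea
from .types import ModelSpec, NormalizedMatrix, NullEnsemble, SplitControlResult

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# split-control resampling


def split_control_zscores(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    spec: ModelSpec,
    n_splits: int = 100,
    seed: int = 0,
    case_labels: Sequence[str] = ("SCZ", "BPD"),
    control_label: str = "CTL",
) -> SplitControlResult:
    """Median per-gene Z over random halvings of a shared control arm.

    Each split partitions the controls into disjoint halves (sizes
    floor(n/2) and ceil(n/2), assignment uniform at random); the first case
    group is compared with the first half and the second case group with the
    second, via :func:`run_dgea` with the given model. Medians are taken
    across exactly ``n_splits`` runs per case group.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    controls = meta.index[meta["diagnosis"] == control_label]
    if len(controls) < 4:
        raise ValueError(f"need >= 4 controls for split-control, got {len(controls)}")
    if len(case_labels) != 2:
        raise ValueError("split_control_zscores compares exactly two case groups")
    rng = np.random.default_rng(seed)
    half = len(controls) // 2

    z_runs = {lab: [] for lab in case_labels}
    assign = np.zeros((n_splits, len(controls)), dtype=bool)
    for s in range(n_splits):
        order = rng.permutation(len(controls))
        first = np.zeros(len(controls), dtype=bool)
        first[order[:half]] = True
        assign[s] = first
        halves = (controls[first], controls[~first])
        for lab, ctl_ids in zip(case_labels, halves):
            ids = meta.index[meta["diagnosis"] == lab].union(ctl_ids, sort=False)
            sub_meta = meta.loc[ids]
            sub = NormalizedMatrix(norm.values[ids])
            table = run_dgea(sub, sub_meta, spec, lab, control_label)
            z_runs[lab].append(table["z"])

    z_frames = {
        lab: pd.DataFrame(runs, index=pd.RangeIndex(n_splits, name="split"))
        for lab, runs in z_runs.items()
    }
    return SplitControlResult(
        median_z={lab: fr.median(axis=0) for lab, fr in z_frames.items()},
        z_runs=z_frames,
        assignments=pd.DataFrame(
            assign, index=pd.RangeIndex(n_splits, name="split"), columns=controls
        ),
        n_splits=n_splits,
        seed=seed,
    )


def split_control_null_ensembles(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    spec: ModelSpec,
    B: int,
    n_splits: int = 100,
    seed: int = 0,
    case_labels: Sequence[str] = ("SCZ", "BPD"),
    control_label: str = "CTL",
) -> dict:
    """Null ensembles of split-control median Z: labels permuted, then the
    identical split-control procedure rerun, B times per case group."""
    labels = list(case_labels) + [control_label]
    sub = meta.loc[meta["diagnosis"].isin(labels)]
    out = {lab: [] for lab in case_labels}
    for b in range(B):
        rng = np.random.default_rng([int(seed), b])
        pmeta = sub.copy()
        pmeta["diagnosis"] = rng.permutation(pmeta["diagnosis"].to_numpy())
        res = split_control_zscores(
            norm,
            pmeta,
            spec,
            n_splits=n_splits,
            seed=int(rng.integers(2 ** 31)),
            case_labels=case_labels,
            control_label=control_label,
        )
        for lab in case_labels:
            out[lab].append(res.median_z[lab])
    return {
        lab: NullEnsemble(
            z=pd.DataFrame(rows, index=pd.RangeIndex(B, name="perm")),
            strata=(),
            unit="sample",
            seed=seed,
        )
        for lab, rows in out.items()
    }


# ---------------------------------------------------------------------------
# product statistics


def _align(*series: pd.Series) -> list:
    common = series[0].index
    for s in series[1:]:
        common = common.intersection(s.index)
    if len(common) == 0:
        raise ValueError("empty gene intersection across Z vectors")
    return [s.loc[common] for s in series]


def cross_disorder_product(
    zA: pd.Series, zB: pd.Series, zC: Optional[pd.Series] = None
) -> pd.DataFrame:
    """Per-gene product of two or three Z vectors on their common genes.

    The pairwise table keeps all genes and flags sign concordance; the
    three-way table is restricted to genes whose three Z-scores share one
    sign (the joint analysis is only defined for direction-consistent genes)
    and records how many genes remained.
    """
    if zC is None:
        a, b = _align(zA, zB)
        table = pd.DataFrame({"z_a": a, "z_b": b})
        table["z_cross"] = table["z_a"] * table["z_b"]
        table["concordant"] = np.sign(table["z_a"]) == np.sign(table["z_b"])
    else:
        a, b, c = _align(zA, zB, zC)
        table = pd.DataFrame({"z_a": a, "z_b": b, "z_c": c})
        signs = np.sign(table[["z_a", "z_b", "z_c"]].to_numpy())
        concordant = (signs == signs[:, [0]]).all(axis=1) & (signs[:, 0] != 0)
        table = table.loc[concordant]
        table["z_cross"] = table["z_a"] * table["z_b"] * table["z_c"]
        table["concordant"] = True
        table.attrs["n_concordant"] = int(concordant.sum())
        table.attrs["n_universe"] = len(concordant)
    table.index.name = "gene_id"
    return table


def null_max_products(
    ensA: NullEnsemble,
    ensB: NullEnsemble,
    ensC: Optional[NullEnsemble] = None,
) -> np.ndarray:
    """Per-permutation maximum |Z product| over genes.

    The b-th permutation of each ensemble is paired; for the three-way form
    each permutation's products are restricted to genes concordant in that
    permutation, mirroring the observed analysis.
    """
    ensembles = [e for e in (ensA, ensB, ensC) if e is not None]
    Bs = {e.B for e in ensembles}
    if len(Bs) != 1:
        raise ValueError(f"ensembles must have equal B, got {sorted(Bs)}")
    common = ensembles[0].gene_ids
    for e in ensembles[1:]:
        common = common.intersection(e.gene_ids)
    if len(common) == 0:
        raise ValueError("empty gene intersection across ensembles")
    mats = [e.z[common].to_numpy(dtype=float) for e in ensembles]
    prod = mats[0] * mats[1]
    if ensC is not None:
        signs = [np.sign(m) for m in mats]
        conc = (signs[0] == signs[1]) & (signs[0] == signs[2]) & (signs[0] != 0)
        prod = np.where(conc, prod * mats[2], np.nan)
    with np.errstate(invalid="ignore"):
        return np.nanmax(np.abs(prod), axis=1)


def empirical_cutoff(null_extremes: np.ndarray, alpha: float = 0.05) -> float:
    """The ceil((1-alpha)B)-th order statistic of B null extremes.

    The smallest null value such that at most alpha*B null values are
    strictly greater — the empirical family-wise cutoff at level alpha.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    x = np.sort(np.asarray(null_extremes, dtype=float))
    x = x[np.isfinite(x)]
    B = len(x)
    if B < 1:
        raise ValueError("no finite null extremes")
    idx = int(np.ceil((1 - alpha) * B)) - 1
    return float(x[idx])


def significant_cross_genes(
    table: pd.DataFrame, null_extremes: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Attach the empirical cutoff, significance calls and per-gene FWER p.

    A gene is significant iff |Z_cross| strictly exceeds the cutoff; its
    empirical p is (1 + #{permutations with max |product| >= observed}) /
    (B + 1), never smaller than 1/(B+1).
    """
    c = empirical_cutoff(null_extremes, alpha)
    ext = np.asarray(null_extremes, dtype=float)
    ext = ext[np.isfinite(ext)]
    B = len(ext)
    out = table.copy()
    absz = out["z_cross"].abs().to_numpy()
    out["cutoff"] = c
    out["significant"] = absz > c
    out["empirical_p"] = (1 + (ext[None, :] >= absz[:, None]).sum(axis=1)) / (B + 1)
    return out


# ---------------------------------------------------------------------------
# transcriptome correlation


def transcriptome_correlation_test(
    zA: pd.Series,
    zB: pd.Series,
    nullA: NullEnsemble,
    nullB: NullEnsemble,
) -> dict:
    """Pearson correlation of two Z vectors with permutation significance.

    The observed R is compared with the null distribution obtained by
    pairing the b-th permuted Z vectors of the two ensembles;
    p = (1 + #{|R_b| >= |R|}) / (B + 1).
    """
    if nullA.B != nullB.B:
        raise ValueError("null ensembles must have equal B")
    a, b = _align(zA, zB)
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("zero-variance Z vector")
    r_obs = float(stats.pearsonr(a, b)[0])

    common = nullA.gene_ids.intersection(nullB.gene_ids).intersection(a.index)
    ZA = nullA.z[common].to_numpy(dtype=float)
    ZB = nullB.z[common].to_numpy(dtype=float)
    ZA = ZA - ZA.mean(axis=1, keepdims=True)
    ZB = ZB - ZB.mean(axis=1, keepdims=True)
    num = (ZA * ZB).sum(axis=1)
    den = np.sqrt((ZA ** 2).sum(axis=1) * (ZB ** 2).sum(axis=1))
    r_null = num / den
    B = len(r_null)
    p = (1 + int((np.abs(r_null) >= abs(r_obs)).sum())) / (B + 1)
    return {"R": r_obs, "p": p, "null_R": r_null, "n_genes": len(a)}
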