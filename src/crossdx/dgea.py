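"""Per-gene case-control differential expression and permutation nulls.

Two model families mirror the two study designs: ordinary least squares for
the single-sample-per-subject design, and a subject random-intercept mixed
model (REML) for repeated measures across brain regions. Surrogate variables
estimated from expression residuals enter both as fixed covariates. The OLS
path is vectorized across genes (grouped by identical missingness patterns)
so thousand-permutation null ensembles are tractable.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import DgeaTable, ModelSpec, NormalizedMatrix, NullEnsemble

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# design construction


def build_design(
    meta: pd.DataFrame,
    covariates: Sequence[str],
    diagnosis: Optional[pd.Series] = None,
    svs: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Fixed-effects design matrix: intercept, covariates, SVs, diagnosis.

    Numeric covariates enter as-is; object/categorical covariates are
    dummy-coded dropping the first level. The diagnosis indicator (1 = case)
    is appended last under the name ``"diagnosis"``.
    """
    cols = {"Intercept": np.ones(len(meta))}
    for c in covariates:
        if c not in meta.columns:
            raise ValueError(f"covariate {c!r} not found in metadata")
        v = meta[c]
        if pd.api.types.is_numeric_dtype(v):
            cols[c] = v.to_numpy(dtype=float)
        else:
            d = pd.get_dummies(v.astype(str), prefix=c, drop_first=True)
            for name in d.columns:
                cols[name] = d[name].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=meta.index)
    if svs is not None and np.size(svs):
        svs = np.asarray(svs, dtype=float)
        for j in range(svs.shape[1]):
            X[f"SV{j + 1}"] = svs[:, j]
    if diagnosis is not None:
        X["diagnosis"] = diagnosis.to_numpy(dtype=float)
    return X


# ---------------------------------------------------------------------------
# surrogate variables


def estimate_surrogate_variables(
    norm: NormalizedMatrix | pd.DataFrame,
    known_design: pd.DataFrame | np.ndarray,
    n_sv: int,
) -> np.ndarray:
    """Estimate sample-space surrogate variables from expression residuals.

    Genes are regressed on the known design; the top ``n_sv`` right-singular
    vectors of the residual matrix are taken as candidate SVs. One
    reweighting pass then scales each gene by the proportion of its residual
    variance explained by the candidates before a final decomposition, so
    genes actually carrying the hidden structure dominate. Columns are
    orthonormal with the largest-magnitude loading of each SV made positive.
    Masked entries are imputed at the gene residual mean (zero) for the
    decomposition only.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    X = np.asarray(known_design, dtype=float)
    n_samples = values.shape[1]
    rank = np.linalg.matrix_rank(X)
    if n_sv >= n_samples - rank:
        raise ValueError(
            f"n_sv must be < n_samples - rank(design) = {n_samples - rank}"
        )
    if n_sv == 0:
        return np.empty((n_samples, 0))

    Y = values.to_numpy(dtype=float)
    nan = ~np.isfinite(Y)
    Y = np.where(nan, 0.0, Y)
    P = X @ np.linalg.pinv(X)
    R = Y - Y @ P.T  # residual over samples, per gene
    R[nan] = 0.0     # masked entries carry no residual information

    def _top_right_singular(M: np.ndarray, k: int) -> np.ndarray:
        _, _, Vt = np.linalg.svd(M, full_matrices=False)
        return Vt[:k].T

    V = _top_right_singular(R, n_sv)
    # reweight genes by residual variance explained by the candidate SVs
    proj = R @ V
    ss_tot = (R ** 2).sum(axis=1)
    ss_exp = (proj ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(ss_tot > 0, ss_exp / ss_tot, 0.0)
    V = _top_right_singular(R * w[:, None], n_sv)

    for j in range(V.shape[1]):
        if V[np.argmax(np.abs(V[:, j])), j] < 0:
            V[:, j] = -V[:, j]
    return V


def parallel_analysis_n_sv(
    norm: NormalizedMatrix | pd.DataFrame,
    known_design: pd.DataFrame | np.ndarray,
    n_perm: int = 20,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Choose n_sv as the number of residual singular values exceeding the
    ``quantile`` of singular values from row-permuted residual matrices."""
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    X = np.asarray(known_design, dtype=float)
    Y = values.to_numpy(dtype=float)
    Y = np.where(np.isfinite(Y), Y, 0.0)
    P = X @ np.linalg.pinv(X)
    R = Y - Y @ P.T
    obs = np.linalg.svd(R, compute_uv=False)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(obs)))
    for b in range(n_perm):
        Rp = np.array([rng.permutation(row) for row in R])
        Rp = Rp - Rp @ P.T
        null[b] = np.linalg.svd(Rp, compute_uv=False)
    thresh = np.quantile(null, quantile, axis=0)
    max_sv = values.shape[1] - np.linalg.matrix_rank(X) - 1
    return int(min((obs > thresh).sum(), max(max_sv, 0)))


# ---------------------------------------------------------------------------
# fixed-effects (OLS) fits, vectorized across genes


def _ols_block(Y: np.ndarray, X: np.ndarray, cidx: int):
    """OLS of each row of Y on X; returns effect, se, z, p, flag for column
    ``cidx``. Y is genes x n (complete), X is n x p."""
    n, p = X.shape
    out_flag = np.full(Y.shape[0], "", dtype=object)
    if n <= p or np.linalg.matrix_rank(X) < p:
        out = np.full((Y.shape[0], 4), np.nan)
        out_flag[:] = "rank_deficient"
        return out[:, 0], out[:, 1], out[:, 2], out[:, 3], out_flag
    XtXi = np.linalg.inv(X.T @ X)
    beta = Y @ X @ XtXi          # genes x p
    resid = Y - beta @ X.T
    df = n - p
    sigma2 = (resid ** 2).sum(axis=1) / df
    var = sigma2 * XtXi[cidx, cidx]
    se = np.sqrt(np.maximum(var, 0.0))
    effect = beta[:, cidx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    # an (essentially) exact fit leaves no residual scale for inference
    scale = (Y ** 2).mean(axis=1)
    bad = ~np.isfinite(t) | (sigma2 <= 1e-12 * np.maximum(scale, 1e-300))
    out_flag[bad] = "zero_residual"
    return effect, se, t, pval, out_flag


def fit_gene_fixed(y: pd.Series | np.ndarray, design: pd.DataFrame) -> dict:
    """OLS fit of one gene; the diagnosis column must be last in ``design``.

    Returns effect, se, z (= effect/se, t statistic), two-sided t-based p,
    n_used and a flag ("" when clean).
    """
    yv = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    ok = np.isfinite(yv)
    yv, X = yv[ok], X[ok]
    e, s, z, p, f = _ols_block(yv[None, :], X, X.shape[1] - 1)
    return {
        "effect": float(e[0]),
        "se": float(s[0]),
        "z": float(z[0]),
        "p": float(p[0]),
        "n_used": int(ok.sum()),
        "flag": str(f[0]),
    }


def fit_gene_mixed(
    y: pd.Series | np.ndarray,
    design: pd.DataFrame,
    subject_id: pd.Series | np.ndarray,
) -> dict:
    """Random-intercept (REML) fit of one gene with subject grouping.

    Z is the diagnosis fixed effect over its standard error; p is two-sided
    normal on Z. On non-convergence or singular covariance, falls back to
    OLS on subject-averaged expression (flag ``"mixed_fallback"``).
    """
    import statsmodels.api as sm

    yv = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    groups = np.asarray(subject_id)
    ok = np.isfinite(yv)
    yv, X, groups = yv[ok], X[ok], groups[ok]
    cidx = X.shape[1] - 1
    # one sample per subject: the random intercept is not identified and the
    # model collapses to OLS exactly
    if len(np.unique(groups)) == len(groups):
        res = fit_gene_fixed(yv, pd.DataFrame(X))
        res["p"] = float(2.0 * stats.norm.sf(abs(res["z"]))) if res["flag"] == "" else res["p"]
        return res
    try:
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM(yv, X, groups=groups)
                res = model.fit(reml=True, method="lbfgs", maxiter=200)
                effect = float(res.fe_params[cidx])
                se = float(res.bse_fe[cidx])
        if not (np.isfinite(effect) and np.isfinite(se) and se > 0):
            raise ValueError("non-finite mixed estimates")
        z = effect / se
        return {
            "effect": effect,
            "se": se,
            "z": z,
            "p": float(2.0 * stats.norm.sf(abs(z))),
            "n_used": int(ok.sum()),
            "flag": "",
        }
    except Exception:
        # subject-averaged OLS fallback
        df = pd.DataFrame(X, columns=[f"c{i}" for i in range(X.shape[1])])
        df["_y"] = yv
        df["_g"] = groups
        agg = df.groupby("_g").mean()
        e, s, z, p, f = _ols_block(
            agg["_y"].to_numpy()[None, :],
            agg[[f"c{i}" for i in range(X.shape[1])]].to_numpy(),
            cidx,
        )
        return {
            "effect": float(e[0]),
            "se": float(s[0]),
            "z": float(z[0]),
            "p": float(p[0]),
            "n_used": int(ok.sum()),
            "flag": "mixed_fallback" if f[0] == "" else str(f[0]),
        }


# ---------------------------------------------------------------------------
# whole-table fits


def _diagnosis_indicator(meta: pd.DataFrame, case: str, control: str) -> pd.Series:
    dx = meta["diagnosis"]
    missing = [lab for lab in (case, control) if lab not in set(dx)]
    if missing:
        raise ValueError(f"labels not present in metadata: {missing}")
    return (dx == case).astype(float)


def run_dgea(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    spec: ModelSpec,
    case_label: str,
    control_label: str,
    svs: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-gene differential expression for one case-control contrast.

    Samples are restricted to the two labels; surrogate variables are
    estimated once on that subset (unless supplied, e.g. held fixed across
    permutations) and entered as fixed covariates. The mixed model is used
    when ``spec.random_intercept`` is set, OLS otherwise.
    """
    keep = meta["diagnosis"].isin([case_label, control_label])
    meta = meta.loc[keep]
    values = norm.values[meta.index]
    dxi = _diagnosis_indicator(meta, case_label, control_label)

    known = build_design(meta, spec.covariates)
    if svs is None:
        sv_design = build_design(meta, spec.covariates, diagnosis=dxi)
        svs = estimate_surrogate_variables(
            NormalizedMatrix(values), sv_design, spec.n_sv
        )
    design = build_design(meta, spec.covariates, diagnosis=dxi, svs=svs)

    if spec.random_intercept is not None:
        groups = meta[spec.random_intercept]
        rows = {
            g: fit_gene_mixed(values.loc[g], design, groups) for g in values.index
        }
        table = pd.DataFrame.from_dict(rows, orient="index")
    else:
        table = _run_fixed_table(values, design)
    table.index.name = "gene_id"
    return DgeaTable(table)


def _run_fixed_table(values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Vectorized OLS over genes with per-gene missingness.

    Per-gene normal equations are assembled with the gene's availability
    mask and solved as a batch (SVD-based pseudo-inverse with a rank check),
    so thousands of genes with arbitrary masking cost one LAPACK call.
    """
    Y = np.asarray(values.to_numpy(), dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    cidx = p - 1
    finite = np.isfinite(Y)
    if finite.all():
        e, s, z, p_, f = _ols_block(Y, X, cidx)
        return pd.DataFrame(
            {"effect": e, "se": s, "z": z, "p": p_, "n_used": n, "flag": f},
            index=values.index,
        )
    M = finite.astype(float)
    Y0 = np.where(M > 0, Y, 0.0)
    n_used = M.sum(axis=1)

    XtX = np.einsum("gn,ni,nj->gij", M, X, X, optimize=True)
    Xty = np.einsum("gn,ni->gi", M * Y0, X, optimize=True)
    # rank check via determinant against the Hadamard bound, then batched
    # inverse (singular matrices swapped for identity and flagged)
    diag = np.einsum("gii->gi", XtX)
    det = np.linalg.det(XtX)
    bound = np.maximum(np.prod(diag, axis=1), np.finfo(float).tiny)
    rank_def = ~(det > 1e-10 * bound) | (n_used <= p)
    XtX_safe = XtX.copy()
    XtX_safe[rank_def] = np.eye(p)
    XtXi = np.linalg.inv(XtX_safe)
    beta = (XtXi @ Xty[..., None])[..., 0]
    resid = M * (Y0 - beta @ X.T)
    df = n_used - p
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = (resid ** 2).sum(axis=1) / df
        var = sigma2 * XtXi[:, cidx, cidx]
        se = np.sqrt(np.maximum(var, 0.0))
        effect = beta[:, cidx]
        t = effect / se
        pval = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))

    flag = np.full(Y.shape[0], "", dtype=object)
    flag[~np.isfinite(t)] = "zero_residual"
    flag[rank_def] = "rank_deficient"
    bad = flag != ""
    effect[bad] = np.nan
    se[bad] = np.nan
    t[bad] = np.nan
    pval[bad] = np.nan
    return pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "z": t,
            "p": pval,
            "n_used": n_used.astype(int),
            "flag": flag,
        },
        index=values.index,
    )


# ---------------------------------------------------------------------------
# permutation nulls


def permute_case_labels(
    meta: pd.DataFrame,
    strata: Sequence[str],
    unit: str,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Shuffle diagnosis labels within strata, at sample or subject level.

    ``unit="subject"`` permutes one label per subject and propagates it to
    all of that subject's samples, preserving the subject-level group sizes
    within each stratum exactly; ``unit="sample"`` shuffles sample labels
    directly. A stratum with a single unit keeps its labels (warning).
    """
    if unit not in ("subject", "sample"):
        raise ValueError("unit must be 'subject' or 'sample'")
    for c in strata:
        if c not in meta.columns:
            raise ValueError(f"stratum column {c!r} not in metadata")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    meta = meta.copy()

    if unit == "subject":
        subj = meta.drop_duplicates("subject_id").set_index("subject_id")
        key = (
            subj[list(strata)].astype(str).agg("|".join, axis=1)
            if strata
            else pd.Series("", index=subj.index)
        )
        new = subj["diagnosis"].copy()
        for _, ids in key.groupby(key).groups.items():
            if len(ids) < 2:
                log.warning("stratum with a single subject; labels fixed there")
                continue
            labels = subj.loc[ids, "diagnosis"].to_numpy()
            new.loc[ids] = rng.permutation(labels)
        meta["diagnosis"] = meta["subject_id"].map(new).to_numpy()
    else:
        key = (
            meta[list(strata)].astype(str).agg("|".join, axis=1)
            if strata
            else pd.Series("", index=meta.index)
        )
        for _, ids in key.groupby(key).groups.items():
            if len(ids) < 2:
                log.warning("stratum with a single sample; labels fixed there")
                continue
            meta.loc[ids, "diagnosis"] = rng.permutation(
                meta.loc[ids, "diagnosis"].to_numpy()
            )
    return meta


def run_null_ensemble(
    norm: NormalizedMatrix,
    meta: pd.DataFrame,
    spec: ModelSpec,
    case_label: str,
    control_label: str,
    B: int,
    strata: Sequence[str] = (),
    unit: str = "sample",
    seed: int = 0,
    svs: Optional[np.ndarray] = None,
) -> NullEnsemble:
    """B label-permutation reruns of :func:`run_dgea` with the same model.

    Surrogate variables are estimated once on the observed labeling and held
    fixed across permutations (label exchangeability is preserved given the
    design). Per-permutation seeds derive reproducibly from ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    keep = meta["diagnosis"].isin([case_label, control_label])
    sub_meta = meta.loc[keep]
    values = norm.values[sub_meta.index]
    dxi = _diagnosis_indicator(sub_meta, case_label, control_label)
    if svs is None:
        sv_design = build_design(sub_meta, spec.covariates, diagnosis=dxi)
        svs = estimate_surrogate_variables(
            NormalizedMatrix(values), sv_design, spec.n_sv
        )
    rows = []
    if spec.random_intercept is not None:
        for b in range(B):
            rng = np.random.default_rng([int(seed), b])
            pmeta = permute_case_labels(sub_meta, strata, unit, rng)
            table = run_dgea(
                NormalizedMatrix(values), pmeta, spec, case_label, control_label,
                svs=svs,
            )
            rows.append(table["z"])
    else:
        # fixed model: the design is constant across permutations except for
        # the diagnosis column, so permute labels and refit in place
        design = build_design(sub_meta, spec.covariates, diagnosis=dxi, svs=svs)
        X = np.asarray(design, dtype=float).copy()
        if unit == "subject":
            subj, inverse = np.unique(sub_meta["subject_id"], return_inverse=True)
            first = np.array(
                [np.flatnonzero(inverse == i)[0] for i in range(len(subj))]
            )
            base = sub_meta["diagnosis"].to_numpy()[first]
            key = (
                sub_meta[list(strata)].astype(str).agg("|".join, axis=1).to_numpy()[first]
                if strata
                else np.zeros(len(subj))
            )
        else:
            inverse = None
            base = sub_meta["diagnosis"].to_numpy()
            key = (
                sub_meta[list(strata)].astype(str).agg("|".join, axis=1).to_numpy()
                if strata
                else np.zeros(len(base))
            )
        groups = [np.flatnonzero(key == k) for k in np.unique(key)]
        singles = [g for g in groups if len(g) < 2]
        if singles:
            log.warning("%d strata with a single unit; labels fixed there", len(singles))
        for b in range(B):
            rng = np.random.default_rng([int(seed), b])
            lab = base.copy()
            for g in groups:
                if len(g) >= 2:
                    lab[g] = lab[g[rng.permutation(len(g))]]
            sample_lab = lab[inverse] if inverse is not None else lab
            X[:, -1] = (sample_lab == case_label).astype(float)
            table = _run_fixed_table(values, X)
            rows.append(table["z"])
    z = pd.DataFrame(rows, index=pd.RangeIndex(B, name="perm"))
    return NullEnsemble(z=z, strata=tuple(strata), unit=unit, seed=seed)
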