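"""Synthetic count studies, gene sets and GWAS gene-based p-values.

The generator reproduces the statistical structure the downstream analysis
assumes: negative-binomial counts whose log2 means carry GC/length bias,
known-covariate effects, hidden batch factors, per-disorder true effects with
configurable cross-disorder correlation, and (for the repeated-measures
design) a per-subject random intercept shared across that subject's brain
regions. Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .types import DISORDERS, CountStudy, EffectProfile

# child-rng tags so the two study designs share gene-level structure
_TAG_EFFECTS = 1
_TAG_GENES = 2
_TAG_REPEATED = 3
_TAG_SHARED = 4
_TAG_SETS = 5
_TAG_GWAS = 6


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag)])


def _gene_ids(n: int) -> pd.Index:
    width = max(5, len(str(n)))
    return pd.Index([f"G{i:0{width}d}" for i in range(n)], name="gene_id")


def _check_rho(rho: np.ndarray) -> np.ndarray:
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (3, 3):
        raise ValueError("rho must be a 3x3 matrix")
    if not np.allclose(rho, rho.T):
        raise ValueError("rho must be symmetric")
    if not np.allclose(np.diag(rho), 1.0):
        raise ValueError("rho must have unit diagonal")
    if np.abs(rho).max() > 1 + 1e-12:
        raise ValueError("rho entries must lie in [-1, 1]")
    w = np.linalg.eigvalsh(rho)
    if w.min() < -1e-10:
        raise ValueError(
            f"rho is not positive semidefinite (min eigenvalue {w.min():.3g})"
        )
    return rho


def generate_true_effects(config: SimulationConfig) -> EffectProfile:
    """Draw correlated per-disorder log2 effects with exact non-null counts.

    A common candidate pool of ``round(pool_frac * n_genes)`` genes receives
    trivariate-normal effects with correlation ``config.rho`` and marginal
    s.d. ``config.effect_sd``; each disorder then keeps exactly
    ``round(prop_nonnull * n_genes)`` pool genes non-null (chosen
    independently per disorder) and zeroes the rest, yielding overlapping
    shared and disorder-specific effect sets.
    """
    rho = _check_rho(config.rho)
    rng = _rng(config.seed, _TAG_EFFECTS)
    n = config.n_genes
    genes = _gene_ids(n)

    k = [int(round(p * n)) for p in config.prop_nonnull]
    pool_size = min(n, max(max(k, default=0), int(round(config.pool_frac * n))))
    beta = np.zeros((n, 3))
    is_null = np.ones((n, 3), dtype=bool)
    if pool_size > 0 and max(k) > 0:
        pool = rng.choice(n, size=pool_size, replace=False)
        cov = (config.effect_sd ** 2) * rho
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(3))
        raw = rng.standard_normal((pool_size, 3)) @ L.T
        for d in range(3):
            keep = rng.choice(pool_size, size=k[d], replace=False)
            idx = pool[keep]
            beta[idx, d] = raw[keep, d]
            is_null[idx, d] = False
            # a drawn beta of exactly 0 would violate the is_null contract
            zero = idx[beta[idx, d] == 0.0]
            if zero.size:
                beta[zero, d] = config.effect_sd * 1e-6
    return EffectProfile(
        beta=pd.DataFrame(beta, index=genes, columns=list(DISORDERS)),
        is_null=pd.DataFrame(is_null, index=genes, columns=list(DISORDERS)),
        rho=rho,
    )


def _gene_attributes(config: SimulationConfig):
    """GC, length and baseline log2 means — shared across both designs."""
    rng = _rng(config.seed, _TAG_GENES)
    n = config.n_genes
    gc = rng.uniform(0.3, 0.7, size=n)
    length = np.exp(rng.uniform(np.log(200.0), np.log(20000.0), size=n))
    lo, hi = config.baseline_log_mean
    baseline = rng.uniform(lo, hi, size=n)
    return gc, length, baseline


def _hidden_factor_matrix(
    rng: np.random.Generator, n_genes: int, n_samples: int, config: SimulationConfig
):
    """Hidden-factor contribution to the log2 mean (genes x samples) plus the
    per-sample factor scores (samples x n_factors, for validation)."""
    out = np.zeros((n_genes, n_samples))
    scores_all = np.zeros((n_samples, config.n_hidden_factors))
    n_load = int(round(config.hidden_gene_frac * n_genes))
    for f in range(config.n_hidden_factors):
        loadings = np.zeros(n_genes)
        which = rng.choice(n_genes, size=n_load, replace=False)
        loadings[which] = rng.normal(0.0, 1.0, size=n_load)
        scores = rng.normal(0.0, config.hidden_factor_sd, size=n_samples)
        scores_all[:, f] = scores
        out += np.outer(loadings, scores)
    return out, scores_all


def _nb_counts(
    rng: np.random.Generator, log2_mean: np.ndarray, dispersion: float
) -> np.ndarray:
    mean = np.exp2(log2_mean)
    size = 1.0 / dispersion  # gamma shape; var = m + dispersion * m^2
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def _covariate_effects(
    rng: np.random.Generator, n_genes: int, age: np.ndarray, sex01: np.ndarray
) -> np.ndarray:
    """Small age/sex effects on a subset of genes (log2 scale)."""
    age_slope = np.zeros(n_genes)
    sex_shift = np.zeros(n_genes)
    n_affect = max(1, n_genes // 10)
    age_slope[rng.choice(n_genes, n_affect, replace=False)] = rng.normal(
        0.0, 0.005, n_affect
    )
    sex_shift[rng.choice(n_genes, n_affect, replace=False)] = rng.normal(
        0.0, 0.3, n_affect
    )
    age_c = age - age.mean()
    return np.outer(age_slope, age_c) + np.outer(sex_shift, sex01)


def generate_count_study(
    effects: EffectProfile,
    config: SimulationConfig,
    design_kind: str,
    sample_seed: Optional[int] = None,
) -> CountStudy:
    """Simulate one count study under the requested design.

    ``repeated_multisite``: control and case subjects spread over sites,
    each contributing one sample per sampled brain region, with a per-subject
    gene-level random intercept; diagnosis effects use the AUT beta column.
    ``shared_control``: one sample per subject in a single region/site, with
    SCZ and BPD case arms sharing the control arm; diagnosis effects use the
    SCZ and BPD beta columns.

    Gene-level attributes (GC, length, baseline) derive from ``config.seed``
    so studies over the same gene universe stay consistent; ``sample_seed``
    (default ``config.seed``) drives everything sample-level, letting
    independent cohorts share one annotation. The returned study carries the
    true per-sample hidden-factor scores as ``hidden_factors`` for
    validation of surrogate-variable recovery.
    """
    if design_kind not in ("repeated_multisite", "shared_control"):
        raise ValueError(f"unknown design_kind {design_kind!r}")
    if len(effects.gene_ids) != config.n_genes:
        raise ValueError(
            f"effects cover {len(effects.gene_ids)} genes but config.n_genes="
            f"{config.n_genes}"
        )
    gc, length, baseline = _gene_attributes(config)
    n = config.n_genes
    genes = effects.gene_ids
    sseed = config.seed if sample_seed is None else sample_seed

    if design_kind == "repeated_multisite":
        rng = _rng(sseed, _TAG_REPEATED)
        n_ctl, n_case = config.n_control_subjects, config.n_case_subjects
        n_subj = n_ctl + n_case
        subj_dx = np.array(["CTL"] * n_ctl + ["AUT"] * n_case)
        subj_site = rng.integers(0, config.n_sites, size=n_subj)
        subj_age = np.clip(rng.normal(22.0, 9.0, size=n_subj), 2, 65)
        subj_sex = rng.integers(0, 2, size=n_subj)
        rows = []
        for s in range(n_subj):
            present = rng.random(config.n_regions) < config.region_prob
            if not present.any():
                present[rng.integers(0, config.n_regions)] = True
            for r in np.flatnonzero(present):
                rows.append((s, r))
        meta = pd.DataFrame(
            {
                "subject_id": [f"SUBJ{s:03d}" for s, _ in rows],
                "diagnosis": [subj_dx[s] for s, _ in rows],
                "site": [f"site{subj_site[s]}" for s, _ in rows],
                "brain_region": [f"region{r}" for _, r in rows],
                "age": [subj_age[s] for s, _ in rows],
                "sex": ["F" if subj_sex[s] else "M" for s, _ in rows],
            },
            index=pd.Index([f"S{i:04d}" for i in range(len(rows))], name="sample_id"),
        )
        n_samples = len(meta)
        is_case = (meta["diagnosis"] == "AUT").to_numpy()
        dx_effect = np.outer(effects.beta["AUT"].to_numpy(), is_case.astype(float))
        subj_int = rng.normal(0.0, config.subject_sd, size=(n, n_subj))
        subj_idx = np.array([s for s, _ in rows])
        site_shift = rng.normal(0.0, config.site_sd, size=(n, config.n_sites))
        hidden, hidden_scores = _hidden_factor_matrix(rng, n, n_samples, config)
        mu = (
            baseline[:, None]
            + config.gc_bias * (gc - gc.mean())[:, None]
            + config.length_bias * (np.log2(length) - np.log2(length).mean())[:, None]
            + dx_effect
            + subj_int[:, subj_idx]
            + site_shift[:, subj_site[subj_idx]]
            + _covariate_effects(
                rng, n, meta["age"].to_numpy(), (meta["sex"] == "F").to_numpy(float)
            )
            + hidden
            + rng.normal(0.0, config.depth_sd, size=n_samples)[None, :]
        )
    else:
        rng = _rng(sseed, _TAG_SHARED)
        n_samples = config.n_scz + config.n_bpd + config.n_shared_controls
        dx = np.array(
            ["SCZ"] * config.n_scz
            + ["BPD"] * config.n_bpd
            + ["CTL"] * config.n_shared_controls
        )
        age = np.clip(rng.normal(44.0, 9.0, size=n_samples), 18, 80)
        sex = rng.integers(0, 2, size=n_samples)
        is_case = dx != "CTL"
        meta = pd.DataFrame(
            {
                "subject_id": [f"SUBJ{i:03d}" for i in range(n_samples)],
                "diagnosis": dx,
                "site": "site0",
                "brain_region": "region0",
                "age": age,
                "sex": np.where(sex == 1, "F", "M"),
                "ph": np.clip(rng.normal(6.5, 0.25, size=n_samples), 5.8, 7.2),
                "pmi": np.clip(rng.normal(30.0, 10.0, size=n_samples), 5, 80),
                "antipsychotics": np.where(
                    is_case, np.round(rng.lognormal(8.0, 1.5, size=n_samples)), 0.0
                ),
            },
            index=pd.Index([f"S{i:04d}" for i in range(n_samples)], name="sample_id"),
        )
        dx_effect = np.zeros((n, n_samples))
        for d in ("SCZ", "BPD"):
            dx_effect[:, dx == d] = effects.beta[d].to_numpy()[:, None]
        hidden, hidden_scores = _hidden_factor_matrix(rng, n, n_samples, config)
        mu = (
            baseline[:, None]
            + config.gc_bias * (gc - gc.mean())[:, None]
            + config.length_bias * (np.log2(length) - np.log2(length).mean())[:, None]
            + dx_effect
            + _covariate_effects(
                rng, n, meta["age"].to_numpy(), (meta["sex"] == "F").to_numpy(float)
            )
            + hidden
            + rng.normal(0.0, config.depth_sd, size=n_samples)[None, :]
        )

    counts = _nb_counts(rng, mu, config.nb_dispersion)
    study = CountStudy(
        counts=pd.DataFrame(counts, index=genes, columns=meta.index),
        gene_length=pd.Series(np.round(length).astype(int), index=genes, name="length"),
        gene_gc=pd.Series(gc, index=genes, name="gc"),
        sample_meta=meta,
        design_kind=design_kind,
    )
    study.hidden_factors = pd.DataFrame(
        hidden_scores,
        index=meta.index,
        columns=[f"factor{f}" for f in range(config.n_hidden_factors)],
    )
    return study


def generate_gene_sets(
    gene_ids: Sequence[str],
    n_sets: int,
    size_range: Tuple[int, int],
    n_enriched: int = 0,
    effect_gene_pool: Optional[Sequence[str]] = None,
    seed: int = 0,
    enriched_frac: float = 0.75,
) -> dict:
    """Sample gene sets, optionally biasing some toward an effect-gene pool.

    Returns an ordered mapping set name -> member gene list (writable as GMT
    via :func:`crossdx.io.write_gmt`). The first ``n_enriched`` sets draw
    ``enriched_frac`` of their members from ``effect_gene_pool``.
    """
    genes = pd.Index(gene_ids)
    lo, hi = size_range
    if lo < 2 or hi > len(genes) or lo > hi:
        raise ValueError(
            f"size_range {size_range} infeasible for a universe of {len(genes)} genes"
        )
    if n_enriched > 0 and (effect_gene_pool is None or len(effect_gene_pool) == 0):
        raise ValueError("n_enriched > 0 requires a non-empty effect_gene_pool")
    rng = np.random.default_rng([int(seed), _TAG_SETS])
    pool = pd.Index(effect_gene_pool) if effect_gene_pool is not None else pd.Index([])
    rest = genes.difference(pool)
    width = max(4, len(str(n_sets)))
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET{i:0{width}d}"
        if i < n_enriched:
            n_pool = min(int(round(enriched_frac * size)), len(pool))
            members = list(rng.choice(pool, size=n_pool, replace=False))
            fill = rng.choice(rest, size=size - n_pool, replace=False)
            members.extend(fill)
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        sets[name] = sorted(members)
    return sets


def generate_gwas_gene_p(
    gene_ids: Sequence[str],
    frac_signal: float,
    signal_gene_pool: Optional[Sequence[str]] = None,
    seed: int = 0,
    beta_a: float = 0.1,
    beta_b: float = 1.0,
) -> pd.DataFrame:
    """Gene-based GWAS p-values: uniform nulls, Beta-distributed signals.

    ``frac_signal`` of genes (preferentially from ``signal_gene_pool``) get
    p ~ Beta(beta_a, beta_b) — concentrated near 0 for beta_a < 1 — and the
    rest get p ~ Uniform(0, 1).
    """
    if not (0.0 <= frac_signal <= 1.0):
        raise ValueError("frac_signal must lie in [0, 1]")
    genes = pd.Index(gene_ids)
    rng = np.random.default_rng([int(seed), _TAG_GWAS])
    p = rng.uniform(size=len(genes))
    n_signal = int(round(frac_signal * len(genes)))
    if n_signal > 0:
        if signal_gene_pool is not None and len(signal_gene_pool) > 0:
            pool = genes.get_indexer(pd.Index(signal_gene_pool).intersection(genes))
            if n_signal <= len(pool):
                idx = rng.choice(pool, size=n_signal, replace=False)
            else:
                extra = rng.choice(
                    np.setdiff1d(np.arange(len(genes)), pool),
                    size=n_signal - len(pool),
                    replace=False,
                )
                idx = np.concatenate([pool, extra])
        else:
            idx = rng.choice(len(genes), size=n_signal, replace=False)
        p[idx] = rng.beta(beta_a, beta_b, size=len(idx))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"gene_id": genes, "p": p}).set_index("gene_id")
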