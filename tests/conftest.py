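import logging

import numpy as np
import pytest

import crossdx as cx
from crossdx.types import ModelSpec, NormalizedMatrix

logging.getLogger("crossdx").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cfg():
    return cx.SimulationConfig(
        n_genes=300,
        n_control_subjects=12,
        n_case_subjects=12,
        n_scz=12,
        n_bpd=10,
        n_shared_controls=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def effects(small_cfg):
    return cx.generate_true_effects(small_cfg)


@pytest.fixture(scope="session")
def shared_study(effects, small_cfg):
    return cx.generate_count_study(effects, small_cfg, "shared_control")


@pytest.fixture(scope="session")
def repeated_study(effects, small_cfg):
    return cx.generate_count_study(effects, small_cfg, "repeated_multisite")


@pytest.fixture(scope="session")
def shared_norm(shared_study):
    filtered = cx.filter_low_expression(shared_study)
    return cx.mask_outliers(cx.normalize_gc_length(filtered))


def null_study_z(
    seed,
    n_genes=2000,
    n_per_arm=30,
    B=200,
    n_sv=0,
    prop_nonnull=(0.0, 0.0, 0.0),
    rho=None,
    sample_seed=None,
    case_label="SCZ",
    mask=True,
    pool_frac=0.2,
):
    """One synthetic case-control study run through preprocessing, the fixed
    model and a label-permutation null ensemble; shared helper for the
    calibration and power checks."""
    kwargs = dict(
        n_genes=n_genes,
        n_scz=n_per_arm,
        n_bpd=max(2, n_per_arm if case_label == "BPD" else 2),
        n_shared_controls=n_per_arm,
        prop_nonnull=prop_nonnull,
        pool_frac=pool_frac,
        n_hidden_factors=0,
        seed=seed,
    )
    if rho is not None:
        kwargs["rho"] = rho
    cfg = cx.SimulationConfig(**kwargs)
    eff = cx.generate_true_effects(cfg)
    study = cx.generate_count_study(
        eff, cfg, "shared_control", sample_seed=sample_seed
    )
    filtered = cx.filter_low_expression(study)
    norm = cx.normalize_gc_length(filtered)
    if mask:
        norm = cx.mask_outliers(norm)
    spec = ModelSpec(covariates=["age", "sex"], n_sv=n_sv)
    table = cx.run_dgea(norm, study.sample_meta, spec, case_label, "CTL")
    z = table.loc[table["flag"] == "", "z"]
    ens = cx.run_null_ensemble(
        norm, study.sample_meta, spec, case_label, "CTL", B=B, seed=seed + 1_000_000
    )
    return z, ens, eff, study
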