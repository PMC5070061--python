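import itertools

import numpy as np
import pandas as pd
import pytest

import crossdx as cx
from crossdx.dgea import (
    build_design,
    estimate_surrogate_variables,
    fit_gene_fixed,
    fit_gene_mixed,
    permute_case_labels,
)
from crossdx.types import ModelSpec, NormalizedMatrix


def _design_from_dx(dx):
    n = len(dx)
    return pd.DataFrame({"Intercept": np.ones(n), "diagnosis": dx})


class TestFixedFit:
    def test_two_group_mean_difference(self):
        y = np.array([1.0, 2, 3, 6, 7, 9])
        res = fit_gene_fixed(y, _design_from_dx([0, 0, 0, 1, 1, 1]))
        assert res["effect"] == pytest.approx(16 / 3, abs=1e-12)
        assert res["flag"] == ""
        assert np.sign(res["z"]) == np.sign(res["effect"])

    def test_degenerate_zero_residual_flagged(self):
        dx = np.array([0.0, 0, 0, 1, 1, 1])
        res = fit_gene_fixed(dx, _design_from_dx(dx))
        assert res["flag"] == "zero_residual"

    def test_orthogonal_covariate_leaves_effect(self):
        rng = np.random.default_rng(0)
        dx = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        y = rng.standard_normal(8)
        base = fit_gene_fixed(y, _design_from_dx(dx))
        # construct a covariate orthogonal to intercept, diagnosis and y
        raw = rng.standard_normal(8)
        Q, _ = np.linalg.qr(np.column_stack([np.ones(8), dx, y, raw]))
        orth = Q[:, 3]
        design = pd.DataFrame(
            {"Intercept": np.ones(8), "extra": orth, "diagnosis": dx}
        )
        aug = fit_gene_fixed(y, design)
        # the coefficient is untouched; Z shifts only through the residual
        # degrees of freedom lost to the extra column
        assert aug["effect"] == pytest.approx(base["effect"], abs=1e-8)
        assert aug["z"] * np.sqrt(8 - 2) / np.sqrt(8 - 3) == pytest.approx(
            base["z"], abs=1e-8
        )

    def test_label_swap_negates_z(self, shared_norm, shared_study):
        spec = ModelSpec(covariates=["age", "sex"], n_sv=0)
        fwd = cx.run_dgea(shared_norm, shared_study.sample_meta, spec, "SCZ", "CTL")
        rev = cx.run_dgea(shared_norm, shared_study.sample_meta, spec, "CTL", "SCZ")
        ok = (fwd["flag"] == "") & (rev["flag"] == "")
        assert np.allclose(fwd.loc[ok, "z"], -rev.loc[ok, "z"], atol=1e-10)


class TestMixedFit:
    def test_collapses_to_ols_with_singleton_subjects(self):
        rng = np.random.default_rng(4)
        dx = np.array([0.0] * 6 + [1.0] * 6)
        y = 0.8 * dx + rng.standard_normal(12)
        design = _design_from_dx(dx)
        subjects = np.array([f"s{i}" for i in range(12)])
        ols = fit_gene_fixed(y, design)
        mix = fit_gene_mixed(y, design, subjects)
        assert mix["effect"] == pytest.approx(ols["effect"], abs=1e-6)
        assert mix["se"] == pytest.approx(ols["se"], abs=1e-5)

    def test_recovers_planted_effect_with_repeated_measures(self):
        rng = np.random.default_rng(7)
        n_subj, n_rep = 40, 2
        dx_subj = np.repeat([0.0, 1.0], n_subj // 2)
        subjects = np.repeat([f"s{i}" for i in range(n_subj)], n_rep)
        dx = np.repeat(dx_subj, n_rep)
        design = _design_from_dx(dx)
        estimates = []
        for _ in range(200):
            intercepts = np.repeat(rng.normal(0, 1.0, n_subj), n_rep)
            y = 1.0 * dx + intercepts + rng.normal(0, 0.5, n_subj * n_rep)
            estimates.append(fit_gene_mixed(y, design, subjects)["effect"])
        assert abs(np.mean(estimates) - 1.0) < 0.1

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(9)
        dx = np.repeat([0.0, 1.0], 10)
        subjects = np.repeat([f"s{i}" for i in range(10)], 2)
        y = dx + np.repeat(rng.normal(0, 1, 10), 2) + rng.normal(0, 0.3, 20)
        design = _design_from_dx(dx)
        base = fit_gene_mixed(y, design, subjects)
        order = rng.permutation(20)
        perm = fit_gene_mixed(y[order], design.iloc[order], subjects[order])
        assert perm["effect"] == pytest.approx(base["effect"], abs=1e-6)
        assert perm["z"] == pytest.approx(base["z"], abs=1e-5)


class TestSurrogateVariables:
    def test_recovers_planted_hidden_factor(self):
        cfg = cx.SimulationConfig(
            n_genes=1000, n_hidden_factors=1, hidden_factor_sd=1.0, seed=7
        )
        eff = cx.generate_true_effects(cfg)
        study = cx.generate_count_study(eff, cfg, "shared_control")
        norm = cx.mask_outliers(
            cx.normalize_gc_length(cx.filter_low_expression(study))
        )
        meta = study.sample_meta
        dxi = (meta["diagnosis"] != "CTL").astype(float)
        design = build_design(meta, ["age", "sex"], diagnosis=dxi)
        sv = estimate_surrogate_variables(norm, design, 1)
        r = np.corrcoef(sv[:, 0], study.hidden_factors["factor0"])[0, 1]
        assert abs(r) > 0.9

    def test_zero_sv_gives_empty_matrix(self, shared_norm, shared_study):
        meta = shared_study.sample_meta
        design = build_design(meta, ["age", "sex"])
        sv = estimate_surrogate_variables(shared_norm, design, 0)
        assert sv.shape == (len(meta), 0)

    def test_too_many_sv_rejected(self, shared_norm, shared_study):
        design = build_design(shared_study.sample_meta, ["age", "sex"])
        with pytest.raises(ValueError, match="n_sv"):
            estimate_surrogate_variables(
                shared_norm, design, shared_study.n_samples
            )

    def test_gene_duplication_invariance(self, shared_norm, shared_study):
        meta = shared_study.sample_meta
        design = build_design(meta, ["age", "sex"])
        sv1 = estimate_surrogate_variables(shared_norm, design, 2)
        stacked = pd.concat(
            [
                shared_norm.values,
                shared_norm.values.set_index(shared_norm.values.index + "_dup"),
            ]
        )
        sv2 = estimate_surrogate_variables(NormalizedMatrix(stacked), design, 2)
        for j in range(2):
            assert abs(np.corrcoef(sv1[:, j], sv2[:, j])[0, 1]) > 1 - 1e-8

    def test_orthonormal_columns(self, shared_norm, shared_study):
        design = build_design(shared_study.sample_meta, ["age", "sex"])
        sv = estimate_surrogate_variables(shared_norm, design, 3)
        assert np.allclose(sv.T @ sv, np.eye(3), atol=1e-8)


class TestPermutation:
    @staticmethod
    def _meta(labels, sites=None, subjects=None):
        n = len(labels)
        return pd.DataFrame(
            {
                "diagnosis": labels,
                "subject_id": subjects if subjects is not None else [f"u{i}" for i in range(n)],
                "site": sites if sites is not None else ["a"] * n,
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_counts_preserved_within_stratum(self):
        meta = self._meta(
            ["SCZ", "SCZ", "CTL", "CTL", "SCZ", "CTL"],
            sites=["a", "a", "a", "a", "b", "b"],
        )
        perm = permute_case_labels(meta, ("site",), "sample", 3)
        for site in ("a", "b"):
            orig = meta[meta["site"] == site]["diagnosis"].value_counts()
            new = perm[perm["site"] == site]["diagnosis"].value_counts()
            assert orig.to_dict() == new.to_dict()

    def test_subject_level_labels_concordant(self, repeated_study):
        meta = repeated_study.sample_meta
        perm = permute_case_labels(meta, ("site",), "subject", 11)
        per_subject = perm.groupby("subject_id")["diagnosis"].nunique()
        assert (per_subject == 1).all()
        # subject-level counts preserved within site
        subj = meta.drop_duplicates("subject_id")
        psubj = perm.drop_duplicates("subject_id")
        for site in subj["site"].unique():
            a = subj[subj["site"] == site]["diagnosis"].value_counts().to_dict()
            b = psubj[psubj["site"] == site]["diagnosis"].value_counts().to_dict()
            assert a == b

    def test_four_unit_stratum_assignments_uniform(self):
        meta = self._meta(["SCZ", "SCZ", "CTL", "CTL"])
        rng = np.random.default_rng(123)
        counts = {c: 0 for c in itertools.combinations(range(4), 2)}
        n_draws = 10000
        for _ in range(n_draws):
            perm = permute_case_labels(meta, (), "sample", rng)
            cases = tuple(np.flatnonzero((perm["diagnosis"] == "SCZ").to_numpy()))
            counts[cases] += 1
        for c, k in counts.items():
            assert abs(k / n_draws - 1 / 6) < 0.02

    def test_unknown_unit_rejected(self):
        with pytest.raises(ValueError):
            permute_case_labels(self._meta(["SCZ", "CTL"]), (), "region", 0)


class TestNullEnsemble:
    def test_deterministic_rerun(self, shared_norm, shared_study):
        spec = ModelSpec(covariates=["age", "sex"], n_sv=0)
        a = cx.run_null_ensemble(
            shared_norm, shared_study.sample_meta, spec, "SCZ", "CTL", B=2, seed=5
        )
        b = cx.run_null_ensemble(
            shared_norm, shared_study.sample_meta, spec, "SCZ", "CTL", B=2, seed=5
        )
        pd.testing.assert_frame_equal(a.z, b.z)

    def test_null_z_approximately_standard_normal(self):
        from conftest import null_study_z

        z, ens, _, _ = null_study_z(seed=41, n_genes=1500, B=50)
        pooled = ens.z.to_numpy().ravel()
        pooled = pooled[np.isfinite(pooled)]
        assert abs(pooled.mean()) < 0.05
        assert abs(pooled.std() - 1.0) < 0.1

    def test_type_one_error_calibrated(self):
        cfg = cx.SimulationConfig(
            n_genes=5000, n_scz=30, n_bpd=2, n_shared_controls=30,
            prop_nonnull=(0, 0, 0), n_hidden_factors=0, seed=42,
        )
        eff = cx.generate_true_effects(cfg)
        study = cx.generate_count_study(eff, cfg, "shared_control")
        norm = cx.mask_outliers(
            cx.normalize_gc_length(cx.filter_low_expression(study))
        )
        spec = ModelSpec(covariates=["age", "sex"], n_sv=0)
        table = cx.run_dgea(norm, study.sample_meta, spec, "SCZ", "CTL")
        p = table.loc[table["flag"] == "", "p"]
        frac = float((p < 0.05).mean())
        assert 0.04 <= frac <= 0.06


def test_run_dgea_planted_effects_rank_above_null(shared_norm, shared_study, effects):
    spec = ModelSpec(covariates=["age", "sex"], n_sv=0)
    table = cx.run_dgea(shared_norm, shared_study.sample_meta, spec, "SCZ", "CTL")
    ok = table["flag"] == ""
    nonnull = (~effects.is_null["SCZ"]).reindex(table.index[ok]).fillna(False)
    planted = table.loc[ok].loc[nonnull.to_numpy(), "z"].abs()
    null_genes = table.loc[ok].loc[~nonnull.to_numpy(), "z"].abs()
    assert planted.median() > null_genes.median()
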