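"""End-to-end orchestration: preprocess -> DGEA (+nulls) -> cross-disorder ->
enrichment -> GWAS overlap, with all results written as stamped TSV/JSON."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import crossdisorder as cd
from . import dgea, enrichment, gwas, io, preprocess, simulate
from .config import PipelineConfig, SimulationConfig
from .types import ModelSpec, NormalizedMatrix

log = logging.getLogger(__name__)

COMPARISONS = ("AUT_SCZ", "AUT_BPD", "SCZ_BPD", "AUT_SCZ_BPD")


def _cap_n_sv(n_sv: int, norm: NormalizedMatrix, design) -> int:
    n_samples = norm.values.shape[1]
    rank = np.linalg.matrix_rank(np.asarray(design, dtype=float))
    return int(max(0, min(n_sv, n_samples - rank - 1)))


def _load_or_simulate(config: PipelineConfig):
    file_keys = ("counts_aut", "meta_aut", "annot_aut", "counts_smri", "meta_smri",
                 "annot_smri")
    if all(getattr(config, k) for k in file_keys):
        aut = io.read_count_study(config.counts_aut, config.meta_aut, config.annot_aut)
        smri = io.read_count_study(
            config.counts_smri, config.meta_smri, config.annot_smri
        )
        effects = None
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        effects = simulate.generate_true_effects(sim)
        aut = simulate.generate_count_study(effects, sim, "repeated_multisite")
        smri = simulate.generate_count_study(effects, sim, "shared_control")
    return aut, smri, effects


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full cross-disorder analysis; returns the summary dict.

    Stages: expression filtering and GC/length normalization with per-gene
    outlier masking for each study; per-study differential expression with
    surrogate variables (mixed model for the repeated-measures study, OLS
    for the shared-control study, plus split-control resampling);
    label-permutation null ensembles; pairwise and three-way Z products with
    empirical cutoffs; permutation-calibrated transcriptome correlations;
    Stouffer-based set enrichment; and GWAS QQ overlap. Any stage failure
    aborts with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed, chash = config.seed, config.hash()
    summary: dict = {"seed": seed, "config_hash": chash, "comparisons": {}}

    def stamp(frame, name):
        io.write_result_table(frame, outdir / name, seed, chash)

    stage = "load"
    try:
        aut_raw, smri_raw, effects = _load_or_simulate(config)

        stage = "preprocess"
        studies = {}
        for name, study in (("aut", aut_raw), ("smri", smri_raw)):
            filtered = preprocess.filter_low_expression(
                study, config.min_reads, config.min_frac
            )
            norm = preprocess.normalize_gc_length(filtered)
            norm = preprocess.mask_outliers(norm, config.outlier_k)
            studies[name] = (filtered, norm)
        universe = studies["aut"][1].values.index.intersection(
            studies["smri"][1].values.index
        )
        if len(universe) == 0:
            raise ValueError("empty cross-study gene universe after filtering")
        aut_norm = NormalizedMatrix(studies["aut"][1].values.loc[universe])
        smri_norm = NormalizedMatrix(studies["smri"][1].values.loc[universe])
        aut_meta = aut_raw.sample_meta
        smri_meta = smri_raw.sample_meta
        summary["n_genes_universe"] = int(len(universe))

        stage = "dgea"
        aut_spec = ModelSpec(
            covariates=list(config.covariates_aut),
            n_sv=config.n_sv_aut,
            random_intercept="subject_id",
        )
        smri_spec = ModelSpec(
            covariates=list(config.covariates_smri), n_sv=config.n_sv_smri
        )
        # cap SV counts for small (synthetic) sample sizes
        aut_spec.n_sv = _cap_n_sv(
            aut_spec.n_sv, aut_norm, dgea.build_design(aut_meta, aut_spec.covariates)
        )
        smri_spec.n_sv = _cap_n_sv(
            smri_spec.n_sv, smri_norm,
            dgea.build_design(smri_meta, smri_spec.covariates),
        )

        z_aut = dgea.run_dgea(aut_norm, aut_meta, aut_spec, "AUT", "CTL")
        z_scz_full = dgea.run_dgea(smri_norm, smri_meta, smri_spec, "SCZ", "CTL")
        z_bpd_full = dgea.run_dgea(smri_norm, smri_meta, smri_spec, "BPD", "CTL")
        split = cd.split_control_zscores(
            smri_norm, smri_meta, smri_spec, n_splits=config.n_splits, seed=seed
        )
        stamp(z_aut, "dgea_aut.tsv")
        stamp(z_scz_full, "dgea_scz_full.tsv")
        stamp(z_bpd_full, "dgea_bpd_full.tsv")
        split_frame = pd.DataFrame(
            {
                "z_scz_split": split.median_z["SCZ"],
                "z_bpd_split": split.median_z["BPD"],
            }
        )
        stamp(split_frame, "dgea_split_control.tsv")

        stage = "null_ensembles"
        ens_aut = dgea.run_null_ensemble(
            aut_norm, aut_meta, aut_spec, "AUT", "CTL", B=config.n_perm,
            strata=("site",), unit="subject", seed=seed + 1,
        )
        ens_scz = dgea.run_null_ensemble(
            smri_norm, smri_meta, smri_spec, "SCZ", "CTL", B=config.n_perm,
            strata=(), unit="sample", seed=seed + 2,
        )
        ens_bpd = dgea.run_null_ensemble(
            smri_norm, smri_meta, smri_spec, "BPD", "CTL", B=config.n_perm,
            strata=(), unit="sample", seed=seed + 3,
        )
        split_nulls = cd.split_control_null_ensembles(
            smri_norm, smri_meta, smri_spec, B=config.n_perm,
            n_splits=config.n_splits, seed=seed + 4,
        )

        stage = "crossdisorder"
        zs = {
            "AUT": z_aut.loc[z_aut["flag"] == "", "z"],
            "SCZ": z_scz_full.loc[z_scz_full["flag"] == "", "z"],
            "BPD": z_bpd_full.loc[z_bpd_full["flag"] == "", "z"],
            "SCZ_split": split.median_z["SCZ"],
            "BPD_split": split.median_z["BPD"],
        }
        plans = {
            "AUT_SCZ": (("AUT", "SCZ"), (ens_aut, ens_scz)),
            "AUT_BPD": (("AUT", "BPD"), (ens_aut, ens_bpd)),
            "SCZ_BPD": (
                ("SCZ_split", "BPD_split"),
                (split_nulls["SCZ"], split_nulls["BPD"]),
            ),
            "AUT_SCZ_BPD": (
                ("AUT", "SCZ_split", "BPD_split"),
                (ens_aut, split_nulls["SCZ"], split_nulls["BPD"]),
            ),
        }
        cross_tables, null_extremes, ensembles = {}, {}, {}
        for comp, (keys, ens) in plans.items():
            table = cd.cross_disorder_product(*[zs[k] for k in keys])
            extremes = cd.null_max_products(*ens)
            table = cd.significant_cross_genes(table, extremes, config.alpha)
            cross_tables[comp] = table
            null_extremes[comp] = extremes
            ensembles[comp] = ens
            stamp(table, f"cross_{comp}.tsv")
            summary["comparisons"][comp] = {
                "cutoff": float(table["cutoff"].iloc[0]),
                "n_significant": int(table["significant"].sum()),
                "significant_genes": table.index[table["significant"]].tolist(),
            }
            if comp == "AUT_SCZ_BPD":
                summary["comparisons"][comp]["n_concordant"] = table.attrs.get(
                    "n_concordant", len(table)
                )

        stage = "correlation"
        for comp in ("AUT_SCZ", "AUT_BPD", "SCZ_BPD"):
            keys, ens = plans[comp]
            res = cd.transcriptome_correlation_test(
                zs[keys[0]], zs[keys[1]], ens[0], ens[1]
            )
            summary["comparisons"][comp]["R"] = res["R"]
            summary["comparisons"][comp]["R_p"] = res["p"]

        stage = "enrichment"
        if config.gene_sets:
            sets = io.read_gmt(config.gene_sets)
        else:
            rng_pool = zs["AUT"].abs().nlargest(max(50, len(universe) // 10)).index
            sets = simulate.generate_gene_sets(
                list(universe), n_sets=50, size_range=(10, 50),
                n_enriched=5, effect_gene_pool=list(rng_pool), seed=seed + 5,
            )
        for comp in ("AUT_SCZ", "AUT_BPD", "SCZ_BPD"):
            keys, ens = plans[comp]
            combined = enrichment.stouffer_combine([zs[k] for k in keys])
            common = ens[0].gene_ids.intersection(ens[1].gene_ids).intersection(
                combined.index
            )
            null_comb = (ens[0].z[common] + ens[1].z[common]) / np.sqrt(2)
            try:
                set_table = enrichment.set_enrichment_empirical(
                    combined.loc[common], sets, null_comb, config.alpha
                )
                stamp(set_table, f"enrichment_{comp}.tsv")
                summary["comparisons"][comp]["n_sets_significant"] = int(
                    set_table["study_wide_significant"].sum()
                )
            except ValueError as err:
                log.warning("set enrichment skipped for %s: %s", comp, err)
            deg = enrichment.select_deg_lists(
                zs[keys[0]], zs[keys[1]], threshold=config.deg_threshold
            )
            stamp(deg, f"deg_{comp}.tsv")
            summary["comparisons"][comp]["concordance"] = enrichment.concordance_table(
                deg
            )
            if len(deg) >= 1:
                hyper = enrichment.hypergeometric_enrichment(
                    deg.index, combined.index, sets, correction="BH"
                )
                stamp(hyper, f"hypergeometric_{comp}.tsv")

        stage = "gwas_overlap"
        gwas_tables = {}
        if config.gwas_tables:
            for dis, path in config.gwas_tables.items():
                gwas_tables[dis] = io.read_gwas_table(path)
        else:
            for i, dis in enumerate(("AUT", "SCZ", "BPD")):
                gwas_tables[dis] = simulate.generate_gwas_gene_p(
                    list(universe), frac_signal=0.05, seed=seed + 10 + i
                )
        n_null = min(config.n_gwas_perm, config.n_perm)
        for comp in ("AUT_SCZ", "AUT_BPD", "SCZ_BPD"):
            keys, ens = plans[comp]
            common = ens[0].gene_ids.intersection(ens[1].gene_ids)
            prod_null = pd.DataFrame(
                ens[0].z[common].to_numpy() * ens[1].z[common].to_numpy(),
                index=ens[0].z.index, columns=common,
            )
            dgea_p = gwas.pointwise_empirical_p(
                cross_tables[comp]["z_cross"], prod_null
            )
            null_p = gwas.null_pointwise_p(prod_null).iloc[:n_null]
            gw = {}
            for dis, table in gwas_tables.items():
                sweep = gwas.cutoff_sweep(dgea_p, table, null_p)
                stamp(sweep, f"gwas_{comp}_{dis}.tsv")
                gw[dis] = {
                    str(c): bool(v) for c, v in sweep["enriched"].items()
                }
            summary["comparisons"][comp]["gwas_enriched"] = gw

        stage = "summary"
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        with open(outdir / "run_log.txt", "w") as fh:
            fh.write(f"seed={seed}\nconfig_hash={chash}\n")
            fh.write(f"n_genes_universe={summary['n_genes_universe']}\n")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return summary
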