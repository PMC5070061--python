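"""Readers and writers for the pipeline's delimited-text formats.

Counts, metadata, annotations and result tables are plain TSV; gene sets use
the standard GMT dialect (set name, description, tab-separated member ids).
Result writers stamp a comment header with the seed and configuration hash
so reruns are verifiably identical.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .types import CountStudy

log = logging.getLogger(__name__)


def write_count_study(study: CountStudy, outdir: str | Path, prefix: str = "study") -> dict:
    """Write counts, metadata and gene annotation as TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}_counts.tsv",
        "meta": outdir / f"{prefix}_meta.tsv",
        "annot": outdir / f"{prefix}_annot.tsv",
    }
    study.counts.to_csv(paths["counts"], sep="\t")
    study.sample_meta.to_csv(paths["meta"], sep="\t")
    pd.DataFrame(
        {"length": study.gene_length, "gc": study.gene_gc}
    ).rename_axis("gene_id").to_csv(paths["annot"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def infer_design_kind(meta: pd.DataFrame) -> str:
    """Infer the study design from metadata.

    More than two diagnosis levels with unique subject ids implies a
    shared-control design; duplicated subject ids imply repeated measures.
    """
    n_dx = meta["diagnosis"].nunique()
    unique_subjects = not meta["subject_id"].duplicated().any()
    if n_dx > 2 and unique_subjects:
        return "shared_control"
    return "repeated_multisite" if not unique_subjects else (
        "shared_control" if n_dx > 2 else "repeated_multisite"
    )


def read_count_study(
    counts_path: str | Path,
    meta_path: str | Path,
    annot_path: str | Path,
    design_kind: Optional[str] = None,
) -> CountStudy:
    """Read and validate a count study from three TSV files.

    Sample ids in the counts header must match the metadata rows (order is
    harmonized to the counts file); duplicate gene ids and non-integer
    counts are rejected with explicit messages.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    annot = pd.read_csv(annot_path, sep="\t", index_col=0)

    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in counts: {dup[:10]}")
    missing_meta = counts.columns.difference(meta.index).tolist()
    if missing_meta:
        raise ValueError(f"samples in counts but absent from metadata: {missing_meta}")
    extra_meta = meta.index.difference(counts.columns).tolist()
    if extra_meta:
        raise ValueError(f"samples in metadata but absent from counts: {extra_meta}")
    sample_index_name = meta.index.name
    meta = meta.loc[counts.columns]
    meta.index.name = sample_index_name
    for col in ("diagnosis", "subject_id"):
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    for col in ("length", "gc"):
        if col not in annot.columns:
            raise ValueError(f"annotation missing required column {col!r}")
    missing_annot = counts.index.difference(annot.index).tolist()
    if missing_annot:
        raise ValueError(f"genes without annotation: {missing_annot[:10]}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values), atol=0):
            bad_genes = counts.index[
                (values != np.round(values)).any(axis=1)
            ].tolist()
            raise ValueError(f"non-integer counts at genes: {bad_genes[:10]}")
        counts = counts.round().astype("int64")
    counts.columns.name = meta.index.name

    if design_kind is None:
        design_kind = infer_design_kind(meta)
    return CountStudy(
        counts=counts,
        gene_length=annot.loc[counts.index, "length"],
        gene_gc=annot.loc[counts.index, "gc"],
        sample_meta=meta,
        design_kind=design_kind,
    )


def read_gmt(path: str | Path) -> Dict[str, list]:
    """Read a GMT gene-set file: name, description, then member gene ids.

    Set names must be unique; empty sets are dropped with a warning;
    malformed lines (fewer than three tab-separated fields) raise with the
    line number.
    """
    sets: Dict[str, list] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            if not genes:
                log.warning("%s: line %d: empty set %r dropped", path, lineno, name)
                continue
            sets[name] = genes
    return sets


def write_gmt(sets: Dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_gwas_table(path: str | Path) -> pd.DataFrame:
    """Two-column TSV (gene_id, p) -> DataFrame indexed by gene_id."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "p" not in df.columns:
        raise ValueError(f"{path}: expected columns gene_id and p")
    bad = df[(df["p"] <= 0) | (df["p"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: p-values outside (0, 1]: {bad['gene_id'].tolist()[:10]}")
    return df.set_index("gene_id")


def write_result_table(
    frame: pd.DataFrame, path: str | Path, seed: int, config_hash: str
) -> None:
    """Write a result TSV with a provenance comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t")
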