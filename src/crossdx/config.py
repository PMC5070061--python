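"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

import numpy as np

#: default correlation of non-null log2 effects between disorders
#: (order AUT, SCZ, BPD) — the observed transcriptome-level correlations
#: reported for cortical case-control studies of these disorders.
DEFAULT_RHO = np.array(
    [
        [1.0, 0.298, 0.06],
        [0.298, 1.0, 0.11],
        [0.06, 0.11, 1.0],
    ]
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic count-study generator.

    Arm sizes default to the designs the analysis targets: a repeated-measures
    multi-site cortical study (40 control and 32 case subjects, up to 3 brain
    regions each) and a single-region shared-control study (31 SCZ, 25 BPD and
    26 control subjects). Effects are log2 fold-changes; counts are
    negative-binomial (gamma-Poisson) with one dispersion.
    """

    n_genes: int = 2000
    # repeated_multisite design (autism-style)
    n_control_subjects: int = 40
    n_case_subjects: int = 32
    n_sites: int = 2
    n_regions: int = 3
    region_prob: float = 0.5      # each region sampled per subject w.p. this, min 1
    subject_sd: float = 0.5       # log2 s.d. of the per-subject random intercept
    site_sd: float = 0.25         # log2 s.d. of per-site gene-level shifts
    # shared_control design (SCZ/BPD-style)
    n_scz: int = 31
    n_bpd: int = 25
    n_shared_controls: int = 26
    # true effects
    prop_nonnull: Tuple[float, float, float] = (0.1, 0.1, 0.1)  # AUT, SCZ, BPD
    pool_frac: float = 0.2        # candidate-pool fraction of the gene universe
    effect_sd: float = 0.5        # log2 s.d. of non-null effects
    rho: np.ndarray = field(default_factory=lambda: DEFAULT_RHO.copy())
    # unwanted variation
    n_hidden_factors: int = 2
    hidden_factor_sd: float = 1.0
    hidden_gene_frac: float = 0.3  # fraction of genes each factor loads on
    # count model
    nb_dispersion: float = 0.1
    baseline_log_mean: Tuple[float, float] = (2.0, 9.0)  # log2 mean-count range
    gc_bias: float = 2.0           # log2 slope on centered GC fraction
    length_bias: float = 0.5       # log2 slope on centered log2 length
    depth_sd: float = 0.2          # log2 s.d. of per-sample depth offsets
    seed: int = 0

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        for name in (
            "n_genes",
            "n_control_subjects",
            "n_case_subjects",
            "n_sites",
            "n_regions",
            "n_scz",
            "n_bpd",
            "n_shared_controls",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if any(not (0.0 <= p <= 1.0) for p in self.prop_nonnull):
            raise ValueError("prop_nonnull entries must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_hidden_factors < 0:
            raise ValueError("n_hidden_factors must be >= 0")
        if not (0 < self.region_prob <= 1):
            raise ValueError("region_prob must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """Full-pipeline settings with the analysis's canonical defaults.

    Defaults: expression filter keeps genes with >=10 reads in >=75% of
    samples; per-gene outliers beyond 2.7 s.d. are masked; DEG lists use
    |Z| > 2.2; significance uses 1000 label permutations; shared controls are
    re-halved 100 times; GWAS QQ overlap uses 100 null ensembles at alpha
    0.05.
    """

    # file inputs (optional — the pipeline can run on synthetic data)
    counts_aut: Optional[str] = None
    meta_aut: Optional[str] = None
    annot_aut: Optional[str] = None
    counts_smri: Optional[str] = None
    meta_smri: Optional[str] = None
    annot_smri: Optional[str] = None
    gene_sets: Optional[str] = None
    gwas_tables: dict = field(default_factory=dict)  # disorder -> path
    # model formulas (covariate lists per study)
    covariates_aut: Sequence[str] = ("age", "sex", "site", "brain_region")
    covariates_smri: Sequence[str] = ("age", "sex", "antipsychotics", "ph", "pmi")
    n_sv_aut: int = 12
    n_sv_smri: int = 4
    # filtering / masking / thresholds
    min_reads: int = 10
    min_frac: float = 0.75
    outlier_k: float = 2.7
    deg_threshold: float = 2.2
    # resampling
    n_perm: int = 1000
    n_splits: int = 100
    n_gwas_perm: int = 100
    alpha: float = 0.05
    seed: int = 0
    # synthetic fallback
    simulation: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not (0 < self.min_frac <= 1):
            raise ValueError("min_frac must lie in (0, 1]")
        for name in ("min_reads",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("outlier_k", "deg_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    def hash(self) -> str:
        """Short stable hash of the configuration, stamped on outputs."""
        d = asdict(self)
        if d.get("simulation") is not None:
            d["simulation"]["rho"] = np.asarray(d["simulation"]["rho"]).tolist()
        payload = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
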