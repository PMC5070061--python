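"""Worked-example inputs: published per-disorder Z-scores.

Per-gene Z-scores (effect size / standard error) reported for the genes
called differentially expressed across disorders in post-mortem cortical
case-control studies of autism (AUT), schizophrenia (SCZ) and bipolar
disorder (BPD). The pairwise comparisons carry the full-control SCZ/BPD
Z-scores; the three-way comparison carries split-control median Z-scores for
SCZ and BPD, because those two case groups share a control arm. Values are
printed at two decimals, so products recomputed from them agree with the
reported cross-disorder Z only to within that rounding.

These are worked-example inputs for :func:`crossdx.cross_disorder_product`;
they are not produced by this package's models.
"""

from __future__ import annotations

import pandas as pd

# gene -> (Z_AUT, Z_SCZ_full, Z_BPD_full, reported Z_AUT*Z_SCZ)
AUT_SCZ = {
    "ZKSCAN1": (4.08, 3.74, 0.68, 15.24),
    "MAL": (5.24, 2.80, 1.20, 14.66),
    "IQSEC3": (-4.04, -3.59, -3.46, 14.53),
    "GPM6B": (3.62, 3.91, 0.26, 14.16),
    "GPRC5B": (3.72, 3.72, 0.78, 13.85),
    "EGLN3": (4.76, 2.86, 0.13, 13.62),
    "RNF123": (-3.46, -3.71, -0.99, 12.81),
    "DAGLA": (-4.22, -2.98, -0.57, 12.54),
    "TANGO2": (-3.83, -3.27, 0.25, 12.53),
}

# gene -> (Z_AUT, Z_SCZ_full, Z_BPD_full, reported Z_AUT*Z_BPD)
AUT_BPD = {
    "IQSEC3": (-4.04, -3.59, -3.46, 14.00),
}

# gene -> (Z_AUT, Z_SCZ_split, Z_BPD_split, reported Z_AUT*Z_SCZ*Z_BPD)
THREE_WAY = {
    "IQSEC3": (-4.04, -2.95, -2.97, -35.45),
    "COPS7A": (-3.31, -3.14, -2.17, -22.52),
}

#: reported family-wise empirical cutoffs (functions of the original data;
#: kept for context only, never reproduced by the synthetic pipeline)
REPORTED_CUTOFFS = {
    "AUT_SCZ": 12.42,
    "AUT_BPD": 12.29,
    "SCZ_BPD": 21.71,
    "AUT_SCZ_BPD": 19.56,
}

#: reported DEG concordance for the |Z| > 2.2 lists: (total, discordant)
REPORTED_DISCORDANCE = {
    "AUT_SCZ": (191, 16),
    "AUT_BPD": (191, 76),
    "SCZ_BPD": (191, 38),
}


def zscore_frame(comparison: str) -> pd.DataFrame:
    """Return the worked-example Z table for one comparison.

    ``comparison`` is "AUT_SCZ", "AUT_BPD" or "AUT_SCZ_BPD"; columns are
    z_aut, z_scz, z_bpd and reported_z_cross, indexed by gene name.
    """
    source = {"AUT_SCZ": AUT_SCZ, "AUT_BPD": AUT_BPD, "AUT_SCZ_BPD": THREE_WAY}
    if comparison not in source:
        raise ValueError(f"unknown comparison {comparison!r}")
    rows = source[comparison]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["z_aut", "z_scz", "z_bpd", "reported_z_cross"]
    )
    df.index.name = "gene"
    return df
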