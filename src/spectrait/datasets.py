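"""Small built-in reference tables used in worked examples and checks."""

from __future__ import annotations

import pandas as pd

_CLUSTER_MEANS_ROWS = [
    # treatment, cluster, n_genotypes, DW kg/m2, DW sd, WC %, WC sd, GY t/ha, GY sd
    ("FL", 1, 4, 2.71, 0.11, 79.0, 1.96, 8.39, 0.65),
    ("FL", 2, 22, 2.10, 0.09, 74.4, 2.22, 6.46, 0.34),
    ("FL", 3, 6, 1.59, 0.11, 70.7, 2.84, 5.30, 0.42),
    ("LM", 1, 9, 1.58, 0.07, 68.9, 2.43, 4.62, 0.12),
    ("LM", 2, 17, 1.31, 0.10, 64.2, 1.64, 3.52, 0.41),
    ("LM", 3, 6, 0.95, 0.11, 58.8, 1.97, 2.50, 0.51),
    ("FL+LM", 1, 8, 2.10, 0.13, 73.5, 1.76, 6.23, 0.42),
    ("FL+LM", 2, 16, 1.69, 0.14, 69.2, 1.62, 5.06, 0.43),
    ("FL+LM", 3, 8, 1.39, 0.10, 65.9, 1.82, 4.03, 0.37),
]


def wheat_ril_cluster_means() -> pd.DataFrame:
    """Published cluster-level trait means from a two-year wheat RIL
    irrigation trial (30 recombinant inbred lines plus two parents grown
    under full and limited irrigation).

    Genotypes were grouped into three clusters per irrigation scope by UPGMA
    on shoot dry weight (DW, kg m-2), biomass water content (WC, %), and
    grain yield (GY, t ha-1); the table holds each cluster's size and trait
    mean +/- sd.  Used as the worked example for the cluster-contrast
    arithmetic (``cluster.relative_decrease``).
    """
    return pd.DataFrame(
        _CLUSTER_MEANS_ROWS,
        columns=[
            "treatment", "cluster", "n",
            "DW_mean", "DW_sd", "WC_mean", "WC_sd", "GY_mean", "GY_sd",
        ],
    )
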