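"""Sub-stoichiometry of ribosomal proteins across translational states.

Re-analysis layout for polysome-profile proteomics: per-protein abundances
(SILAC ratio over an internal standard) measured in the 40S, 60S, 80S and
polysome fractions are normalized over the median abundance of the
protein's own subunit within each fraction, then clustered to reveal
proteins that are under-represented in free subunits but fully present in
translating ribosomes (or vice versa).

Small-subunit proteins receive no value in the 60S fraction and large-
subunit proteins none in the 40S fraction — those cells are structurally
absent, not missing data.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .kinetics import ClusterResult, cluster_profiles

__all__ = ["FRACTIONS", "normalize_occupancy", "cluster_occupancy"]

logger = logging.getLogger(__name__)

FRACTIONS = ("40S", "60S", "80S", "polysome")

#: (subunit, fraction) cells that are structurally absent
_EXCLUDED = {("40S", "60S"), ("60S", "40S")}


def normalize_occupancy(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize abundances over the subunit median within each fraction.

    ``records`` columns: ``protein, subunit, fraction, abundance`` (one row
    per protein x fraction, abundance > 0).  Returns a wide matrix indexed
    by protein with one column per fraction; excluded (subunit, fraction)
    cells and absent fractions are NaN.  Requires at least two proteins per
    (subunit, fraction) cell used.
    """
    required = {"protein", "subunit", "fraction", "abundance"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (records["abundance"] <= 0).any():
        raise ValueError("abundances must be positive")
    work = records.copy()
    excl = [
        (sub, frac) in _EXCLUDED
        for sub, frac in zip(work["subunit"], work["fraction"])
    ]
    n_excl = int(np.sum(excl))
    if n_excl:
        logger.info("dropping %d cross-subunit cells (40S protein in 60S "
                    "fraction or vice versa)", n_excl)
    work = work.loc[~np.asarray(excl)]

    counts = work.groupby(["subunit", "fraction"])["abundance"].count()
    thin = counts[counts < 2]
    if not thin.empty:
        raise ValueError(
            f"fewer than 2 proteins in cells: {list(thin.index)}")
    medians = work.groupby(["subunit", "fraction"])["abundance"].transform(
        "median")
    work["normalized"] = work["abundance"] / medians
    wide = work.pivot_table(index="protein", columns="fraction",
                            values="normalized", aggfunc="mean")
    order = [f for f in FRACTIONS if f in wide.columns]
    extra = [c for c in wide.columns if c not in order]
    return wide[order + extra]


def cluster_occupancy(matrix: pd.DataFrame, k: int | str = "auto",
                      k_max: int = 10, linkage: str = "complete",
                      log_scale: bool = True) -> ClusterResult:
    """Hierarchical clustering of normalized occupancy profiles.

    Rows are restricted to the columns present for every protein (cells
    that are structurally absent for one subunit are dropped for all, so no
    imputation is needed); the clustering itself is shared with the
    kinetics module.
    """
    shared = matrix.dropna(axis=1, how="any")
    if shared.shape[1] == 0:
        raise ValueError("no fraction shared by all proteins; cluster "
                         "subunits separately")
    dropped = matrix.shape[1] - shared.shape[1]
    if dropped:
        logger.info("cluster_occupancy: restricted to %d shared fractions "
                    "(%d dropped)", shared.shape[1], dropped)
    return cluster_profiles(shared, k=k, k_max=k_max, linkage=linkage,
                            log_scale=log_scale)
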