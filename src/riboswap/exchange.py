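"""Exchanger calling from the biogenesis-inhibition experiment.

When nuclear export of new ribosomes is blocked, the heavy fraction of a
stable ribosomal protein in assembled ribosomes collapses (its only entry
route is gone), while an exchanging protein keeps incorporating from the
free precursor pool.  Exchangers are therefore the proteins whose
treated/control fold change of heavy fractions is an *upward* outlier after
normalizing out the subunit-wide effect of the treatment.

Outlier calling follows the ROUT recipe (robust fit + FDR-sequenced outlier
tests with user parameter Q) specialized to its degenerate case, a
one-parameter constant model on log fold changes: the robust center is the
median, the scale is the RSDR estimated from the 68.27th percentile of
absolute residuals, and residuals are tested largest-first against
t-distribution thresholds whose significance levels follow the
Benjamini-Hochberg sequence alpha_i = Q * (n - i + 1) / (100 * n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "normalize_by_subunit",
    "RoutResult",
    "rout_outliers",
    "call_exchangers",
]

logger = logging.getLogger(__name__)

#: one-sigma coverage of the normal distribution; the percentile of
#: |residuals| that estimates the robust SD
_SD_PERCENTILE = 68.27


def normalize_by_subunit(records: pd.DataFrame,
                         subunit_map: dict[str, str] | pd.Series | None = None,
                         ) -> pd.DataFrame:
    """Divide each protein's fold change by its subunit's median fold change.

    ``records`` needs columns ``protein, fold_change`` and either a
    ``subunit`` column or an explicit ``subunit_map``.  When a
    ``compartment`` column is present, medians are taken within each
    compartment.  The median includes the protein itself.  An unmapped
    protein raises :class:`KeyError` naming it; a subunit with fewer than
    two proteins raises :class:`ValueError`.
    """
    out = records.copy()
    if subunit_map is not None:
        sub = pd.Series(subunit_map)
        missing = set(out["protein"]) - set(sub.index)
        if missing:
            raise KeyError(
                f"proteins without subunit assignment: {sorted(missing)}")
        out["subunit"] = out["protein"].map(sub)
    elif "subunit" not in out.columns:
        raise ValueError("no subunit column and no subunit_map given")
    if out["subunit"].isna().any():
        bad = sorted(out.loc[out["subunit"].isna(), "protein"])
        raise KeyError(f"proteins without subunit assignment: {bad}")

    group_cols = ["subunit"]
    if "compartment" in out.columns:
        group_cols = ["compartment", "subunit"]
    counts = out.groupby(group_cols)["fold_change"].count()
    if (counts < 2).any():
        raise ValueError("need at least 2 proteins per subunit to normalize")
    medians = out.groupby(group_cols)["fold_change"].transform("median")
    out["normalized_fold_change"] = out["fold_change"] / medians
    return out


@dataclass
class RoutResult:
    """Outcome of ROUT outlier detection on one set of values."""

    is_outlier: np.ndarray  # bool, input order
    side: np.ndarray  # "high" | "low" | "" per value
    center: float  # robust center (median of log values)
    rsdr: float  # robust SD of residuals (log scale)
    q: float  # FDR parameter, percent
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def n_outliers(self) -> int:
        return int(self.is_outlier.sum())


def rout_outliers(values, q: float = 0.2) -> RoutResult:
    """ROUT outlier detection on positive values, constant model, log scale.

    Procedure: (1) robust center = median of log values; (2) RSDR = 68.27th
    percentile of absolute residuals times the n/(n-1) small-sample
    correction; (3) residuals sorted by absolute size and tested
    largest-first with two-tailed t tests (df = n - 1) at significance
    levels alpha_i = q * (n - i + 1) / (100 * n); the first residual that
    fails stops the scan and all smaller ones are inliers.

    ``q`` is the ROUT FDR parameter in percent (0.2 means 0.2%).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 5:
        raise ValueError("need a 1-D array of at least 5 values")
    if not (0 < q < 100):
        raise ValueError("q is a percentage in (0, 100)")
    if (x <= 0).any() or not np.isfinite(x).all():
        raise ValueError("values must be positive and finite (log scale)")
    n = x.size
    logx = np.log(x)
    center = float(np.median(logx))
    resid = logx - center
    rsdr = float(np.percentile(np.abs(resid), _SD_PERCENTILE)) * n / (n - 1)

    is_out = np.zeros(n, dtype=bool)
    side = np.array([""] * n, dtype=object)
    if rsdr > 0:
        order = np.argsort(-np.abs(resid), kind="stable")
        tdist = stats.t(df=n - 1)
        for rank, idx in enumerate(order, start=1):
            alpha = q * (n - rank + 1) / (100.0 * n)
            p = 2.0 * tdist.sf(abs(resid[idx]) / rsdr)
            if p < alpha:
                is_out[idx] = True
                side[idx] = "high" if resid[idx] > 0 else "low"
            else:
                break
    return RoutResult(is_outlier=is_out, side=side, center=center,
                      rsdr=rsdr, q=q, residuals=resid)


def call_exchangers(records: pd.DataFrame,
                    subunit_map: dict[str, str] | pd.Series | None = None,
                    q: float = 0.2) -> dict:
    """Identify exchanging proteins per compartment.

    Runs :func:`normalize_by_subunit` and then :func:`rout_outliers` on the
    normalized fold changes of each compartment (a missing ``compartment``
    column means a single unnamed compartment).  Exchangers are the
    HIGH-side outliers — the proteins whose incorporation is least reduced
    by biogenesis inhibition; low-side outliers are reported in the table
    but not called exchangers.

    Returns a dict with ``table`` (per-protein calls), ``exchangers``
    (compartment -> set), ``intersection`` and ``only`` (compartment ->
    proteins unique to it).
    """
    work = records.copy()
    single = "compartment" not in work.columns
    if single:
        work["compartment"] = "all"
    work = normalize_by_subunit(work, subunit_map)

    tables = []
    exchangers: dict[str, set] = {}
    for comp, grp in work.groupby("compartment", sort=False):
        res = rout_outliers(grp["normalized_fold_change"].to_numpy(), q=q)
        grp = grp.copy()
        grp["outlier"] = res.is_outlier
        grp["side"] = res.side
        grp["is_exchanger"] = res.is_outlier & (res.side == "high")
        exchangers[comp] = set(grp.loc[grp["is_exchanger"], "protein"])
        tables.append(grp)
        logger.info("compartment %s: %d high / %d low outliers at Q=%.3g%%",
                    comp, int(grp["is_exchanger"].sum()),
                    int((grp["outlier"] & ~grp["is_exchanger"]).sum()), q)
    table = pd.concat(tables, ignore_index=True)
    sets = list(exchangers.values())
    inter = set.intersection(*sets) if sets else set()
    only = {comp: s - set.union(*(o for c, o in exchangers.items() if c != comp))
            if len(exchangers) > 1 else set(s)
            for comp, s in exchangers.items()}
    return {"table": table, "exchangers": exchangers,
            "intersection": inter, "only": only}
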