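"""Differential incorporation under acute stress.

Oxidative stress transiently inhibits bulk translation, so every peptide's
heavy fraction drops in the treated samples.  The analysis therefore first
rescales the treated samples by the average peptide-level fold change
(:func:`global_normalize`), then asks which proteins deviate from that
global behaviour with a peptide-aware linear mixed model per protein:

    log2(%H) = mu + beta * treatment + u_peptide + eps,

with a random intercept per peptide.  ``beta`` is the log2 differential
incorporation.  Proteins are accepted as regulated when the
Benjamini-Hochberg adjusted p-value passes the FDR cut *and* |beta| clears
a data-driven minimal difference (half the interquartile range of the
per-protein average differences).

The model is exposed statsmodels-style: build a
:class:`DifferentialIncorporation` from the peptide table, call ``fit()``,
inspect the returned :class:`DifferentialResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import quant

__all__ = [
    "global_normalize",
    "DifferentialIncorporation",
    "DifferentialResults",
    "differential_incorporation",
]

logger = logging.getLogger(__name__)


def global_normalize(table: pd.DataFrame, treated: str, control: str,
                     method: str = "arithmetic") -> pd.DataFrame:
    """Rescale treated heavy fractions by the average peptide fold change.

    The scalar is the mean over all peptides of (treated %H / control %H),
    each side first averaged over biological replicates; ``method`` selects
    the arithmetic (default) or geometric mean.  Every treated-condition
    heavy fraction is divided by the scalar; control rows are untouched.
    After normalization the all-peptide mean fold change is exactly 1.
    """
    if "heavy_fraction" not in table.columns:
        table = quant.add_heavy_fraction(table)
    t = quant._replicate_mean(table, treated)
    c = quant._replicate_mean(table, control)
    both = pd.concat({"t": t, "c": c}, axis=1).dropna()
    both = both[both["c"] > 0]
    if both.empty:
        raise ValueError("no peptides shared between conditions")
    ratios = both["t"] / both["c"]
    if method == "arithmetic":
        scalar = float(ratios.mean())
    elif method == "geometric":
        scalar = float(np.exp(np.log(ratios).mean()))
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(scalar) or scalar <= 0:
        raise ValueError("mean fold change is zero or undefined")
    logger.info("global normalization scalar (%s mean FC) = %.4g",
                method, scalar)
    out = table.copy()
    mask = out["condition"] == treated
    out.loc[mask, "heavy_fraction"] = out.loc[mask, "heavy_fraction"] / scalar
    return out


def _fit_protein(y: np.ndarray, treat: np.ndarray,
                 peptide: np.ndarray) -> tuple[float, float, float]:
    """Treatment effect, SE and residual df for one protein.

    For the balanced complete design (every peptide measured in both
    conditions with equal replication) the REML fit of the random-intercept
    model coincides with two-way fixed-effects ANOVA: peptide intercepts
    cancel in the treatment contrast, so beta is the difference of
    condition means and Var(beta) = sigma_e^2 (1/n1 + 1/n0) with
    sigma_e^2 the residual mean square on N - P - 1 degrees of freedom.
    Unbalanced proteins fall back to a REML mixed model (statsmodels) with
    the same residual df.
    """
    peptides, pep_idx = np.unique(peptide, return_inverse=True)
    n, p = y.size, peptides.size
    df = n - p - 1
    n1, n0 = int(treat.sum()), int((1 - treat).sum())
    if n1 == 0 or n0 == 0 or df < 1:
        return np.nan, np.nan, np.nan

    cells = pd.crosstab(pep_idx, treat)
    balanced = cells.nunique().eq(1).all() and (cells > 0).all().all()
    if balanced:
        beta = y[treat == 1].mean() - y[treat == 0].mean()
        # residuals after removing peptide and treatment effects
        fitted = np.zeros_like(y)
        for j in range(p):
            sel = pep_idx == j
            fitted[sel] += y[sel].mean()
        adj = np.where(treat == 1, beta * n0 / n, -beta * n1 / n)
        resid = y - fitted - adj
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * (1.0 / n1 + 1.0 / n0))
        return float(beta), float(se), float(df)

    if p >= 3:
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM
        exog = sm.add_constant(treat.astype(float))
        with np.errstate(all="ignore"):
            fit = MixedLM(y, exog, groups=pep_idx).fit(reml=True)
        return float(fit.params[1]), float(fit.bse[1]), float(df)
    # too few peptides for variance components: fixed peptide intercepts
    X = np.column_stack([np.eye(p)[pep_idx], treat.astype(float)])
    coef, res_ss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    return float(coef[-1]), float(se), float(df)


@dataclass
class DifferentialResults:
    """Per-protein differential-incorporation estimates and calls."""

    frame: pd.DataFrame
    min_difference: float
    fdr_cut: float
    treated: str
    control: str

    @property
    def significant(self) -> list[str]:
        sig = self.frame.loc[self.frame["significant"], "protein"]
        return list(sig)

    def summary(self) -> str:
        f = self.frame
        n_test = int(f["testable"].sum())
        lines = [
            "Differential incorporation "
            f"({self.treated} vs {self.control})",
            f"proteins tested: {n_test}/{len(f)}   "
            f"FDR cut: {self.fdr_cut:g}   "
            f"minimal |log2 effect|: {self.min_difference:.4f}",
            f"significant: {len(self.significant)}",
            "",
            f[["protein", "effect", "se", "p_value", "q_value",
               "passes_min_difference", "significant"]]
            .sort_values("q_value").head(15).to_string(index=False),
        ]
        return "\n".join(lines)


class DifferentialIncorporation:
    """Peptide-level mixed model of treated-vs-control incorporation.

    Parameters
    ----------
    table : tidy peptide table with ``heavy_fraction`` (tech replicates
        already merged), containing both conditions.
    treated, control : condition labels.
    normalize : apply :func:`global_normalize` first (default True).
    """

    def __init__(self, table: pd.DataFrame, treated: str, control: str,
                 normalize: bool = True, norm_method: str = "arithmetic"):
        if "heavy_fraction" not in table.columns:
            table = quant.add_heavy_fraction(table)
        for cond in (treated, control):
            if cond not in set(table["condition"]):
                raise ValueError(f"condition {cond!r} absent from table")
        if normalize:
            table = global_normalize(table, treated, control,
                                     method=norm_method)
        self.table = table[table["condition"].isin([treated, control])].copy()
        self.treated = treated
        self.control = control

    @classmethod
    def from_simulation(cls, peptides: pd.DataFrame, treated: str,
                        control: str, **kw) -> "DifferentialIncorporation":
        """Build from a raw simulated peptide table (merges tech reps)."""
        merged = quant.merge_technical(quant.add_heavy_fraction(peptides))
        return cls(merged, treated, control, **kw)

    def fit(self, fdr_cut: float = 0.01) -> DifferentialResults:
        """Fit per-protein models, BH-correct, apply the minimal-difference
        gate, and return the results object."""
        work = self.table[self.table["heavy_fraction"] > 0].copy()
        work["y"] = np.log2(work["heavy_fraction"])
        work["treat"] = (work["condition"] == self.treated).astype(int)

        rows = []
        for prot, grp in work.groupby("protein", sort=True):
            beta, se, df = _fit_protein(grp["y"].to_numpy(),
                                        grp["treat"].to_numpy(),
                                        grp["peptide"].to_numpy())
            testable = np.isfinite(beta) and np.isfinite(se) and se > 0
            if testable:
                p = 2.0 * stats.t.sf(abs(beta) / se, df)
            else:
                p = np.nan
            rows.append({"protein": prot, "effect": beta, "se": se,
                         "df": df, "p_value": p,
                         "n_peptides": grp["peptide"].nunique(),
                         "testable": bool(testable)})
        frame = pd.DataFrame(rows)

        frame["q_value"] = np.nan
        mask = frame["testable"].to_numpy()
        if mask.any():
            frame.loc[mask, "q_value"] = multipletests(
                frame.loc[mask, "p_value"], method="fdr_bh")[1]

        effects = frame.loc[mask, "effect"]
        q1, q3 = np.percentile(effects, [25, 75]) if mask.any() else (0, 0)
        min_diff = 0.5 * (q3 - q1)
        frame["passes_min_difference"] = frame["effect"].abs() >= min_diff
        frame["significant"] = (mask & (frame["q_value"] < fdr_cut)
                                & frame["passes_min_difference"])
        n_untestable = int((~frame["testable"]).sum())
        if n_untestable:
            logger.info("%d proteins untestable (one-sided observations)",
                        n_untestable)
        return DifferentialResults(frame=frame, min_difference=float(min_diff),
                                   fdr_cut=fdr_cut, treated=self.treated,
                                   control=self.control)


def differential_incorporation(table: pd.DataFrame, treated: str,
                               control: str, fdr_cut: float = 0.01,
                               normalize: bool = True) -> DifferentialResults:
    """Functional wrapper: build the model and fit in one call."""
    model = DifferentialIncorporation(table, treated, control,
                                      normalize=normalize)
    return model.fit(fdr_cut=fdr_cut)
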