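"""Peptide-level heavy/light quantification and protein roll-up.

The atomic record is one peptide's heavy (H) and light (L) peak area in one
condition/replicate.  All functions operate on tidy :class:`pandas.DataFrame`
tables with the columns

``protein, peptide, condition, bio_rep, tech_rep, area_heavy, area_light``

(``subunit`` is carried through when present).  The processing chain is:
heavy fraction %H = H/(H+L) per peptide, technical replicates merged by
mean, peptides failing the 3x no-label background check removed, protein
values as the median over peptides, and treated/control fold changes as the
protein-level median of peptide-level ratios of replicate means.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "read_peptide_report",
    "heavy_fraction",
    "add_heavy_fraction",
    "merge_technical",
    "background_filter",
    "protein_rollup",
    "protein_foldchange",
    "total_intensity_foldchange",
    "polysome_fraction",
    "qpcr_relative",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "protein", "peptide", "condition", "bio_rep", "tech_rep",
    "area_heavy", "area_light",
)

_PEPTIDE_KEY = ["protein", "peptide", "condition", "bio_rep"]


def read_peptide_report(path, *, sep: str | None = None,
                        column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a peptide quantification export (CSV/TSV) into a validated table.

    ``column_map`` renames source columns to the canonical names.  Rows with
    negative areas or with both areas zero are dropped (counted in the log);
    a missing required column raises :class:`ValueError` naming it.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if column_map:
        df = df.rename(columns=column_map)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column: {col!r}")
    if df.empty:
        logger.warning("peptide report %s contains a header only", path)
        return df
    n0 = len(df)
    bad = (
        df["area_heavy"].isna() | df["area_light"].isna()
        | (df["area_heavy"] < 0) | (df["area_light"] < 0)
        | ((df["area_heavy"] == 0) & (df["area_light"] == 0))
    )
    if bad.any():
        logger.info("dropped %d/%d invalid peptide rows", int(bad.sum()), n0)
    return df.loc[~bad].reset_index(drop=True)


def heavy_fraction(area_heavy: float, area_light: float) -> float:
    """%H = H / (H + L); NaN when both areas are zero (never 0/0)."""
    total = area_heavy + area_light
    if total <= 0:
        return float("nan")
    return area_heavy / total


def add_heavy_fraction(table: pd.DataFrame) -> pd.DataFrame:
    """Vectorized %H column; rows with H + L = 0 get NaN."""
    out = table.copy()
    total = out["area_heavy"] + out["area_light"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["heavy_fraction"] = np.where(total > 0, out["area_heavy"] / total,
                                         np.nan)
    return out


def _carry_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in ("subunit",) if c in table.columns]


def merge_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of %H over technical replicates, one row per (protein, peptide,
    condition, bio_rep).  Missing technical values are ignored."""
    if "heavy_fraction" not in table.columns:
        table = add_heavy_fraction(table)
    keys = _carry_columns(table) + _PEPTIDE_KEY
    merged = (table.groupby(keys, sort=False, dropna=False)["heavy_fraction"]
              .mean().reset_index())
    return merged


def background_filter(table: pd.DataFrame, no_label_condition: str,
                      factor: float = 3.0,
                      conditions: list[str] | None = None) -> pd.DataFrame:
    """Remove peptides not clearly above the no-label background.

    A peptide is kept iff its mean %H in **every** labeled condition of
    interest is >= ``factor`` times its mean %H in the no-label condition.
    Peptides with no no-label record are kept with a warning; the no-label
    rows themselves are removed from the output.
    """
    if no_label_condition not in set(table["condition"]):
        raise ValueError(f"no-label condition {no_label_condition!r} absent")
    if "heavy_fraction" not in table.columns:
        table = add_heavy_fraction(table)
    labeled = table[table["condition"] != no_label_condition]
    if conditions is not None:
        labeled = labeled[labeled["condition"].isin(conditions)]
    bg = (table[table["condition"] == no_label_condition]
          .groupby(["protein", "peptide"])["heavy_fraction"].mean())
    per_cond = (labeled.groupby(["protein", "peptide", "condition"])
                ["heavy_fraction"].mean())
    worst = per_cond.groupby(["protein", "peptide"]).min()

    keep, missing_bg = [], 0
    for key, value in worst.items():
        if key not in bg.index:
            missing_bg += 1
            keep.append(key)
        elif value >= factor * bg.loc[key]:
            keep.append(key)
    if missing_bg:
        logger.warning("%d peptides had no no-label record; kept", missing_bg)
    n_pep = worst.shape[0]
    logger.info("background filter (%.3gx): kept %d/%d peptides",
                factor, len(keep), n_pep)
    keep_idx = pd.MultiIndex.from_tuples(keep, names=["protein", "peptide"])
    out = labeled.set_index(["protein", "peptide"])
    out = out.loc[out.index.isin(keep_idx)].reset_index()
    return out


def protein_rollup(table: pd.DataFrame) -> pd.DataFrame:
    """Protein %H per (condition, bio_rep): median over peptides.

    Returns columns ``protein[, subunit], condition, bio_rep,
    heavy_fraction, n_peptides``.
    """
    if table.empty:
        raise ValueError("empty table")
    if "heavy_fraction" not in table.columns:
        table = add_heavy_fraction(table)
    keys = _carry_columns(table) + ["protein", "condition", "bio_rep"]
    grouped = table.groupby(keys, sort=False)["heavy_fraction"]
    out = grouped.median().reset_index()
    out["n_peptides"] = grouped.count().to_numpy()
    return out


def _replicate_mean(table: pd.DataFrame, condition: str) -> pd.Series:
    sub = table[table["condition"] == condition]
    return sub.groupby(["protein", "peptide"])["heavy_fraction"].mean()


def protein_foldchange(table: pd.DataFrame, treated: str,
                       control: str) -> pd.DataFrame:
    """Treated/control fold change of %H, peptide-level first.

    Per peptide, FC = (mean %H over treated bio reps) / (mean over control
    bio reps); per protein, the median of its peptide FCs.  Peptides missing
    either side or with a zero control fraction are skipped and counted.
    """
    for cond in (treated, control):
        if cond not in set(table["condition"]):
            raise ValueError(f"condition {cond!r} absent from table")
    if "heavy_fraction" not in table.columns:
        table = add_heavy_fraction(table)
    t = _replicate_mean(table, treated)
    c = _replicate_mean(table, control)
    both = pd.concat({"treated": t, "control": c}, axis=1)
    n_total = len(both)
    usable = both.dropna()
    usable = usable[usable["control"] > 0]
    skipped = n_total - len(usable)
    if skipped:
        logger.info("fold change: skipped %d/%d peptides (missing side or "
                    "zero control)", skipped, n_total)
    fc = (usable["treated"] / usable["control"]).rename("fold_change")
    out = fc.groupby("protein").median().reset_index()
    out["n_peptides"] = fc.groupby("protein").size().to_numpy()
    if "subunit" in table.columns:
        sub_map = table.drop_duplicates("protein").set_index("protein")["subunit"]
        out.insert(1, "subunit", out["protein"].map(sub_map))
    return out


def total_intensity_foldchange(table: pd.DataFrame, treated: str,
                               control: str) -> pd.DataFrame:
    """Total-intensity (H + L) fold change, used for the EDTA control.

    Per peptide and condition the total intensity is merged over replicates
    by mean; peptide-level FCs are combined per protein by median.
    """
    for cond in (treated, control):
        if cond not in set(table["condition"]):
            raise ValueError(f"condition {cond!r} absent from table")
    work = table.copy()
    work["total_intensity"] = work["area_heavy"] + work["area_light"]
    per = (work.groupby(["protein", "peptide", "condition"])["total_intensity"]
           .mean().unstack("condition"))
    usable = per[[treated, control]].dropna()
    usable = usable[usable[control] > 0]
    fc = (usable[treated] / usable[control]).rename("fold_change")
    out = fc.groupby("protein").median().reset_index()
    out["n_peptides"] = fc.groupby("protein").size().to_numpy()
    return out


def polysome_fraction(position: np.ndarray, absorbance: np.ndarray,
                      monosome_region: tuple[float, float],
                      polysome_region: tuple[float, float],
                      baseline: float = 0.0) -> float:
    """Polysome area over (monosome + polysome) area of a 254-nm trace.

    Areas are trapezoidal integrals of the absorbance above ``baseline``
    within each region; regions must be ordered and non-overlapping.
    """
    position = np.asarray(position, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    for lo, hi in (monosome_region, polysome_region):
        if hi <= lo:
            raise ValueError("region boundaries must be increasing")
    if monosome_region[1] > polysome_region[0]:
        raise ValueError("monosome and polysome regions overlap")

    def area(lo: float, hi: float) -> float:
        mask = (position >= lo) & (position <= hi)
        y = np.clip(absorbance[mask] - baseline, 0.0, None)
        return float(np.trapezoid(y, position[mask]))

    a_mono = area(*monosome_region)
    a_poly = area(*polysome_region)
    total = a_mono + a_poly
    if total <= 0:
        raise ValueError("zero total area under monosome + polysome regions")
    return a_poly / total


def qpcr_relative(ct_target: float, ct_reference: float,
                  ct_target_ctrl: float, ct_reference_ctrl: float) -> float:
    """Relative qPCR level by 2^(-ddCt), internally normalized to a
    reference assay and then to a no-label control sample."""
    for ct in (ct_target, ct_reference, ct_target_ctrl, ct_reference_ctrl):
        if not np.isfinite(ct):
            raise ValueError("all Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_ctrl - ct_reference_ctrl)
    return float(2.0 ** (-ddct))
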