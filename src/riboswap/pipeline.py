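"""End-to-end orchestration: simulate -> quant -> kinetics/exchange/stress.

Each stage reads tidy CSVs, writes tidy CSVs into the run directory plus a
machine-readable ``summary`` block (records in/out, parameters), and the
whole run is sealed by ``manifest.json`` with SHA-256 hashes of every
output, so identical configurations reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, exchange, kinetics, occupancy, quant, simkit, stress
from .config import RunConfig

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, index=index, float_format="%.10g")
    return path


def _sim_config(params: dict, seed: int) -> simkit.SimConfig:
    experiment = params["experiment"]
    builders = {"kinetics": simkit.kinetics_config, "lmb": simkit.lmb_config,
                "stress": simkit.stress_config}
    if experiment not in builders:
        raise ValueError(f"unknown experiment preset {experiment!r}")
    kwargs = {"noise_cv": params["noise_cv"]}
    if params["n_biological"] is not None:
        kwargs["n_biological"] = params["n_biological"]
    return builders[experiment](seed, **kwargs)


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> dict:
    sim = _sim_config(cfg["simulate"], cfg.seed)
    peptides, truth = simkit.simulate_experiment(sim)
    _write(peptides, out / "peptides.csv")
    _write(truth, out / "ground_truth.csv")
    state["peptides"] = peptides
    state["conditions"] = sorted(sim.conditions)
    return {"n_rows": len(peptides), "n_proteins": len(sim.proteins),
            "conditions": state["conditions"],
            "experiment": cfg["simulate"]["experiment"]}


def _load_peptides(cfg: RunConfig, state: dict) -> pd.DataFrame:
    if "peptides" in state:
        return state["peptides"]
    path = cfg["quant"]["input"]
    if path is None:
        raise ValueError("quant.input not set and no simulate stage ran")
    return quant.read_peptide_report(path)


def _stage_quant(cfg: RunConfig, out: Path, state: dict) -> dict:
    p = cfg["quant"]
    table = _load_peptides(cfg, state)
    known = set(table["condition"])
    for key in ("no_label_condition", "treated", "control"):
        if p[key] is not None and p[key] not in known:
            raise ValueError(f"quant.{key}={p[key]!r} not a condition "
                             f"of the input (has {sorted(known)})")
    merged = quant.merge_technical(quant.add_heavy_fraction(table))
    n_before = merged[["protein", "peptide"]].drop_duplicates().shape[0]
    if p["no_label_condition"] is not None:
        merged = quant.background_filter(
            merged, p["no_label_condition"], factor=p["background_factor"])
    n_after = merged[["protein", "peptide"]].drop_duplicates().shape[0]
    _write(merged, out / "heavy_fractions.csv")
    rollup = quant.protein_rollup(merged)
    _write(rollup, out / "protein_quant.csv")
    state["heavy_fractions"] = merged
    state["protein_quant"] = rollup
    summary = {"n_peptides_in": n_before, "n_peptides_kept": n_after,
               "background_factor": p["background_factor"]}
    if p["treated"] is not None and p["control"] is not None:
        fc = quant.protein_foldchange(merged, p["treated"], p["control"])
        _write(fc, out / "fold_changes.csv")
        state["fold_changes"] = fc
        summary["n_fold_changes"] = len(fc)
    return summary


def _stage_kinetics(cfg: RunConfig, out: Path, state: dict) -> dict:
    p = cfg["kinetics"]
    rollup = state.get("protein_quant")
    if rollup is None:
        raise ValueError("kinetics requires the quant stage")
    conditions = p["conditions"]
    if conditions is None:
        raise ValueError("kinetics.conditions not set")
    known = set(rollup["condition"])
    missing = [c for c in conditions if c not in known]
    if missing:
        raise ValueError(f"kinetics.conditions {missing} not in data "
                         f"(has {sorted(known)})")
    matrix = kinetics.build_profiles(rollup, conditions)
    result = kinetics.cluster_profiles(matrix, k=p["k"], k_max=p["k_max"],
                                       linkage=p["linkage"])
    rapid = kinetics.rapid_group(result, matrix, p["no_chase_conditions"])
    flat = matrix.copy()
    flat.columns = [f"{c}|rep{r}" for c, r in matrix.columns]
    _write(flat, out / "profile_matrix.csv", index=True)
    assignments = result.assignments.reset_index()
    assignments["rapid"] = assignments["protein"].isin(rapid)
    _write(assignments, out / "cluster_assignments.csv")
    summary = {"n_proteins": len(matrix), "k": result.k,
               "silhouette_by_k": {str(k): round(v, 4) for k, v in
                                   result.silhouette_by_k.items()},
               "n_rapid": len(rapid)}
    if p["pulse_condition"] and p["chase_condition"]:
        resp = kinetics.chase_response(matrix, p["pulse_condition"],
                                       p["chase_condition"])
        _write(resp.reset_index(), out / "chase_response.csv")
        summary["n_chase_increase"] = int((resp["delta"] > 0).sum())
    return summary


def _stage_exchange(cfg: RunConfig, out: Path, state: dict) -> dict:
    p = cfg["exchange"]
    fc = state.get("fold_changes")
    if fc is None:
        raise ValueError("exchange requires quant with treated/control set")
    sub_map = None
    if p["subunits"] is not None:
        sub_map = pd.read_csv(p["subunits"]).set_index("protein")["subunit"]
    res = exchange.call_exchangers(fc, subunit_map=sub_map, q=p["q"])
    _write(res["table"], out / "exchanger_calls.csv")
    return {"q": p["q"],
            "exchangers": {c: sorted(s) for c, s in res["exchangers"].items()},
            "n_exchangers": {c: len(s) for c, s in res["exchangers"].items()}}


def _stage_stress(cfg: RunConfig, out: Path, state: dict) -> dict:
    p = cfg["stress"]
    table = state.get("heavy_fractions")
    if table is None:
        raise ValueError("stress requires the quant stage")
    if p["treated"] is None or p["control"] is None:
        raise ValueError("stress.treated and stress.control must be set")
    model = stress.DifferentialIncorporation(
        table, p["treated"], p["control"], normalize=p["normalize"])
    res = model.fit(fdr_cut=p["fdr"])
    _write(res.frame, out / "differential_incorporation.csv")
    return {"fdr": p["fdr"], "min_difference": res.min_difference,
            "significant": sorted(res.significant)}


def _stage_sasa(cfg: RunConfig, out: Path, state: dict) -> dict:
    from . import structure as st
    p = cfg["sasa"]
    if p["pdb"] is None:
        raise ValueError("sasa.pdb not set")
    struct = st.Structure.from_pdb(p["pdb"])
    fracs = st.all_chain_fractions(struct, probe=p["probe"],
                                   n_points=p["n_points"])
    df = pd.DataFrame([{"chain": f.chain,
                        "sasa_in_complex": f.sasa_in_complex,
                        "sasa_isolated": f.sasa_isolated,
                        "accessible_fraction": f.accessible_fraction}
                       for f in fracs])
    summary: dict = {"n_chains": len(df)}
    if p["groups"] is not None:
        groups = pd.read_csv(p["groups"]).set_index("chain")["group"]
        df["group"] = df["chain"].map(groups)
        comp = st.compare_accessibility(df["accessible_fraction"],
                                        df["group"])
        summary["mann_whitney"] = comp
    _write(df, out / "chain_sasa.csv")
    return summary


def _stage_occupancy(cfg: RunConfig, out: Path, state: dict) -> dict:
    p = cfg["occupancy"]
    if p["input"] is None:
        raise ValueError("occupancy.input not set")
    records = pd.read_csv(p["input"])
    matrix = occupancy.normalize_occupancy(records)
    _write(matrix, out / "occupancy_matrix.csv", index=True)
    result = occupancy.cluster_occupancy(matrix, k=p["k"])
    _write(result.assignments.reset_index(), out / "occupancy_clusters.csv")
    return {"n_proteins": len(matrix), "k": result.k}


_STAGES = {
    "simulate": _stage_simulate, "quant": _stage_quant,
    "kinetics": _stage_kinetics, "exchange": _stage_exchange,
    "stress": _stage_stress, "sasa": _stage_sasa,
    "occupancy": _stage_occupancy,
}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory.  A failing stage raises
    :class:`PipelineError` naming it; outputs of completed stages are
    retained.  Reruns with an identical configuration reproduce identical
    output hashes (recorded in ``manifest.json``).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state: dict = {}
    manifest = {"version": __version__, "seed": cfg.seed,
                "stages": [], "outputs": {}}
    ordered = [s for s in _STAGES if s in cfg.stages]
    for stage in ordered:
        logger.info("running stage %s", stage)
        before = set(out.iterdir())
        try:
            summary = _STAGES[stage](cfg, out, state)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise PipelineError(stage, exc) from exc
        manifest["stages"].append({"name": stage, "summary": summary,
                                   "params": cfg[stage]})
        for path in sorted(set(out.iterdir()) - before):
            manifest["outputs"][path.name] = _sha256(path)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
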