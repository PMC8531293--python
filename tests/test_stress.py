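"""Stress arm: global normalization and the differential mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from riboswap import quant, simkit, stress


def _peptide_table(effects, n_peptides=5, n_reps=3, noise_sd=0.07,
                   base=0.05, seed=0):
    """Balanced two-condition table with planted log2 shifts per protein."""
    rng = np.random.default_rng(seed)
    rows = []
    for prot, delta in effects.items():
        for j in range(n_peptides):
            pep_offset = rng.normal(0, 0.3)  # peptide-specific level
            for cond, shift in (("ctrl", 0.0), ("h2o2", delta)):
                for rep in range(1, n_reps + 1):
                    frac = base * 2 ** (pep_offset + shift
                                        + rng.normal(0, noise_sd))
                    rows.append((prot, f"{prot}_p{j}", cond, rep, frac))
    return pd.DataFrame(rows, columns=["protein", "peptide", "condition",
                                       "bio_rep", "heavy_fraction"])


class TestGlobalNormalize:
    def test_uniform_halving_restored(self):
        table = _peptide_table({"P1": -1.0, "P2": -1.0}, noise_sd=0.0)
        out = stress.global_normalize(table, "h2o2", "ctrl")
        t = quant._replicate_mean(out, "h2o2")
        c = quant._replicate_mean(out, "ctrl")
        np.testing.assert_allclose(t / c, 1.0)

    def test_identity_scalar_for_identical_tables(self):
        table = _peptide_table({"P1": 0.0, "P2": 0.0}, noise_sd=0.0)
        out = stress.global_normalize(table, "h2o2", "ctrl")
        pd.testing.assert_frame_equal(out, table)

    def test_mean_fold_change_is_one_after(self):
        table = _peptide_table({f"P{i}": d for i, d in
                                enumerate([-1.5, -0.5, 0.3, -1.0])},
                               noise_sd=0.1, seed=4)
        out = stress.global_normalize(table, "h2o2", "ctrl")
        t = quant._replicate_mean(out, "h2o2")
        c = quant._replicate_mean(out, "ctrl")
        assert (t / c).mean() == pytest.approx(1.0, rel=1e-12)

    def test_geometric_option(self):
        table = _peptide_table({"P1": -2.0, "P2": 0.0}, noise_sd=0.0)
        out = stress.global_normalize(table, "h2o2", "ctrl",
                                      method="geometric")
        t = quant._replicate_mean(out, "h2o2")
        c = quant._replicate_mean(out, "ctrl")
        assert np.exp(np.log(t / c).mean()) == pytest.approx(1.0)

    def test_planted_enhanced_subset_stands_out(self):
        # global halving of synthesis; only the enhanced proteins deviate
        # from FC 1 after normalization
        effects = {f"S{i}": -1.0 for i in range(12)}
        effects.update({"E1": -0.2, "E2": -0.2})
        table = _peptide_table(effects, noise_sd=0.03, seed=9)
        out = stress.global_normalize(table, "h2o2", "ctrl")
        t = quant._replicate_mean(out, "h2o2")
        c = quant._replicate_mean(out, "ctrl")
        fc = (t / c).groupby("protein").mean()
        enhanced = fc[["E1", "E2"]]
        background = fc.drop(["E1", "E2"])
        assert (enhanced > 1.4).all()
        assert np.allclose(background, background.mean(), rtol=0.1)


class TestModelFit:
    def test_balanced_path_matches_mixedlm(self):
        import statsmodels.api as sm
        from statsmodels.regression.mixed_linear_model import MixedLM
        table = _peptide_table({"P1": -0.4}, n_peptides=6, n_reps=4, seed=1)
        model = stress.DifferentialIncorporation(table, "h2o2", "ctrl",
                                                 normalize=False)
        res = model.fit().frame.iloc[0]
        work = table.copy()
        work["y"] = np.log2(work["heavy_fraction"])
        work["treat"] = (work["condition"] == "h2o2").astype(float)
        fit = MixedLM(work["y"], sm.add_constant(work["treat"]),
                      groups=work["peptide"]).fit(reml=True)
        assert res["effect"] == pytest.approx(fit.params.iloc[1], abs=1e-6)
        assert res["se"] == pytest.approx(fit.bse.iloc[1], rel=0.05)

    def test_single_peptide_reduces_to_t_test(self):
        table = _peptide_table({"P1": -0.6}, n_peptides=1, n_reps=4, seed=2)
        model = stress.DifferentialIncorporation(table, "h2o2", "ctrl",
                                                 normalize=False)
        res = model.fit().frame.iloc[0]
        y = np.log2(table["heavy_fraction"])
        t = y[table["condition"] == "h2o2"]
        c = y[table["condition"] == "ctrl"]
        tt = sps.ttest_ind(t, c, equal_var=True)
        assert res["effect"] == pytest.approx(t.mean() - c.mean())
        assert res["p_value"] == pytest.approx(tt.pvalue, rel=1e-9)

    def test_planted_shift_recovered(self):
        # delta = 0.5 log2 in 3 of 40 proteins at 10% measurement noise
        effects = {f"N{i:02d}": 0.0 for i in range(37)}
        effects.update({"UP1": 0.5, "UP2": 0.5, "UP3": 0.5})
        table = _peptide_table(effects, n_peptides=5, n_reps=3,
                               noise_sd=0.10, seed=5)
        model = stress.DifferentialIncorporation(table, "h2o2", "ctrl",
                                                 normalize=False)
        res = model.fit(fdr_cut=0.01)
        frame = res.frame.set_index("protein")
        for prot in ("UP1", "UP2", "UP3"):
            assert abs(frame.loc[prot, "effect"] - 0.5) <= 0.15
            assert frame.loc[prot, "q_value"] < 0.01
            assert frame.loc[prot, "significant"]

    def test_null_significance_rate(self):
        # 1,000 null proteins across batches: q < 0.01 rate stays below 2%
        n_sig = n_tot = 0
        for seed in range(5):
            effects = {f"N{i:03d}": 0.0 for i in range(200)}
            table = _peptide_table(effects, n_peptides=3, n_reps=3,
                                   noise_sd=0.1, seed=100 + seed)
            res = stress.DifferentialIncorporation(
                table, "h2o2", "ctrl", normalize=False).fit(fdr_cut=0.01)
            n_sig += int((res.frame["q_value"] < 0.01).sum())
            n_tot += len(res.frame)
        assert n_sig / n_tot < 0.02

    def test_null_pvalues_uniform(self):
        effects = {f"N{i:04d}": 0.0 for i in range(1000)}
        table = _peptide_table(effects, n_peptides=3, n_reps=3,
                               noise_sd=0.1, seed=77)
        res = stress.DifferentialIncorporation(
            table, "h2o2", "ctrl", normalize=False).fit()
        ks = sps.kstest(res.frame["p_value"], "uniform").statistic
        assert ks < 0.05

    def test_effect_equivariance(self):
        table = _peptide_table({"P1": -0.3, "P2": 0.2}, seed=6)
        base = stress.DifferentialIncorporation(
            table, "h2o2", "ctrl", normalize=False).fit().frame
        shifted = table.copy()
        mask = shifted["condition"] == "h2o2"
        shifted.loc[mask, "heavy_fraction"] *= 2 ** 0.7
        out = stress.DifferentialIncorporation(
            shifted, "h2o2", "ctrl", normalize=False).fit().frame
        np.testing.assert_allclose(out["effect"], base["effect"] + 0.7,
                                   atol=1e-9)
        np.testing.assert_allclose(out["se"], base["se"], atol=1e-9)

    def test_one_sided_protein_untestable(self):
        table = _peptide_table({"P1": 0.0, "P2": 0.0}, seed=8)
        table = table[~((table["protein"] == "P2")
                        & (table["condition"] == "h2o2"))]
        res = stress.DifferentialIncorporation(
            table, "h2o2", "ctrl", normalize=False).fit()
        frame = res.frame.set_index("protein")
        assert not frame.loc["P2", "testable"]
        assert np.isnan(frame.loc["P2", "q_value"])
        assert frame.loc["P1", "testable"]

    def test_min_difference_gates_significance(self):
        # a precise but tiny effect below half the IQR of the effect
        # distribution must not be called, however small its q-value
        rng = np.random.default_rng(13)
        effects = {f"N{i}": float(rng.uniform(-0.25, 0.25))
                   for i in range(24)}
        effects["TINY"] = 0.02
        effects["BIG"] = 0.9
        table = _peptide_table(effects, n_peptides=8, n_reps=4,
                               noise_sd=0.02, seed=10)
        res = stress.DifferentialIncorporation(
            table, "h2o2", "ctrl", normalize=False).fit()
        frame = res.frame.set_index("protein")
        assert res.min_difference > 0.02
        assert frame.loc["BIG", "significant"]
        assert frame.loc["TINY", "q_value"] < 0.01  # precise...
        assert not frame.loc["TINY", "passes_min_difference"]  # ...but tiny
        assert not frame.loc["TINY", "significant"]

    def test_unbalanced_design_falls_back(self):
        table = _peptide_table({"P1": -0.5}, n_peptides=4, n_reps=3, seed=11)
        # drop one replicate of one peptide: design no longer balanced
        drop = ((table["peptide"] == "P1_p0")
                & (table["condition"] == "h2o2") & (table["bio_rep"] == 1))
        res = stress.DifferentialIncorporation(
            table[~drop], "h2o2", "ctrl", normalize=False).fit()
        row = res.frame.iloc[0]
        assert row["testable"]
        assert abs(row["effect"] + 0.5) < 0.2


class TestEndToEnd:
    def test_stress_simulation_enhanced_on_top(self):
        cfg = simkit.stress_config(seed=21)
        peptides, truth = simkit.simulate_experiment(cfg)
        model = stress.DifferentialIncorporation.from_simulation(
            peptides, "h2o2", "ctrl")
        res = model.fit()
        enhanced = {s.name for s in cfg.proteins if s.stress_enhanced}
        top = set(res.frame.nlargest(len(enhanced), "effect")["protein"])
        assert top == enhanced
        frame = res.frame.set_index("protein")
        assert frame.loc[sorted(enhanced), "significant"].all()
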