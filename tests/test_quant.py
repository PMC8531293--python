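"""Quantification chain: %H, replicate merging, filtering, roll-ups."""

import math

import numpy as np
import pandas as pd
import pytest

from riboswap import quant


def _table(rows, columns=("protein", "peptide", "condition", "bio_rep",
                          "tech_rep", "area_heavy", "area_light")):
    return pd.DataFrame(rows, columns=list(columns))


@pytest.fixture()
def small_table():
    return _table([
        ("P1", "a", "t", 1, 1, 10.0, 90.0),
        ("P1", "a", "t", 1, 2, 30.0, 70.0),
        ("P1", "b", "t", 1, 1, 40.0, 60.0),
        ("P1", "a", "c", 1, 1, 5.0, 95.0),
        ("P1", "b", "c", 1, 1, 20.0, 80.0),
        ("P2", "x", "t", 1, 1, 75.0, 25.0),
    ])


class TestReadReport:
    def test_well_formed(self, tmp_path, small_table):
        path = tmp_path / "report.csv"
        small_table.to_csv(path, index=False)
        out = quant.read_peptide_report(path)
        assert len(out) == 6

    def test_invalid_rows_dropped(self, tmp_path):
        df = _table([
            ("P1", "a", "t", 1, 1, 10.0, 90.0),
            ("P1", "b", "t", 1, 1, 0.0, 0.0),  # unusable
            ("P1", "c", "t", 1, 1, -1.0, 5.0),  # negative area
        ])
        path = tmp_path / "report.csv"
        df.to_csv(path, index=False)
        out = quant.read_peptide_report(path)
        assert list(out["peptide"]) == ["a"]

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("protein,peptide\nP1,a\n")
        with pytest.raises(ValueError, match="condition"):
            quant.read_peptide_report(path)

    def test_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(",".join(quant.REQUIRED_COLUMNS) + "\n")
        assert quant.read_peptide_report(path).empty

    def test_tsv_sniffed(self, tmp_path, small_table):
        path = tmp_path / "report.tsv"
        small_table.to_csv(path, index=False, sep="\t")
        assert len(quant.read_peptide_report(path)) == 6


class TestHeavyFraction:
    @pytest.mark.parametrize("h,l,expected", [
        (75.0, 25.0, 0.75), (0.0, 50.0, 0.0), (50.0, 0.0, 1.0),
    ])
    def test_values(self, h, l, expected):
        assert quant.heavy_fraction(h, l) == expected

    def test_both_zero_is_missing(self):
        assert math.isnan(quant.heavy_fraction(0.0, 0.0))

    def test_vectorized_matches_scalar(self, small_table):
        out = quant.add_heavy_fraction(small_table)
        for _, row in out.iterrows():
            assert row["heavy_fraction"] == pytest.approx(
                quant.heavy_fraction(row["area_heavy"], row["area_light"]))


class TestMergeTechnical:
    def test_mean_of_duplicates(self, small_table):
        merged = quant.merge_technical(small_table)
        val = merged.query(
            "protein == 'P1' and peptide == 'a' and condition == 't'"
        )["heavy_fraction"].item()
        assert val == pytest.approx((0.10 + 0.30) / 2)

    def test_single_replicate_identity(self, small_table):
        merged = quant.merge_technical(small_table)
        val = merged.query(
            "protein == 'P2' and peptide == 'x'")["heavy_fraction"].item()
        assert val == pytest.approx(0.75)

    def test_missing_tech_value_ignored(self):
        df = _table([
            ("P1", "a", "t", 1, 1, 10.0, 90.0),
            ("P1", "a", "t", 1, 2, 0.0, 0.0),  # NaN fraction
        ])
        merged = quant.merge_technical(df)
        assert merged["heavy_fraction"].item() == pytest.approx(0.10)


class TestBackgroundFilter:
    def _with_background(self, sample_fracs, bg_frac):
        rows = []
        for pep, frac in sample_fracs.items():
            rows.append(("P1", pep, "t", 1, 1, frac * 100, (1 - frac) * 100))
            rows.append(("P1", pep, "NL", 1, 1, bg_frac * 100,
                         (1 - bg_frac) * 100))
        return _table(rows)

    def test_kept_and_removed(self):
        table = self._with_background({"hi": 0.012, "lo": 0.008}, 0.003)
        out = quant.background_filter(table, "NL", factor=3.0)
        assert set(out["peptide"]) == {"hi"}

    def test_zero_background_kept(self):
        table = self._with_background({"a": 0.01}, 0.0)
        out = quant.background_filter(table, "NL", factor=3.0)
        assert set(out["peptide"]) == {"a"}

    def test_factor_zero_is_identity(self):
        table = self._with_background({"a": 0.004, "b": 0.001}, 0.003)
        out = quant.background_filter(table, "NL", factor=0.0)
        assert set(out["peptide"]) == {"a", "b"}

    def test_monotone_in_factor(self):
        table = self._with_background(
            {f"p{i}": 0.002 * (i + 1) for i in range(8)}, 0.003)
        survivors = [
            set(quant.background_filter(table, "NL", factor=f)["peptide"])
            for f in (0.0, 1.0, 2.0, 3.0, 5.0)
        ]
        for bigger, smaller in zip(survivors, survivors[1:]):
            assert smaller <= bigger

    def test_peptide_without_background_kept(self):
        table = self._with_background({"a": 0.01}, 0.003)
        extra = _table([("P1", "orphan", "t", 1, 1, 1.0, 99.0)])
        out = quant.background_filter(pd.concat([table, extra]), "NL")
        assert "orphan" in set(out["peptide"])

    def test_absent_condition_rejected(self, small_table):
        with pytest.raises(ValueError):
            quant.background_filter(small_table, "NL")


class TestProteinRollup:
    @pytest.mark.parametrize("fracs,expected", [
        ((0.1, 0.2, 0.4), 0.2), ((0.1, 0.3), 0.2), ((0.42,), 0.42),
    ])
    def test_median(self, fracs, expected):
        rows = [("P", f"p{i}", "t", 1, 1, f * 100, (1 - f) * 100)
                for i, f in enumerate(fracs)]
        out = quant.protein_rollup(quant.merge_technical(_table(rows)))
        assert out["heavy_fraction"].item() == pytest.approx(expected)
        assert out["n_peptides"].item() == len(fracs)

    def test_permutation_invariant(self, rng):
        rows = [("P", f"p{i}", "t", 1, 1, v, 100 - v)
                for i, v in enumerate(rng.uniform(1, 99, 9))]
        base = _table(rows)
        shuffled = base.sample(frac=1, random_state=1)
        a = quant.protein_rollup(quant.merge_technical(base))
        b = quant.protein_rollup(quant.merge_technical(shuffled))
        assert a["heavy_fraction"].item() == pytest.approx(
            b["heavy_fraction"].item())


class TestProteinFoldchange:
    def _two_condition(self, fcs):
        rows = []
        for i, fc in enumerate(fcs):
            base = 0.10
            rows.append(("P", f"p{i}", "c", 1, 1, base * 100,
                         (1 - base) * 100))
            rows.append(("P", f"p{i}", "t", 1, 1, base * fc * 100,
                         (1 - base * fc) * 100))
        return _table(rows)

    def test_median_of_peptide_fcs(self):
        out = quant.protein_foldchange(
            self._two_condition([0.5, 0.6, 1.4]), "t", "c")
        assert out["fold_change"].item() == pytest.approx(0.6)

    def test_identity_on_equal_conditions(self, small_table):
        both = pd.concat([
            small_table.assign(condition="c"),
            small_table.assign(condition="t"),
        ])
        out = quant.protein_foldchange(both, "t", "c")
        assert np.allclose(out["fold_change"], 1.0)

    def test_zero_control_peptide_skipped(self):
        df = _table([
            ("P", "a", "c", 1, 1, 0.0, 100.0),
            ("P", "a", "t", 1, 1, 10.0, 90.0),
            ("P", "b", "c", 1, 1, 10.0, 90.0),
            ("P", "b", "t", 1, 1, 20.0, 80.0),
        ])
        out = quant.protein_foldchange(df, "t", "c")
        assert out["n_peptides"].item() == 1

    def test_swapped_conditions_reciprocal_for_odd_counts(self):
        table = self._two_condition([0.5, 0.8, 1.6])
        fwd = quant.protein_foldchange(table, "t", "c")["fold_change"].item()
        rev = quant.protein_foldchange(table, "c", "t")["fold_change"].item()
        assert fwd * rev == pytest.approx(1.0)

    def test_missing_condition_rejected(self, small_table):
        with pytest.raises(ValueError):
            quant.protein_foldchange(small_table, "t", "nope")


class TestTotalIntensityFoldchange:
    def test_uniform_halving(self):
        rows = []
        for i in range(3):
            rows.append(("P", f"p{i}", "c", 1, 1, 40.0, 60.0))
            rows.append(("P", f"p{i}", "t", 1, 1, 20.0, 30.0))
        out = quant.total_intensity_foldchange(_table(rows), "t", "c")
        assert out["fold_change"].item() == pytest.approx(0.5)

    def test_median_combination(self):
        rows = []
        for i, fc in enumerate([0.2, 0.4, 0.9]):
            rows.append(("P", f"p{i}", "c", 1, 1, 50.0, 50.0))
            rows.append(("P", f"p{i}", "t", 1, 1, 50.0 * fc, 50.0 * fc))
        out = quant.total_intensity_foldchange(_table(rows), "t", "c")
        assert out["fold_change"].item() == pytest.approx(0.4)


class TestPolysomeFraction:
    def test_known_ratio(self):
        x = np.linspace(0, 10, 1001)
        y = np.where(x < 4, 1.0, np.where(x >= 6, 3.0, 0.0))
        frac = quant.polysome_fraction(x, y, (0, 4), (6, 10))
        # areas: monosome 1*4, polysome 3*4
        assert frac == pytest.approx(0.75, abs=1e-3)

    def test_flat_zero_polysome(self):
        x = np.linspace(0, 10, 101)
        y = np.where(x < 4, 1.0, 0.0)
        assert quant.polysome_fraction(x, y, (0, 4), (6, 10)) == 0.0

    def test_two_gaussian_trace(self):
        # well-separated Gaussians of known area: ratio is analytic
        x = np.linspace(0, 40, 8001)
        mono = 2.0 * np.exp(-0.5 * ((x - 10) / 1.0) ** 2)
        poly = 1.5 * np.exp(-0.5 * ((x - 30) / 2.0) ** 2)
        a_mono = 2.0 * 1.0 * math.sqrt(2 * math.pi)
        a_poly = 1.5 * 2.0 * math.sqrt(2 * math.pi)
        frac = quant.polysome_fraction(x, mono + poly, (0, 20), (20, 40))
        assert frac == pytest.approx(a_poly / (a_mono + a_poly), abs=1e-3)

    def test_zero_area_rejected(self):
        x = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            quant.polysome_fraction(x, np.zeros_like(x), (0, 4), (6, 10))

    def test_overlapping_regions_rejected(self):
        x = np.linspace(0, 10, 11)
        with pytest.raises(ValueError):
            quant.polysome_fraction(x, np.ones_like(x), (0, 5), (4, 10))


class TestQpcrRelative:
    @pytest.mark.parametrize("ddct,expected", [(0, 1.0), (-1, 2.0),
                                               (2, 0.25)])
    def test_ddct(self, ddct, expected):
        # build Ct values realizing the requested ddCt
        val = quant.qpcr_relative(20.0 + ddct, 15.0, 20.0, 15.0)
        assert val == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            quant.qpcr_relative(float("nan"), 15.0, 20.0, 15.0)
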