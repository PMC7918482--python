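"""Acetylation-site aggregation, ratio estimation, and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from acetylfq.acetylome import (
    ID,
    ND,
    TABLE_PRESET_THRESHOLD,
    acetylated_protein_proportion,
    build_site_table,
    classify_highly_acetylated,
    collapse_oxidation_variants,
    estimate_acetylation_ratio,
    multi_site_summary,
    site_phase_status,
)
from acetylfq.quant import QUANTIFIED

COLS = ["peptide", "protein", "start", "mods", "area", "xcorr", "qvalue",
        "phase", "replicate", "fraction", "contaminant"]


def kac_row(peptide="AMRIKAK", protein="P1", start=10, mods=frozenset({(5, "acetyl")}),
            area=100.0, phase="exponential", replicate=1):
    return [peptide, protein, start, mods, area, 3.0, 0.001, phase, replicate, "kac_eluate", False]


def frame(rows):
    return pd.DataFrame(rows, columns=COLS)


class TestCollapse:
    def test_oxidation_variants_summed(self):
        rows = [
            kac_row(mods=frozenset({(5, "acetyl")}), area=100.0),
            kac_row(mods=frozenset({(5, "acetyl"), (2, "oxidation")}), area=50.0),
        ]
        out = collapse_oxidation_variants(frame(rows))
        assert len(out) == 1
        assert out["area"].iloc[0] == 150.0

    def test_different_acetyl_positions_stay_distinct(self):
        rows = [
            kac_row(mods=frozenset({(5, "acetyl")})),
            kac_row(mods=frozenset({(7, "acetyl")})),
        ]
        out = collapse_oxidation_variants(frame(rows))
        assert len(out) == 2

    def test_area_conserved_per_sample(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(60):
            mods = frozenset({(5, "acetyl")} | ({(2, "oxidation")} if i % 2 else set()))
            rows.append(kac_row(mods=mods, area=float(rng.uniform(1, 100)),
                                replicate=1 + i % 3))
        df = frame(rows)
        out = collapse_oxidation_variants(df)
        for rep in (1, 2, 3):
            total_in = df.loc[df["replicate"] == rep, "area"].sum()
            total_out = out.loc[out["replicate"] == rep, "area"].sum()
            assert total_out == pytest.approx(total_in, rel=1e-12)

    def test_collapse_idempotent(self):
        rows = [kac_row(area=10.0), kac_row(mods=frozenset({(5, "acetyl"), (2, "oxidation")}), area=5.0)]
        once = collapse_oxidation_variants(frame(rows))
        again = (
            once.groupby(["protein", "peptide", "acetyl_positions", "phase", "replicate"])["area"]
            .sum()
            .reset_index()
        )
        assert np.allclose(sorted(once["area"]), sorted(again["area"]))


class TestRatio:
    def test_subtraction(self):
        assert estimate_acetylation_ratio(2.0, 3.0) == -1.0

    def test_equal_areas(self):
        assert estimate_acetylation_ratio(4.2, 4.2) == 0.0

    def test_linear_interpretation(self):
        # ratio 0.84 -> ~7-fold acetyl peptide over protein
        assert round(10 ** 0.84) == 7

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_pure_subtraction_no_hidden_normalization(self, a, b):
        # inverts up to one rounding step: plain a - b, nothing else
        assert estimate_acetylation_ratio(a, b) + b == pytest.approx(a, abs=1e-12)


class TestSiteStatus:
    @pytest.mark.parametrize(
        "present,expected",
        [((True, True, False), QUANTIFIED), ((True, False, False), ID), ((False, False, False), ND)],
    )
    def test_rule(self, present, expected):
        assert site_phase_status(present, 3) == expected


def _site_table(collapsed_rows, protein_abund=None):
    collapsed = collapse_oxidation_variants(frame(collapsed_rows))
    if protein_abund is None:
        protein_abund = pd.DataFrame(
            {"exponential": [3.0], "stationary": [3.0]}, index=pd.Index(["P1"], name="protein")
        )
    return build_site_table(collapsed, protein_abund)


class TestSiteTable:
    def test_quantified_site_gets_ratio(self):
        rows = [kac_row(area=100.0, replicate=r) for r in (1, 2)]
        sites = _site_table(rows)
        assert sites["status_exponential"].iloc[0] == QUANTIFIED
        assert sites["ratio_exponential"].iloc[0] == pytest.approx(2.0 - 3.0)
        assert sites["site_spec"].iloc[0] == "K14"  # start 10 + pos 5 - 1

    def test_single_replicate_is_identified_without_ratio(self):
        sites = _site_table([kac_row(replicate=1)])
        assert sites["status_exponential"].iloc[0] == ID
        assert np.isnan(sites["ratio_exponential"].iloc[0])

    def test_protein_not_quantified_blocks_ratio(self):
        abund = pd.DataFrame(
            {"exponential": [np.nan], "stationary": [np.nan]}, index=pd.Index(["P1"], name="protein")
        )
        rows = [kac_row(replicate=r) for r in (1, 2)]
        sites = _site_table(rows, abund)
        assert sites["status_exponential"].iloc[0] == QUANTIFIED
        assert np.isnan(sites["ratio_exponential"].iloc[0])

    def test_zero_area_detected_but_ratio_missing(self):
        rows = [kac_row(area=0.0, replicate=r) for r in (1, 2)]
        sites = _site_table(rows)
        assert sites["status_exponential"].iloc[0] == QUANTIFIED
        assert np.isnan(sites["ratio_exponential"].iloc[0])

    def test_replicate_matched_mode(self):
        cols = pd.MultiIndex.from_tuples(
            [("exponential", 1), ("exponential", 2), ("stationary", 1), ("stationary", 2)],
            names=["phase", "replicate"],
        )
        rep_abund = pd.DataFrame([[3.0, 4.0, np.nan, np.nan]], index=pd.Index(["P1"], name="protein"), columns=cols)
        collapsed = collapse_oxidation_variants(
            frame([kac_row(area=100.0, replicate=1), kac_row(area=1000.0, replicate=2)])
        )
        phase_abund = pd.DataFrame(
            {"exponential": [3.5], "stationary": [np.nan]}, index=pd.Index(["P1"], name="protein")
        )
        sites = build_site_table(collapsed, phase_abund, n_replicates=2,
                                 protein_replicate_abundance=rep_abund)
        # mean of (2-3) and (3-4) = -1
        assert sites["ratio_exponential"].iloc[0] == pytest.approx(-1.0)


class TestHighlyAcetylated:
    def _sites(self, ratios):
        return pd.DataFrame(
            {
                "protein": [f"P{i}" for i in range(len(ratios))],
                "peptide": ["AAAK"] * len(ratios),
                "site_spec": ["K5"] * len(ratios),
                "site_positions": [(5,)] * len(ratios),
                "status_exponential": [QUANTIFIED] * len(ratios),
                "log10_area_exponential": [1.0] * len(ratios),
                "ratio_exponential": ratios,
                "status_stationary": [ND] * len(ratios),
                "log10_area_stationary": [np.nan] * len(ratios),
                "ratio_stationary": [np.nan] * len(ratios),
            }
        )

    def test_text_threshold(self):
        sites = self._sites([0.84, -1.02, np.nan])
        kept = classify_highly_acetylated(sites, threshold=-1.0)
        assert list(kept["ratio_exponential"]) == [0.84]

    def test_table_preset_includes_borderline(self):
        sites = self._sites([0.84, -1.02])
        kept = classify_highly_acetylated(sites, threshold=TABLE_PRESET_THRESHOLD)
        assert list(kept["ratio_exponential"]) == [0.84, -1.02]

    def test_missing_ratio_excluded(self):
        sites = self._sites([np.nan])
        assert len(classify_highly_acetylated(sites)) == 0


class TestProportionAndCounts:
    def _status(self, proteins, phase_status_value="quantified"):
        return pd.DataFrame(
            {"exponential": [phase_status_value] * len(proteins),
             "stationary": [phase_status_value] * len(proteins)},
            index=pd.Index(proteins, name="protein"),
        )

    def _sites(self, rows):
        return pd.DataFrame(
            rows,
            columns=["protein", "peptide", "site_spec", "site_positions",
                     "status_exponential", "log10_area_exponential", "ratio_exponential",
                     "status_stationary", "log10_area_stationary", "ratio_stationary"],
        )

    def test_basic_fraction(self):
        status = self._status([f"P{i}" for i in range(200)])
        rows = [
            [f"P{i}", "AAAK", "K5", (5,), ID, np.nan, np.nan, ND, np.nan, np.nan]
            for i in range(10)
        ]
        assert acetylated_protein_proportion(status, self._sites(rows), "exponential") == 0.05

    def test_no_sites(self):
        status = self._status(["P1", "P2"])
        assert acetylated_protein_proportion(status, self._sites([]), "exponential") == 0.0

    def test_nterm_only_site_not_counted(self):
        status = self._status(["P1", "P2"])
        rows = [["P1", "MAAK", "protein-N-term", ("protein-N-term",), ID, np.nan, np.nan,
                 ND, np.nan, np.nan]]
        assert acetylated_protein_proportion(status, self._sites(rows), "exponential") == 0.0

    def test_multi_site_summary_counts(self):
        rows = [
            ["P1", "AAAK", "K10", (10,), QUANTIFIED, 1.0, -1.0, ND, np.nan, np.nan],
            ["P1", "CCCK", "K116", (116,), QUANTIFIED, 1.0, -1.0, QUANTIFIED, 1.0, -1.0],
            ["P1", "DDDK", "K121", (121,), ID, np.nan, np.nan, ND, np.nan, np.nan],
            ["P2", "EEEK", "K66", (66,), QUANTIFIED, 1.0, -1.0, ND, np.nan, np.nan],
            ["P2", "FFFK", "K19", (19,), ID, np.nan, np.nan, ND, np.nan, np.nan],
        ]
        out = multi_site_summary(self._sites(rows))
        assert out.loc["P1", "n_detected"] == 3 and out.loc["P1", "n_quantifiable"] == 2
        assert out.loc["P2", "n_detected"] == 2 and out.loc["P2", "n_quantifiable"] == 1
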