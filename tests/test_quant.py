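"""Protein quantification: filters, top-3 roll-up, normalization, tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from acetylfq.io import PsmRecord, ValidationError
from acetylfq.quant import (
    ABSENT,
    IDENTIFIED,
    QUANTIFIED,
    bh_adjust,
    filter_psms,
    normalize_abundances,
    phase_fold_changes,
    phase_status,
    protein_abundance_table,
    quantification_status,
    top3_abundance,
)


def _rec(q, xcorr, contaminant=False):
    return PsmRecord(
        peptide_sequence="PEPTIDEK",
        protein_id="cRAP_X" if contaminant else "P1",
        ms1_area=1.0,
        xcorr=xcorr,
        q_value=q,
        phase="exponential",
        replicate=1,
        fraction="proteome",
        is_contaminant=contaminant,
    )


class TestFilter:
    def test_passing_record_kept(self):
        assert len(filter_psms([_rec(0.005, 2.5)])) == 1

    def test_high_q_removed(self):
        assert filter_psms([_rec(0.02, 3.0)]) == []

    def test_boundary_xcorr_removed(self):
        # the cutoff is strictly greater-than
        assert filter_psms([_rec(0.001, 2.0)]) == []

    def test_boundary_q_removed(self):
        assert filter_psms([_rec(0.01, 3.0)]) == []

    def test_contaminant_removed(self):
        assert filter_psms([_rec(0.001, 3.0, contaminant=True)]) == []


class TestTop3:
    def test_mean_of_three_largest(self):
        assert top3_abundance([10, 20, 30, 40]) == 30

    def test_two_peptides_average_available(self):
        assert top3_abundance([10, 20]) == 15

    def test_single_peptide(self):
        assert top3_abundance([7]) == 7

    def test_strict_mode_needs_three(self):
        assert np.isnan(top3_abundance([10, 20], strict=True))

    def test_empty_is_missing(self):
        assert np.isnan(top3_abundance([]))

    def test_matches_sort_and_mean_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(1, 12))
            areas = rng.uniform(0, 1e6, n)
            expected = float(np.mean(np.sort(areas)[::-1][:3]))
            assert top3_abundance(areas) == pytest.approx(expected, rel=1e-12)


class TestStatus:
    @pytest.mark.parametrize(
        "present,expected",
        [
            ((True, True, False), QUANTIFIED),
            ((True, True, True), QUANTIFIED),
            ((True, False, False), IDENTIFIED),
            ((False, False, False), ABSENT),
        ],
    )
    def test_three_replicates(self, present, expected):
        assert quantification_status(present, 3) == expected

    def test_exactly_half_is_not_quantified(self):
        assert quantification_status((True, False), 2) == IDENTIFIED


def _wide(data, phases=("exponential",)):
    cols = pd.MultiIndex.from_tuples(
        [(p, r + 1) for p in phases for r in range(len(next(iter(data.values()))) // len(phases))],
        names=["phase", "replicate"],
    )
    return pd.DataFrame.from_dict(data, orient="index", columns=cols)


class TestNormalization:
    def test_single_sample(self):
        wide = _wide({"a": [1.0], "b": [2.0], "c": [3.0]})
        norm, info = normalize_abundances(wide)
        assert list(norm.iloc[:, 0]) == [0.0, 1.0, 2.0]
        assert info.global_shift == 1.0

    def test_two_samples_hand_check(self):
        # medians 2 and 4; centered A=[-1,1], B=[-2,2]; global min -2
        wide = _wide({"a": [1.0, 2.0], "b": [3.0, 6.0]}, phases=("exponential", "stationary"))
        norm, _ = normalize_abundances(wide)
        assert list(norm.loc["a"]) == [1.0, 0.0]
        assert list(norm.loc["b"]) == [3.0, 4.0]

    def test_constant_sample_centers_to_zero_before_shift(self):
        wide = _wide({"a": [5.0], "b": [5.0], "c": [5.0]})
        norm, info = normalize_abundances(wide)
        assert norm.iloc[:, 0].nunique() == 1
        assert info.sample_medians.iloc[0] == 5.0

    def test_global_min_zero_and_common_median(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.normal(3, 0.6, size=(50, 6)))
        raw.columns = pd.MultiIndex.from_tuples(
            [(p, r) for p in ("exponential", "stationary") for r in (1, 2, 3)],
            names=["phase", "replicate"],
        )
        raw.iloc[rng.random(raw.shape) < 0.1] = np.nan  # missing stays missing
        norm, info = normalize_abundances(raw)
        assert np.nanmin(norm.to_numpy()) == 0.0
        medians = norm.median(axis=0, skipna=True)
        assert np.allclose(medians, info.global_shift)
        assert raw.isna().equals(norm.isna())

    def test_invariant_to_per_sample_rescaling(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.normal(3, 0.6, size=(40, 4)))
        raw.columns = pd.MultiIndex.from_tuples(
            [("exponential", 1), ("exponential", 2), ("stationary", 1), ("stationary", 2)],
            names=["phase", "replicate"],
        )
        norm1, _ = normalize_abundances(raw)
        scaled = raw.copy()
        scaled.iloc[:, 0] += 1.0  # one sample's linear areas × 10
        norm2, _ = normalize_abundances(scaled)
        assert np.allclose(norm1.to_numpy(), norm2.to_numpy())

    def test_empty_sample_rejected(self):
        wide = _wide({"a": [1.0, np.nan], "b": [2.0, np.nan]}, phases=("exponential", "stationary"))
        with pytest.raises(ValidationError, match="stationary"):
            normalize_abundances(wide)


class TestAbundanceTable:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["peptide", "protein", "start", "mods", "area", "xcorr", "qvalue",
                     "phase", "replicate", "fraction", "contaminant"],
        )

    def test_psm_to_peptide_sum_then_top3(self):
        rows = [
            # two PSMs of the same peptide sum to 30; three more peptides
            ["AAAK", "P1", None, frozenset(), 10.0, 3.0, 0.001, "exponential", 1, "proteome", False],
            ["AAAK", "P1", None, frozenset(), 20.0, 3.0, 0.001, "exponential", 1, "proteome", False],
            ["CCCK", "P1", None, frozenset(), 40.0, 3.0, 0.001, "exponential", 1, "proteome", False],
            ["DDDK", "P1", None, frozenset(), 50.0, 3.0, 0.001, "exponential", 1, "proteome", False],
            ["EEEK", "P1", None, frozenset(), 1.0, 3.0, 0.001, "exponential", 1, "proteome", False],
        ]
        wide = protein_abundance_table(self._frame(rows), samples=[("exponential", 1)])
        assert wide.loc["P1", ("exponential", 1)] == pytest.approx(np.log10((30 + 40 + 50) / 3))

    def test_shared_peptides_dropped(self):
        rows = [
            ["AAAK", "P1", None, frozenset(), 10.0, 3.0, 0.001, "exponential", 1, "proteome", False],
            ["AAAK", "P2", None, frozenset(), 10.0, 3.0, 0.001, "exponential", 1, "proteome", False],
            ["CCCK", "P1", None, frozenset(), 40.0, 3.0, 0.001, "exponential", 1, "proteome", False],
        ]
        wide = protein_abundance_table(self._frame(rows), samples=[("exponential", 1)])
        assert list(wide.index) == ["P1"]
        assert wide.loc["P1", ("exponential", 1)] == pytest.approx(np.log10(40))


class TestFoldChanges:
    def _norm(self, a, b):
        cols = pd.MultiIndex.from_tuples(
            [("exponential", r) for r in (1, 2, 3)] + [("stationary", r) for r in (1, 2, 3)],
            names=["phase", "replicate"],
        )
        return pd.DataFrame([list(a) + list(b)], index=["P1"], columns=cols)

    def test_identical_groups(self):
        res = phase_fold_changes(self._norm([1, 2, 3], [1, 2, 3]))
        assert res.loc["P1", "t"] == 0.0 and res.loc["P1", "p"] == 1.0

    def test_known_t_statistic(self):
        # pooled-variance t for [1,2,3] vs [4,5,6]: |t| = 3.674, df = 4
        res = phase_fold_changes(self._norm([1, 2, 3], [4, 5, 6]))
        t = res.loc["P1", "t"]
        assert round(abs(t), 3) == 3.674
        # closed-form oracle: sp^2 = 1, se = sqrt(2/3)
        t_oracle = 3.0 / np.sqrt(2.0 / 3.0)
        p_oracle = 2 * stats.t.sf(t_oracle, df=4)
        assert res.loc["P1", "p"] == pytest.approx(p_oracle, rel=1e-9)
        assert res.loc["P1", "p"] == pytest.approx(0.0214, abs=5e-4)
        assert res.loc["P1", "log10_fc"] == pytest.approx(3.0)
        assert res.loc["P1", "log2_fc"] == pytest.approx(3.0 * np.log2(10))

    def test_single_replicate_phase_untestable(self):
        cols = pd.MultiIndex.from_tuples(
            [("exponential", r) for r in (1, 2, 3)] + [("stationary", r) for r in (1, 2, 3)],
            names=["phase", "replicate"],
        )
        norm = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, np.nan, np.nan]], index=["P1"], columns=cols)
        res = phase_fold_changes(norm)
        assert not res.loc["P1", "tested"]
        assert np.isnan(res.loc["P1", "p"])


def bh_reference(p):
    """Independent BH step-up: p(i) * m / i with a running minimum from the top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for back, idx in enumerate(order[::-1]):
        rank = m - back
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


class TestBenjaminiHochberg:
    def test_stepup_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            p = rng.uniform(0, 1, int(rng.integers(1, 40)))
            assert np.allclose(bh_adjust(p), bh_reference(p), atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_never_below_rank_scaled_p(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


def test_phase_status_table():
    cols = pd.MultiIndex.from_tuples(
        [("exponential", r) for r in (1, 2, 3)] + [("stationary", r) for r in (1, 2, 3)],
        names=["phase", "replicate"],
    )
    wide = pd.DataFrame(
        [[1.0, 2.0, np.nan, np.nan, np.nan, np.nan], [1.0, np.nan, np.nan, 1.0, 2.0, 3.0]],
        index=["P1", "P2"],
        columns=cols,
    )
    status = phase_status(wide)
    assert status.loc["P1", "exponential"] == QUANTIFIED
    assert status.loc["P1", "stationary"] == ABSENT
    assert status.loc["P2", "exponential"] == IDENTIFIED
    assert status.loc["P2", "stationary"] == QUANTIFIED
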