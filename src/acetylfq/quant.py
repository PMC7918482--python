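"""Protein-level label-free quantification from filtered PSM tables.

The quantification scheme:

1. keep PSMs with Percolator q-value < 0.01 and Sequest XCorr > 2.0 (both
   strict), after dropping contaminant-flagged rows;
2. roll PSM areas up to peptides (summing PSMs of the same peptide sequence
   within a sample), then to proteins as the arithmetic mean of the three
   largest peptide MS1 areas per sample (top-3; with fewer than three
   peptides the available ones are averaged);
3. log10-transform, median-centre each sample, and add one global constant
   so the minimum over the whole dataset is exactly zero;
4. call a protein *quantified* in a phase when it has a value in strictly
   more than 50 % of that phase's replicates (two of three), *identified*
   when present in at least one, *absent* otherwise;
5. compare phases per protein with two-tailed homoscedastic t-tests on the
   normalized replicate values and adjust p-values with Benjamini–Hochberg
   across all tested proteins.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PsmRecord, ValidationError, psms_to_frame

__all__ = [
    "QUANTIFIED",
    "IDENTIFIED",
    "ABSENT",
    "filter_psms",
    "top3_abundance",
    "quantification_status",
    "protein_abundance_table",
    "phase_status",
    "NormalizationInfo",
    "normalize_abundances",
    "bh_adjust",
    "phase_fold_changes",
]

log = logging.getLogger(__name__)

QUANTIFIED = "quantified"
IDENTIFIED = "identified"
ABSENT = "absent"

LOG2_10 = math.log2(10.0)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return psms_to_frame(records)


def filter_psms(records, q_max: float = 0.01, xcorr_min: float = 2.0):
    """Keep PSMs passing the identification filters.

    A PSM survives iff ``q_value < q_max`` and ``xcorr > xcorr_min`` (both
    comparisons strict) and it is not contaminant-flagged.  Accepts either a
    list of :class:`~acetylfq.io.PsmRecord` or a PSM frame; returns the same
    kind.  Emits a count summary to the module logger.
    """
    if isinstance(records, pd.DataFrame):
        keep = (records["qvalue"] < q_max) & (records["xcorr"] > xcorr_min) & (~records["contaminant"])
        out = records.loc[keep].reset_index(drop=True)
        log.info(
            "filter_psms: kept %d of %d PSMs (q<%g, xcorr>%g, %d contaminant-flagged)",
            len(out), len(records), q_max, xcorr_min, int(records["contaminant"].sum()),
        )
        return out
    kept = [
        r
        for r in records
        if r.q_value < q_max and r.xcorr > xcorr_min and not r.is_contaminant
    ]
    log.info("filter_psms: kept %d of %d PSMs (q<%g, xcorr>%g)", len(kept), len(records), q_max, xcorr_min)
    return kept


def top3_abundance(peptide_areas, strict: bool = False) -> float:
    """Mean of the three largest peptide-level MS1 areas (linear scale).

    With fewer than three peptides, the available ones are averaged unless
    ``strict`` is set, in which case the result is missing (NaN).  An empty
    input yields NaN (the protein contributes "absent" to that sample).
    """
    areas = sorted((float(a) for a in peptide_areas), reverse=True)
    if not areas or (strict and len(areas) < 3):
        return float("nan")
    top = areas[:3]
    return sum(top) / len(top)


def quantification_status(present, n_replicates: int | None = None) -> str:
    """Phase-level status from per-replicate presence flags.

    ``quantified`` iff present in strictly more than half the replicates,
    ``identified`` for at least one but not more than half, ``absent`` for
    none.
    """
    present = [bool(p) for p in present]
    n = n_replicates if n_replicates is not None else len(present)
    if n < 1:
        raise ValidationError("n_replicates must be >= 1")
    k = sum(present)
    if k / n > 0.5:
        return QUANTIFIED
    if k >= 1:
        return IDENTIFIED
    return ABSENT


def protein_abundance_table(
    psm_frame: pd.DataFrame,
    strict_top3: bool = False,
    drop_shared_peptides: bool = True,
    samples: list[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Per-protein, per-sample log10 raw abundances from filtered PSMs.

    Returns a wide frame indexed by protein with a (phase, replicate)
    column MultiIndex; missing values are NaN.  Peptide areas are PSM-area
    sums per (protein, peptide, sample); peptide sequences assigned to more
    than one protein across the table are dropped before roll-up
    (unique-peptide rule) and logged.
    """
    df = psm_frame
    if drop_shared_peptides and len(df):
        n_prot = df.groupby("peptide")["protein"].nunique()
        shared = set(n_prot.index[n_prot > 1])
        if shared:
            log.info("dropping %d peptide sequences shared between proteins", len(shared))
            df = df[~df["peptide"].isin(shared)]
    if samples is None:
        samples = sorted(
            {(p, int(r)) for p, r in zip(psm_frame["phase"], psm_frame["replicate"])}
        )
    cols = pd.MultiIndex.from_tuples(samples, names=["phase", "replicate"])
    if not len(df):
        return pd.DataFrame(index=pd.Index([], name="protein"), columns=cols, dtype=float)

    pep = (
        df.groupby(["protein", "phase", "replicate", "peptide"], sort=True)["area"]
        .sum()
        .reset_index()
    )
    prot = (
        pep.groupby(["protein", "phase", "replicate"])["area"]
        .apply(lambda a: top3_abundance(a, strict=strict_top3))
        .reset_index(name="abundance")
    )
    prot = prot[prot["abundance"] > 0]
    prot["log10"] = np.log10(prot["abundance"])
    wide = prot.pivot_table(index="protein", columns=["phase", "replicate"], values="log10")
    wide = wide.reindex(columns=cols)
    wide.index.name = "protein"
    return wide


def phase_status(abundances: pd.DataFrame, phases=None) -> pd.DataFrame:
    """Quantification status per protein and phase from the wide table."""
    if phases is None:
        phases = list(dict.fromkeys(abundances.columns.get_level_values("phase")))
    out = {}
    for phase in phases:
        block = abundances.xs(phase, axis=1, level="phase")
        n = block.shape[1]
        out[phase] = block.notna().apply(lambda row: quantification_status(row, n), axis=1)
    res = pd.DataFrame(out)
    res.index.name = "protein"
    return res


@dataclass(frozen=True)
class NormalizationInfo:
    """Bookkeeping from :func:`normalize_abundances`.

    ``sample_medians`` maps each sample column to the median subtracted from
    it; ``global_shift`` is the constant added afterwards so the dataset
    minimum is zero.  After normalization every sample's median equals
    ``global_shift``, and a ratio computed against normalized protein
    abundances carries the dataset-wide offset ``sample_median −
    global_shift`` relative to one computed against raw abundances.
    """

    sample_medians: pd.Series
    global_shift: float


def normalize_abundances(abundances: pd.DataFrame) -> tuple[pd.DataFrame, NormalizationInfo]:
    """Median-centre each sample and shift so the global minimum is zero.

    Operates on log10 values.  Each sample's median is computed over the
    proteins present in that sample; missing values stay missing.  A sample
    with no present values is an error.
    """
    medians = abundances.median(axis=0, skipna=True)
    empty = [c for c in abundances.columns if abundances[c].notna().sum() == 0]
    if empty:
        raise ValidationError(f"sample(s) with no present values: {empty}")
    centered = abundances.sub(medians, axis=1)
    shift = -float(np.nanmin(centered.to_numpy()))
    return centered + shift, NormalizationInfo(sample_medians=medians, global_shift=shift)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaNs pass through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def phase_fold_changes(
    norm: pd.DataFrame,
    status: pd.DataFrame | None = None,
    phase_a: str = "exponential",
    phase_b: str = "stationary",
) -> pd.DataFrame:
    """Per-protein phase comparison on normalized log10 abundances.

    Reports the difference of replicate means (``phase_b − phase_a``) in
    log10 and log2 units, a two-tailed homoscedastic Student's t-test
    (df = nA + nB − 2) for proteins quantified in both phases with at least
    two present values per phase, and BH-adjusted p-values over all tested
    proteins jointly.  Proteins failing the testability rule are reported
    with missing p and ``tested == False``.
    """
    if status is None:
        status = phase_status(norm, [phase_a, phase_b])
    a = norm.xs(phase_a, axis=1, level="phase")
    b = norm.xs(phase_b, axis=1, level="phase")
    rows = []
    for protein in norm.index:
        va = a.loc[protein].dropna().to_numpy(dtype=float)
        vb = b.loc[protein].dropna().to_numpy(dtype=float)
        mean_a = va.mean() if va.size else np.nan
        mean_b = vb.mean() if vb.size else np.nan
        log10_fc = mean_b - mean_a if va.size and vb.size else np.nan
        testable = (
            status.loc[protein, phase_a] == QUANTIFIED
            and status.loc[protein, phase_b] == QUANTIFIED
            and va.size >= 2
            and vb.size >= 2
        )
        t = p = np.nan
        if testable:
            with warnings.catch_warnings():
                # near-identical replicate values trip a harmless precision
                # warning inside the moment calculation
                warnings.simplefilter("ignore", RuntimeWarning)
                t, p = stats.ttest_ind(vb, va, equal_var=True)
            t, p = float(t), float(p)
            if np.isnan(p) and np.allclose(va, va.mean()) and np.allclose(vb, vb.mean()) and np.isclose(va.mean(), vb.mean()):
                t, p = 0.0, 1.0  # identical constant groups: no evidence of change
        rows.append(
            {
                "protein": protein,
                "mean_" + phase_a: mean_a,
                "mean_" + phase_b: mean_b,
                "log10_fc": log10_fc,
                "log2_fc": log10_fc * LOG2_10 if not np.isnan(log10_fc) else np.nan,
                "t": t,
                "p": p,
                "tested": bool(testable),
            }
        )
    res = pd.DataFrame(rows).set_index("protein")
    res["p_adj"] = bh_adjust(res["p"].to_numpy())
    return res
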