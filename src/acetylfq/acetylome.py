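"""Acetylation-site aggregation and stoichiometry-ratio estimation.

Peptides from the anti-acetyl-lysine (Kac) enrichment eluate are grouped
into acetylation sites: observations of the same peptide with the same set
of acetylated positions that differ only in methionine-oxidation (or static
carbamidomethyl) status are summed and counted as one site.  Each site's
log10 summed MS1 area is then compared with the median-normalized log10
abundance of its parent protein measured in the total proteome:

    estimated ratio = log10(site area, Kac eluate)
                      − normalized log10(protein abundance, proteome)

On a linear scale 10^ratio is the acetylated-peptide signal as a fraction of
the protein signal, so a ratio of −1 means the acetylated peptide carried
10 % of the protein's MS1 signal — the working proxy for site stoichiometry.

Per-phase site status mirrors the protein rule: *quantified* when the site
was seen in more than half the replicates, *id.* when seen in exactly one,
*n.d.* when never seen.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .digest import PROTEIN_NTERM, TrypticPeptide, map_mod_to_protein
from .io import NTERM, ValidationError
from .quant import QUANTIFIED

__all__ = [
    "ND",
    "ID",
    "site_spec_label",
    "collapse_oxidation_variants",
    "site_phase_status",
    "estimate_acetylation_ratio",
    "build_site_table",
    "classify_highly_acetylated",
    "acetylated_protein_proportion",
    "multi_site_summary",
    "HIGH_RATIO_THRESHOLD",
    "TABLE_PRESET_THRESHOLD",
]

log = logging.getLogger(__name__)

ND = "n.d."
ID = "id."

#: default cutoff: acetyl-peptide signal at least 10 % of the protein signal
HIGH_RATIO_THRESHOLD = -1.0
#: slightly laxer preset used for tabular reporting
TABLE_PRESET_THRESHOLD = -1.1


def _acetyl_positions(mods) -> tuple:
    """Sorted within-peptide acetyl positions (N-term token sorts first)."""
    pos = [p for p, kind in mods if kind == "acetyl"]
    return tuple(sorted(pos, key=lambda x: (-1, "") if x == NTERM else (x, "")))


def site_spec_label(protein_positions) -> str:
    """Render candidate protein positions as a site label.

    Residue positions become ``K<pos>`` (acetyl-lysine), the protein
    N-terminus ``protein-N-term``, and an acetylated N-terminus of an
    internal peptide ``Nt<pos>``.  Multiple positions join with ``|``.
    """
    parts = []
    for p in protein_positions:
        if p == PROTEIN_NTERM:
            parts.append(PROTEIN_NTERM)
        elif isinstance(p, tuple) and p[0] == "pep-nterm":
            parts.append(f"Nt{p[1]}")
        else:
            parts.append(f"K{p}")
    return "|".join(parts)


def collapse_oxidation_variants(kac_frame: pd.DataFrame) -> pd.DataFrame:
    """Sum MS1 areas of Kac peptides differing only in oxidation status.

    Grouping key: (protein, peptide sequence, set of acetyl positions,
    phase, replicate).  Input rows must carry at least one acetyl
    modification; rows without one are ignored with a log message.  Returns
    a long frame with one row per site × sample and the summed linear area;
    log10 is taken downstream, after summing.
    """
    df = kac_frame
    has_ac = df["mods"].apply(lambda m: any(k == "acetyl" for _, k in m))
    n_drop = int((~has_ac).sum())
    if n_drop:
        log.info("collapse_oxidation_variants: ignoring %d Kac rows without acetyl marks", n_drop)
    df = df[has_ac].copy()
    if not len(df):
        return pd.DataFrame(
            columns=["protein", "peptide", "start", "acetyl_positions", "phase", "replicate", "area"]
        )
    df["acetyl_positions"] = df["mods"].apply(_acetyl_positions)
    grouped = (
        df.groupby(["protein", "peptide", "acetyl_positions", "phase", "replicate"], sort=True)
        .agg(area=("area", "sum"), start=("start", "first"))
        .reset_index()
    )
    return grouped[["protein", "peptide", "start", "acetyl_positions", "phase", "replicate", "area"]]


def site_phase_status(present, n_replicates: int | None = None) -> str:
    """Site status in one phase: quantified (> 50 % of replicates), id. (one), n.d. (none)."""
    present = [bool(p) for p in present]
    n = n_replicates if n_replicates is not None else len(present)
    if n < 1:
        raise ValidationError("n_replicates must be >= 1")
    k = sum(present)
    if k / n > 0.5:
        return QUANTIFIED
    if k >= 1:
        return ID
    return ND


def estimate_acetylation_ratio(site_log10_area: float, protein_log10_norm: float) -> float:
    """log10 acetylation abundance ratio: site area minus protein abundance.

    Pure subtraction — 10^ratio is the acetylated-peptide MS1 signal as a
    fraction of the parent protein's signal.  Either operand missing yields
    a missing ratio.
    """
    if site_log10_area is None or protein_log10_norm is None:
        return float("nan")
    return float(site_log10_area) - float(protein_log10_norm)


def _protein_positions(peptide: str, start, acetyl_positions) -> tuple:
    """Map within-peptide acetyl positions to protein coordinates."""
    if start is None or (isinstance(start, float) and math.isnan(start)):
        return tuple(("unmapped", p) for p in acetyl_positions)
    tp = TrypticPeptide(protein_id="", start=int(start), end=int(start) + len(peptide) - 1,
                        sequence=peptide, missed_cleavages=0)
    out = []
    for p in acetyl_positions:
        mapped = map_mod_to_protein(tp, p)
        if p == NTERM and mapped != PROTEIN_NTERM:
            out.append(("pep-nterm", mapped))
        else:
            out.append(mapped)
    return tuple(out)


def build_site_table(
    collapsed: pd.DataFrame,
    protein_phase_abundance: pd.DataFrame,
    phases=("exponential", "stationary"),
    n_replicates: int = 3,
    protein_replicate_abundance: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Aggregate collapsed site × sample areas into a per-site phase table.

    Parameters
    ----------
    collapsed : output of :func:`collapse_oxidation_variants`.
    protein_phase_abundance : frame indexed by protein with one column per
        phase holding the normalized log10 phase-mean abundance for proteins
        quantified in that phase (NaN otherwise).
    protein_replicate_abundance : optional wide frame (protein ×
        (phase, replicate) normalized log10 values) switching the ratio to
        replicate-matched mode: each replicate's site area is compared with
        the same replicate's protein abundance and the per-replicate ratios
        averaged; the default compares against the phase-mean abundance.

    Returns one row per site with, for each phase, ``status_<phase>``,
    ``log10_area_<phase>`` (mean of per-replicate log10 summed areas over
    replicates where the site was seen, reported when quantified) and
    ``ratio_<phase>`` (present only when the site is quantified and the
    parent protein has a phase-level abundance).  Zero-area observations
    count as detections but contribute no log area.
    """
    cols_out = ["protein", "peptide", "site_spec", "site_positions"]
    rows = []
    if len(collapsed):
        for (protein, peptide, acpos), grp in collapsed.groupby(
            ["protein", "peptide", "acetyl_positions"], sort=True
        ):
            start = grp["start"].iloc[0]
            positions = _protein_positions(peptide, start, acpos)
            row = {
                "protein": protein,
                "peptide": peptide,
                "site_spec": site_spec_label(positions),
                "site_positions": positions,
            }
            for phase in phases:
                sub = grp[grp["phase"] == phase]
                present = sub["replicate"].nunique()
                status = site_phase_status([True] * present + [False] * (n_replicates - present), n_replicates)
                row[f"status_{phase}"] = status
                la = np.nan
                ratio = np.nan
                pos_sub = sub[sub["area"] > 0]
                areas = pos_sub["area"].to_numpy(dtype=float)
                if status == QUANTIFIED and areas.size:
                    la = float(np.mean(np.log10(areas)))
                    if protein_replicate_abundance is not None:
                        # replicate-matched mode: pair each replicate's site
                        # area with that replicate's protein abundance
                        ratios = []
                        for rep, a in zip(pos_sub["replicate"], areas):
                            try:
                                pv = protein_replicate_abundance.loc[protein, (phase, rep)]
                            except KeyError:
                                continue
                            if not np.isnan(pv):
                                ratios.append(math.log10(a) - float(pv))
                        if ratios:
                            ratio = float(np.mean(ratios))
                    else:
                        pab = np.nan
                        if protein in protein_phase_abundance.index and phase in protein_phase_abundance.columns:
                            pab = protein_phase_abundance.loc[protein, phase]
                        if not np.isnan(pab):
                            ratio = estimate_acetylation_ratio(la, float(pab))
                row[f"log10_area_{phase}"] = la
                row[f"ratio_{phase}"] = ratio
            rows.append(row)
    for phase in phases:
        cols_out += [f"status_{phase}", f"log10_area_{phase}", f"ratio_{phase}"]
    return pd.DataFrame(rows, columns=cols_out)


def classify_highly_acetylated(
    sites: pd.DataFrame, threshold: float = HIGH_RATIO_THRESHOLD, phases=("exponential", "stationary")
) -> pd.DataFrame:
    """Sites whose best per-phase ratio is at or above ``threshold``.

    The default −1.0 selects sites whose acetyl-peptide signal reaches 10 %
    of the protein signal; the −1.1 table preset is available via
    ``threshold=TABLE_PRESET_THRESHOLD``.  Missing ratios never qualify.
    """
    ratio_cols = [f"ratio_{p}" for p in phases]
    if not len(sites):
        return sites.copy()
    best = sites[ratio_cols].max(axis=1, skipna=True)
    return sites[best >= threshold].copy()


def _has_lysine_site(positions) -> bool:
    return any(
        not (p == PROTEIN_NTERM or (isinstance(p, tuple) and p[0] in ("pep-nterm", "unmapped")))
        for p in positions
    )


def acetylated_protein_proportion(
    proteome_status: pd.DataFrame, sites: pd.DataFrame, phase: str
) -> float:
    """Fraction of detected proteins carrying ≥ 1 acetyl-lysine in a phase.

    Numerator: proteins with at least one lysine-position site detected in
    at least one replicate of the phase (status not ``n.d.``); sites whose
    only positions are N-terminal are excluded, since the quantity concerns
    acetylated lysines.  Denominator: proteins identified or quantified in
    the phase's total proteome.
    """
    detected = proteome_status.index[proteome_status[phase] != "absent"]
    if len(detected) == 0:
        raise ValidationError(f"no proteins detected in phase {phase!r}")
    if not len(sites):
        return 0.0
    seen = sites[(sites[f"status_{phase}"] != ND) & sites["site_positions"].apply(_has_lysine_site)]
    acetylated = set(seen["protein"]) & set(detected)
    return len(acetylated) / len(detected)


def multi_site_summary(sites: pd.DataFrame, phases=("exponential", "stationary")) -> pd.DataFrame:
    """Per-protein counts of detected and quantifiable acetylation sites.

    A site counts as detected when seen in at least one replicate of either
    phase, and as quantifiable when quantified in at least one phase.
    Proteins without sites do not appear.
    """
    if not len(sites):
        return pd.DataFrame(columns=["protein", "n_detected", "n_quantifiable"]).set_index("protein")
    status_cols = [f"status_{p}" for p in phases]
    detected = sites[status_cols].apply(lambda r: any(s != ND for s in r), axis=1)
    quantifiable = sites[status_cols].apply(lambda r: any(s == QUANTIFIED for s in r), axis=1)
    df = pd.DataFrame(
        {"protein": sites["protein"], "detected": detected, "quantifiable": quantifiable}
    )
    out = df.groupby("protein").agg(
        n_detected=("detected", "sum"), n_quantifiable=("quantifiable", "sum")
    )
    out = out[out["n_detected"] > 0]
    return out.astype(int)
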