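"""Pathway coverage of the proteome and acetylome across growth phases.

Coverage of a pathway is the fraction of its genome-encoded proteins that
were detected in a sample set: quantified proteins for the proteome layer,
proteins with at least one acetylation site seen in at least one replicate
for the acetylome layer.  Phase comparison uses log2 fold changes of
coverage with one asymmetric convention: for the acetylome layer a pathway
with zero exponential-phase coverage reports a fold change of 0 (nothing to
compare against), whereas the proteome layer reports it as missing.

Significance comes from two-tailed homoscedastic t-tests on per-replicate
coverages (the detected set evaluated separately for each replicate), with
the usual star encoding (* p < 0.05, ** p < 0.01, *** p < 0.001, strict).
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PathwayAnnotation, ValidationError

__all__ = [
    "UNASSIGNED",
    "pathway_coverage",
    "coverage_log2fc",
    "significance_stars",
    "coverage_significance",
    "pathway_phase_comparison",
]

#: reserved row for proteins the annotation tool did not assign to a pathway
UNASSIGNED = "No pathway assigned"


def _genome_map(annotations: Iterable[PathwayAnnotation]) -> dict[str, frozenset[str]]:
    return {a.protein_id: a.pathway_ids for a in annotations}


def _pathway_universe(genome: Mapping[str, frozenset[str]]) -> dict[str, set[str]]:
    """pathway → set of genome proteins; unassigned proteins pooled under UNASSIGNED."""
    universe: dict[str, set[str]] = {}
    for pid, pws in genome.items():
        targets = pws if pws else {UNASSIGNED}
        for pw in targets:
            universe.setdefault(pw, set()).add(pid)
    return universe


def pathway_coverage(
    annotations: Iterable[PathwayAnnotation],
    detected_ids: Iterable[str],
    layer: str = "proteome",
) -> pd.DataFrame:
    """Per-pathway detection counts and coverage for one detected set.

    The denominator is genome-wide (every annotated protein); a protein in
    several pathways counts once in each.  Detected proteins missing from
    the annotation table are an error listing the offending IDs.
    """
    genome = _genome_map(annotations)
    detected = set(detected_ids)
    unknown = sorted(detected - genome.keys())
    if unknown:
        raise ValidationError(f"detected proteins missing from annotation table: {unknown}")
    universe = _pathway_universe(genome)
    rows = []
    for pw in sorted(universe):
        members = universe[pw]
        n_cov = len(members & detected)
        rows.append(
            {
                "pathway": pw,
                "layer": layer,
                "n_genome": len(members),
                "n_covered": n_cov,
                "coverage": n_cov / len(members),
            }
        )
    return pd.DataFrame(rows)


def coverage_log2fc(coverage_exp: float, coverage_stat: float, layer: str = "proteome") -> float:
    """log2(stationary / exponential) coverage with the zero conventions.

    Zero exponential coverage maps to 0 for the acetylome layer and to
    missing for the proteome layer; both zero is always missing.
    """
    if coverage_exp == 0 and coverage_stat == 0:
        return float("nan")
    if coverage_exp == 0:
        return 0.0 if layer == "acetylome" else float("nan")
    if coverage_stat == 0:
        return float("-inf")
    return math.log2(coverage_stat / coverage_exp)


def significance_stars(p: float) -> str:
    """Strict, nested star encoding: *** < 0.001 ⊂ ** < 0.01 ⊂ * < 0.05."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def coverage_significance(cov_exp: Sequence[float], cov_stat: Sequence[float]):
    """Two-tailed homoscedastic t-test on per-replicate coverages.

    Returns ``(p, stars, degenerate)``.  Two identical constant groups give
    p = 1 (no evidence).  Constant groups at different values have zero
    pooled variance; rather than fabricate a finite p we report p = 0.0 with
    ``degenerate=True``.
    """
    a = np.asarray(cov_exp, dtype=float)
    b = np.asarray(cov_stat, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 1.0, "", False
        return 0.0, "***", True
    with warnings.catch_warnings():
        # near-constant replicate coverages are routine here; the precision
        # warning from the moment calculation is expected and harmless
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(b, a, equal_var=True)
    p = float(p)
    return p, significance_stars(p), False


def pathway_phase_comparison(
    annotations: Iterable[PathwayAnnotation],
    detected_by_sample: Mapping[tuple[str, int], Iterable[str]],
    layer: str = "proteome",
    phase_a: str = "exponential",
    phase_b: str = "stationary",
    detected_by_phase: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Full per-pathway phase comparison table.

    ``detected_by_sample`` maps (phase, replicate) to that replicate's
    detected protein set and feeds the t-test (per-replicate coverages).
    Phase-level coverage uses ``detected_by_phase`` when given — for the
    proteome layer this is the set of *quantified* proteins, which is not
    the union of replicate detections — and otherwise falls back to the
    union of the phase's replicate sets.
    """
    samples_a = [k for k in detected_by_sample if k[0] == phase_a]
    samples_b = [k for k in detected_by_sample if k[0] == phase_b]
    if detected_by_phase is not None:
        union_a = set(detected_by_phase.get(phase_a, ()))
        union_b = set(detected_by_phase.get(phase_b, ()))
    else:
        union_a = set().union(*(set(detected_by_sample[k]) for k in samples_a)) if samples_a else set()
        union_b = set().union(*(set(detected_by_sample[k]) for k in samples_b)) if samples_b else set()

    cov_a = pathway_coverage(annotations, union_a, layer).set_index("pathway")
    cov_b = pathway_coverage(annotations, union_b, layer).set_index("pathway")
    rep_cov_a = [
        pathway_coverage(annotations, detected_by_sample[k], layer).set_index("pathway")["coverage"]
        for k in sorted(samples_a)
    ]
    rep_cov_b = [
        pathway_coverage(annotations, detected_by_sample[k], layer).set_index("pathway")["coverage"]
        for k in sorted(samples_b)
    ]

    rows = []
    for pw in cov_a.index:
        ce, cs = float(cov_a.loc[pw, "coverage"]), float(cov_b.loc[pw, "coverage"])
        p, stars, degenerate = coverage_significance(
            [rc[pw] for rc in rep_cov_a], [rc[pw] for rc in rep_cov_b]
        )
        rows.append(
            {
                "pathway": pw,
                "layer": layer,
                "n_genome": int(cov_a.loc[pw, "n_genome"]),
                "n_covered_exp": int(cov_a.loc[pw, "n_covered"]),
                "n_covered_stat": int(cov_b.loc[pw, "n_covered"]),
                "coverage_exp": ce,
                "coverage_stat": cs,
                "log2fc": coverage_log2fc(ce, cs, layer),
                "p_value": p,
                "stars": stars,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
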