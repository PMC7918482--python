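"""End-to-end orchestration: PSM tables in, quantification reports out.

Stages: read & validate inputs → identification filters → top-3 protein
quantification and normalization → phase status and fold changes →
acetylation-site aggregation and ratio estimation → pathway coverage →
summary report.  Every number in the summary is recomputable from the
emitted stage tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import acetylome as ac
from . import io as afio
from . import pathways as pw
from . import quant

__all__ = ["RunConfig", "PipelineResult", "StageError", "run_pipeline", "render_report"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the documented thresholds."""

    proteome_psms: str | None = None
    kac_psms: str | None = None
    fasta: str | None = None
    pathway_table: str | None = None
    out_dir: str | None = None
    q_max: float = 0.01
    xcorr_min: float = 2.0
    high_ratio_threshold: float = ac.HIGH_RATIO_THRESHOLD
    phases: tuple[str, str] = ("exponential", "stationary")
    n_replicates: int = 3
    strict_top3: bool = False
    drop_shared_peptides: bool = True
    normalize: bool = True
    replicate_matched_ratio: bool = False
    contaminant_prefix: str = afio.DEFAULT_CONTAMINANT_PREFIX
    bh_adjust_pathways: bool = False

    def validate(self) -> "RunConfig":
        if len(self.phases) != 2:
            raise afio.ValidationError("exactly two phases are required")
        if not (0 < self.q_max <= 1):
            raise afio.ValidationError("q_max must be in (0, 1]")
        if self.n_replicates < 1:
            raise afio.ValidationError("n_replicates must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise afio.ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "phases" in raw:
            raw["phases"] = tuple(raw["phases"])
        return cls(**raw).validate()


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: RunConfig
    abundances: pd.DataFrame  # protein × (phase, replicate) log10 raw
    normalized: pd.DataFrame
    norm_info: quant.NormalizationInfo | None
    status: pd.DataFrame  # protein × phase
    fold_changes: pd.DataFrame
    sites: pd.DataFrame
    highly_acetylated: pd.DataFrame
    multi_site: pd.DataFrame
    pathway_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summary: dict[str, Any] = field(default_factory=dict)
    output_paths: list[Path] = field(default_factory=list)


def _detected_sets(psm_frame: pd.DataFrame, status: pd.DataFrame, phases, n_replicates):
    """Per-replicate detected proteins and phase-level quantified proteins."""
    by_sample = {}
    for phase in phases:
        for rep in range(1, n_replicates + 1):
            sub = psm_frame[(psm_frame["phase"] == phase) & (psm_frame["replicate"] == rep)]
            by_sample[(phase, rep)] = set(sub["protein"])
    by_phase = {
        phase: set(status.index[status[phase] == quant.QUANTIFIED]) for phase in phases
    }
    return by_sample, by_phase


def _acetylome_sets(collapsed: pd.DataFrame, sites: pd.DataFrame, phases, n_replicates):
    by_sample = {}
    for phase in phases:
        for rep in range(1, n_replicates + 1):
            sub = collapsed[(collapsed["phase"] == phase) & (collapsed["replicate"] == rep)]
            by_sample[(phase, rep)] = set(sub["protein"])
    by_phase = {
        phase: set(sites.loc[sites[f"status_{phase}"] != ac.ND, "protein"]) for phase in phases
    }
    return by_sample, by_phase


def run_pipeline(
    config: RunConfig,
    proteome_psms: list[afio.PsmRecord] | None = None,
    kac_psms: list[afio.PsmRecord] | None = None,
    annotations: list[afio.PathwayAnnotation] | None = None,
) -> PipelineResult:
    """Run every stage; inputs may be passed in memory or read from the
    paths in ``config``.  On failure, any partially written output files
    are removed and a :class:`StageError` names the failing stage.
    """
    cfg = config.validate()
    written: list[Path] = []
    try:
        result = _run(cfg, proteome_psms, kac_psms, annotations, written)
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
    return result


def _run(cfg, proteome_psms, kac_psms, annotations, written) -> PipelineResult:
    phases = list(cfg.phases)

    # ---- stage: input ----
    try:
        sequences = dict(afio.read_fasta(cfg.fasta)) if cfg.fasta else None
        if proteome_psms is None:
            if cfg.proteome_psms is None:
                raise afio.ValidationError("no proteome PSM input given")
            proteome_psms = afio.read_psm_table(
                cfg.proteome_psms, contaminant_prefix=cfg.contaminant_prefix, sequences=sequences
            )
        if kac_psms is None and cfg.kac_psms:
            kac_psms = afio.read_psm_table(
                cfg.kac_psms, contaminant_prefix=cfg.contaminant_prefix, sequences=sequences
            )
        kac_psms = kac_psms or []
        if annotations is None and cfg.pathway_table:
            annotations = afio.read_pathway_table(cfg.pathway_table)
    except afio.ValidationError as exc:
        raise StageError("input", str(exc)) from exc

    log.info("inputs: %d proteome PSMs, %d Kac PSMs", len(proteome_psms), len(kac_psms))

    # ---- stage: filter ----
    prot_frame = quant.filter_psms(afio.psms_to_frame(proteome_psms), cfg.q_max, cfg.xcorr_min)
    kac_frame = quant.filter_psms(afio.psms_to_frame(kac_psms), cfg.q_max, cfg.xcorr_min)

    # ---- stage: protein quantification ----
    try:
        samples = [(p, r) for p in phases for r in range(1, cfg.n_replicates + 1)]
        abundances = quant.protein_abundance_table(
            prot_frame,
            strict_top3=cfg.strict_top3,
            drop_shared_peptides=cfg.drop_shared_peptides,
            samples=samples,
        )
        if not len(abundances):
            raise afio.ValidationError("no quantifiable proteins after filtering")
        status = quant.phase_status(abundances, phases)
        if cfg.normalize:
            normalized, norm_info = quant.normalize_abundances(abundances)
        else:
            normalized, norm_info = abundances.copy(), None
        fold_changes = quant.phase_fold_changes(normalized, status, phases[0], phases[1])
    except afio.ValidationError as exc:
        raise StageError("protein_quant", str(exc)) from exc

    # normalized phase means, reported only for quantified proteins
    phase_means = {}
    for phase in phases:
        block = normalized.xs(phase, axis=1, level="phase")
        means = block.mean(axis=1, skipna=True)
        means[status[phase] != quant.QUANTIFIED] = np.nan
        phase_means[phase] = means
    protein_phase_abundance = pd.DataFrame(phase_means)

    # ---- stage: acetylome ----
    try:
        collapsed = ac.collapse_oxidation_variants(kac_frame) if len(kac_frame) else pd.DataFrame(
            columns=["protein", "peptide", "start", "acetyl_positions", "phase", "replicate", "area"]
        )
        sites = ac.build_site_table(
            collapsed,
            protein_phase_abundance,
            phases=phases,
            n_replicates=cfg.n_replicates,
            protein_replicate_abundance=normalized if cfg.replicate_matched_ratio else None,
        )
        high = ac.classify_highly_acetylated(sites, cfg.high_ratio_threshold, phases)
        multi = ac.multi_site_summary(sites, phases)
        proportions = {}
        for phase in phases:
            try:
                proportions[phase] = ac.acetylated_protein_proportion(status, sites, phase)
            except afio.ValidationError:
                proportions[phase] = float("nan")
    except afio.ValidationError as exc:
        raise StageError("acetylome", str(exc)) from exc

    # ---- stage: pathways ----
    pathway_tables: dict[str, pd.DataFrame] = {}
    if annotations:
        try:
            by_sample, by_phase = _detected_sets(prot_frame, status, phases, cfg.n_replicates)
            pathway_tables["proteome"] = pw.pathway_phase_comparison(
                annotations, by_sample, "proteome", phases[0], phases[1], detected_by_phase=by_phase
            )
            kac_by_sample, kac_by_phase = _acetylome_sets(collapsed, sites, phases, cfg.n_replicates)
            pathway_tables["acetylome"] = pw.pathway_phase_comparison(
                annotations, kac_by_sample, "acetylome", phases[0], phases[1], detected_by_phase=kac_by_phase
            )
            if cfg.bh_adjust_pathways:
                for t in pathway_tables.values():
                    t["p_adj"] = quant.bh_adjust(t["p_value"].to_numpy())
        except afio.ValidationError as exc:
            raise StageError("pathways", str(exc)) from exc

    # ---- stage: summary ----
    summary: dict[str, Any] = {"thresholds": {
        "q_max": cfg.q_max, "xcorr_min": cfg.xcorr_min,
        "high_ratio_threshold": cfg.high_ratio_threshold,
    }}
    for phase in phases:
        counts = status[phase].value_counts()
        n_q = int(counts.get(quant.QUANTIFIED, 0))
        n_i = int(counts.get(quant.IDENTIFIED, 0))
        summary[phase] = {
            "proteins_quantified": n_q,
            "proteins_identified": n_i,
            "proteins_detected": n_q + n_i,
            "acetylated_protein_proportion": proportions.get(phase, float("nan")),
        }
    status_cols = [f"status_{p}" for p in phases]
    ratio_cols = [f"ratio_{p}" for p in phases]
    n_quantifiable = int(
        (sites[status_cols] == quant.QUANTIFIED).any(axis=1).sum() if len(sites) else 0
    )
    summary["acetylome"] = {
        "unique_acetylated_peptides": int(len(sites)),
        "quantifiable_acetylated_peptides": n_quantifiable,
        "acetylated_proteins": int(sites["protein"].nunique()) if len(sites) else 0,
        "highly_acetylated_sites": int(len(high)),
    }
    if len(sites):
        best = sites[ratio_cols].max(axis=1, skipna=True)
        if best.notna().any():
            summary["acetylome"]["top_site_ratio"] = float(best.max())

    result = PipelineResult(
        config=cfg,
        abundances=abundances,
        normalized=normalized,
        norm_info=norm_info,
        status=status,
        fold_changes=fold_changes,
        sites=sites,
        highly_acetylated=high,
        multi_site=multi,
        pathway_tables=pathway_tables,
        summary=summary,
    )

    if cfg.out_dir:
        _write_outputs(result, Path(cfg.out_dir), written)
        result.output_paths = list(written)
    return result


def _flatten_norm(result: PipelineResult) -> pd.DataFrame:
    """Protein table: one row per protein with per-sample normalized values,
    phase means, status, fold change and significance columns."""
    cfg = result.config
    out = result.normalized.copy()
    out.columns = [f"log10_norm_{p}_r{r}" for p, r in out.columns]
    for phase in cfg.phases:
        out[f"status_{phase}"] = result.status[phase]
    fc = result.fold_changes
    for col in ("log10_fc", "log2_fc", "t", "p", "p_adj", "tested"):
        out[col] = fc[col]
    return out


def _write_outputs(result: PipelineResult, out_dir: Path, written: list[Path]) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def emit(df: pd.DataFrame, name: str, index: bool) -> None:
        path = out_dir / name
        df.to_csv(path, sep="\t", index=index)
        written.append(path)

    emit(_flatten_norm(result), "protein_table.tsv", True)
    sites_out = result.sites.drop(columns=["site_positions"], errors="ignore")
    emit(sites_out, "sites.tsv", False)
    emit(
        result.highly_acetylated.drop(columns=["site_positions"], errors="ignore"),
        "highly_acetylated.tsv",
        False,
    )
    emit(result.multi_site, "multi_site.tsv", True)
    for layer, table in result.pathway_tables.items():
        emit(table, f"pathway_coverage_{layer}.tsv", False)
    spath = out_dir / "summary.json"
    with open(spath, "w") as fh:
        json.dump(result.summary, fh, indent=2, default=float)
    written.append(spath)
    rpath = out_dir / "report.md"
    rpath.write_text(render_report(result))
    written.append(rpath)


def _fold_line(ratio: float) -> str:
    fold = 10.0 ** ratio
    if ratio >= 0:
        return f"{fold:.1f}-fold the unmodified protein signal (10^{ratio:.2f})"
    return f"{fold * 100:.1f}% of protein signal (10^{ratio:.2f})"


def render_report(result: PipelineResult) -> str:
    """Human-readable markdown summary derived from the stage outputs."""
    cfg = result.config
    s = result.summary
    lines = ["# Proteome / acetylome quantification report", ""]
    lines.append("## Proteome")
    for phase in cfg.phases:
        ph = s[phase]
        lines.append(
            f"- {phase}: {ph['proteins_detected']} proteins detected "
            f"({ph['proteins_quantified']} quantified, {ph['proteins_identified']} identified)"
        )
    n_tested = int(result.fold_changes["tested"].sum())
    n_sig = int((result.fold_changes.loc[result.fold_changes["tested"], "p_adj"] < 0.05).sum())
    lines.append(f"- phase comparison: {n_tested} proteins tested, {n_sig} with BH-adjusted p < 0.05")
    lines.append("")
    lines.append("## Acetylome")
    a = s["acetylome"]
    lines.append(f"- {a['unique_acetylated_peptides']} unique acetylated peptides "
                 f"({a['quantifiable_acetylated_peptides']} quantifiable) on {a['acetylated_proteins']} proteins")
    for phase in cfg.phases:
        prop = s[phase]["acetylated_protein_proportion"]
        if not (isinstance(prop, float) and math.isnan(prop)):
            lines.append(f"- acetylated-protein proportion, {phase}: {prop * 100:.1f}%")
    if "top_site_ratio" in a:
        lines.append(
            f"- top site: estimated log10 acetylation abundance ratio {a['top_site_ratio']:.2f} "
            f"= {_fold_line(a['top_site_ratio'])}"
        )
    else:
        lines.append("- no quantified acetylation sites; ratio section omitted")
    if result.pathway_tables:
        lines.append("")
        lines.append("## Pathway coverage")
        for layer, table in result.pathway_tables.items():
            n_up = int((table["log2fc"] > 0).sum())
            lines.append(
                f"- {layer}: {len(table)} pathways, {n_up} with increased stationary-phase coverage"
            )
    lines.append("")
    return "\n".join(lines)
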