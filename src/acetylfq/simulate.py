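"""Ground-truth simulator for two-phase proteome/acetylome experiments.

The generator emulates the statistical structure of a label-free LC-MS/MS
study of a bacterium sampled in the exponential and stationary growth
phases, three biological replicates each, with a total-proteome fraction
and an anti-acetyl-lysine (Kac) enrichment fraction:

* protein log10 abundances are normal with mean 3.0 and sd 0.6 (the
  observed scale of median-normalized bacterial proteomes), with a subset
  of proteins receiving a phase effect;
* a configurable fraction of proteins carries acetylation sites on lysines
  (defaults: 5 % in the exponential and 11 % in the stationary phase, the
  stationary set containing the exponential one), each with a per-phase
  stoichiometry;
* every tryptic peptide (length ≥ 6) gets a fixed multiplicative response
  factor, and each observation multiplicative lognormal noise;
* Kac-eluate records carry the covering peptide's signal scaled by the
  site's stoichiometry and an enrichment gain; a fraction of acetyl
  peptides containing methionine is split into oxidized/unoxidized variant
  pairs (area-conserving);
* detection dropout removes records with a probability that falls
  logistically with log10 area, so low-abundance signals show replicate
  variability; and a fraction of contaminant records carries failing scores
  plus a cRAP-style accession prefix so the identification filters remove
  them.

Identical (config, seed) pairs produce byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as afio
from .digest import tryptic_digest
from .io import NTERM, PsmRecord, ValidationError

__all__ = ["SimulationConfig", "GroundTruth", "SimulatedExperiment", "build_truth", "simulate_experiment"]

AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # K and R handled separately

PHASE_EXP = "exponential"
PHASE_STAT = "stationary"


@dataclass(frozen=True)
class SimulationConfig:
    """Simulator parameters; defaults encode the emulated study design."""

    n_proteins: int = 1000
    n_replicates: int = 3
    seq_length_range: tuple[int, int] = (100, 600)
    kr_frequency: float = 0.11  # combined K+R frequency → tryptic peptides ~9 residues
    abundance_mean: float = 3.0  # log10 units
    abundance_sd: float = 0.6
    phase_effect_fraction: float = 0.2
    phase_effect_sd: float = 0.4  # log10 units
    acetyl_protein_fraction_exp: float = 0.05
    acetyl_protein_fraction_stat: float = 0.11
    sites_per_protein: tuple[int, int] = (1, 6)
    stoich_log10_range: tuple[float, float] = (-3.0, -0.5)
    noise_sd: float = 0.15  # log10 units, multiplicative lognormal on areas
    dropout_rate: float = 0.2
    response_factor_sd: float = 0.25  # log10 units, fixed per peptide
    enrichment_gain: float = 1.0
    oxidation_split_probability: float = 0.3
    contaminant_fraction: float = 0.05
    min_peptide_length: int = 6
    max_missed: int = 0  # digestion depth used for simulated observations
    n_pathways: int = 20
    unassigned_fraction: float = 0.36

    def validate(self) -> "SimulationConfig":
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValidationError("counts must be positive")
        for r in (
            self.acetyl_protein_fraction_exp,
            self.acetyl_protein_fraction_stat,
            self.dropout_rate,
            self.contaminant_fraction,
            self.oxidation_split_probability,
            self.unassigned_fraction,
        ):
            if not (0.0 <= r <= 1.0):
                raise ValidationError(f"rate {r} outside [0, 1]")
        if self.acetyl_protein_fraction_exp > self.acetyl_protein_fraction_stat:
            raise ValidationError("exponential acetylation prevalence cannot exceed stationary")
        if self.sites_per_protein[0] < 1 or self.sites_per_protein[0] > self.sites_per_protein[1]:
            raise ValidationError("invalid sites_per_protein range")
        if self.kr_frequency <= 0 or self.kr_frequency >= 1:
            raise ValidationError("kr_frequency must be in (0, 1)")
        return self

    def ideal(self) -> "SimulationConfig":
        """Noise-free variant: unit response factors and enrichment, no
        dropout, no contaminants, no oxidation splitting."""
        return replace(
            self,
            noise_sd=0.0,
            dropout_rate=0.0,
            response_factor_sd=0.0,
            enrichment_gain=1.0,
            oxidation_split_probability=0.0,
            contaminant_fraction=0.0,
        )


@dataclass
class GroundTruth:
    """Simulator truth: protein abundances, pathway assignments, acetyl sites.

    ``proteins`` columns: protein, sequence, pathways (``;``-joined),
    log10_exponential, log10_stationary.  ``sites`` columns: protein,
    position (1-based K residue), stoich_exponential, stoich_stationary
    (fractions in [0, 1]; 0 = site not acetylated in that phase).
    """

    proteins: pd.DataFrame
    sites: pd.DataFrame
    config: SimulationConfig
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.proteins.to_csv(out / "truth_proteins.tsv", sep="\t", index=False)
        self.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)


def _random_sequences(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    letters = list(AMINO_ACIDS) + ["K", "R"]
    p_other = (1.0 - cfg.kr_frequency) / len(AMINO_ACIDS)
    probs = [p_other] * len(AMINO_ACIDS) + [cfg.kr_frequency / 2] * 2
    lo, hi = cfg.seq_length_range
    seqs = []
    for _ in range(cfg.n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seqs.append("".join(rng.choice(letters, size=n, p=probs)))
    return seqs


def _eligible_lysines(sequence: str, cfg: SimulationConfig) -> list[int]:
    """K positions (1-based) covered by a detectable tryptic peptide."""
    peptides = tryptic_digest(sequence, max_missed=cfg.max_missed, min_length=cfg.min_peptide_length)
    covered = set()
    for p in peptides:
        for i in range(p.start, p.end + 1):
            if sequence[i - 1] == "K":
                covered.add(i)
    return sorted(covered)


def build_truth(config: SimulationConfig, seed: int) -> GroundTruth:
    """Draw a deterministic ground truth for the given configuration."""
    cfg = config.validate()
    rng = np.random.default_rng(seed)
    sequences = _random_sequences(cfg, rng)
    ids = [f"SYN{i:04d}" for i in range(cfg.n_proteins)]

    base = rng.normal(cfg.abundance_mean, cfg.abundance_sd, cfg.n_proteins)
    has_effect = rng.random(cfg.n_proteins) < cfg.phase_effect_fraction
    delta = rng.normal(0.0, cfg.phase_effect_sd, cfg.n_proteins) * has_effect
    log10_exp = base
    log10_stat = base + delta

    # pathway assignment: a protein belongs to one or two pathways, or none
    pw_ids = [f"map{j:02d}" for j in range(cfg.n_pathways)]
    pathways = []
    for _ in range(cfg.n_proteins):
        if cfg.n_pathways == 0 or rng.random() < cfg.unassigned_fraction:
            pathways.append("")
            continue
        k = 2 if (cfg.n_pathways > 1 and rng.random() < 0.3) else 1
        chosen = rng.choice(pw_ids, size=k, replace=False)
        pathways.append(";".join(sorted(chosen)))

    proteins = pd.DataFrame(
        {
            "protein": ids,
            "sequence": sequences,
            "pathways": pathways,
            "log10_exponential": log10_exp,
            "log10_stationary": log10_stat,
        }
    )

    n_stat = int(round(cfg.acetyl_protein_fraction_stat * cfg.n_proteins))
    n_exp = int(round(cfg.acetyl_protein_fraction_exp * cfg.n_proteins))
    eligible_by_idx = {i: _eligible_lysines(sequences[i], cfg) for i in range(cfg.n_proteins)}
    candidates = [i for i in range(cfg.n_proteins) if eligible_by_idx[i]]
    if n_stat > len(candidates):
        raise ValidationError(
            f"cannot place acetyl sites on {n_stat} proteins: only {len(candidates)} "
            "have a lysine on a detectable tryptic peptide"
        )
    stat_set = list(rng.choice(candidates, size=n_stat, replace=False)) if n_stat else []
    exp_set = set(rng.choice(stat_set, size=n_exp, replace=False)) if n_exp else set()

    lo_s, hi_s = cfg.stoich_log10_range
    site_rows = []
    for idx in stat_set:
        eligible = eligible_by_idx[idx]
        lo_n, hi_n = cfg.sites_per_protein
        n_sites = min(int(rng.integers(lo_n, hi_n + 1)), len(eligible))
        positions = sorted(rng.choice(eligible, size=n_sites, replace=False))
        for pos in positions:
            st_stat = 10.0 ** rng.uniform(lo_s, hi_s)
            st_exp = 10.0 ** rng.uniform(lo_s, hi_s) if idx in exp_set else 0.0
            site_rows.append(
                {
                    "protein": ids[idx],
                    "position": int(pos),
                    "stoich_exponential": st_exp,
                    "stoich_stationary": st_stat,
                }
            )
    sites = pd.DataFrame(
        site_rows, columns=["protein", "position", "stoich_exponential", "stoich_stationary"]
    )
    return GroundTruth(proteins=proteins, sites=sites, config=cfg, seed=int(seed))


@dataclass
class SimulatedExperiment:
    """One simulated two-phase experiment, ready for the pipeline."""

    fasta: list[tuple[str, str]]
    proteome_psms: list[PsmRecord]
    kac_psms: list[PsmRecord]
    annotations: list[afio.PathwayAnnotation]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "proteins.fasta",
            "proteome": out / "proteome_psms.tsv",
            "kac": out / "kac_psms.tsv",
            "pathways": out / "pathways.tsv",
        }
        afio.write_fasta(self.fasta, paths["fasta"])
        afio.write_psm_table(self.proteome_psms, paths["proteome"])
        afio.write_psm_table(self.kac_psms, paths["kac"])
        afio.write_pathway_table(self.annotations, paths["pathways"])
        self.truth.write(out)
        return paths


def _dropout_mask(areas: np.ndarray, rate: float, rng: np.random.Generator, scale: float = 0.35) -> np.ndarray:
    """True for records removed by detection dropout.

    Drop probability falls logistically with log10 area; the logistic is
    centred at the ``rate`` quantile of the table's own log10 areas, so the
    overall removal rate is close to ``rate`` while low-area records are
    removed preferentially.
    """
    if rate <= 0 or len(areas) == 0:
        return np.zeros(len(areas), dtype=bool)
    la = np.log10(np.maximum(areas, 1e-300))
    center = np.quantile(la, rate)
    p_drop = 1.0 / (1.0 + np.exp((la - center) / scale))
    return rng.random(len(areas)) < p_drop


def simulate_experiment(truth: GroundTruth, seed: int) -> SimulatedExperiment:
    """Generate PSM tables for every phase × replicate from a ground truth.

    Deterministic under a fixed (truth, seed).  Returns records in the
    canonical dialect ready to be written or fed directly to the pipeline.
    """
    cfg = truth.config
    rng = np.random.default_rng(seed)
    phases = (PHASE_EXP, PHASE_STAT)

    # fixed per-peptide response factors and site → covering-peptide mapping
    protein_peptides = []
    for _, prot in truth.proteins.iterrows():
        peps = tryptic_digest(
            prot["sequence"],
            max_missed=cfg.max_missed,
            protein_id=prot["protein"],
            min_length=cfg.min_peptide_length,
        )
        rf = rng.normal(0.0, cfg.response_factor_sd, len(peps)) if cfg.response_factor_sd > 0 else np.zeros(len(peps))
        protein_peptides.append((prot, peps, rf))

    site_map: dict[str, list] = {}
    for _, s in truth.sites.iterrows():
        site_map.setdefault(s["protein"], []).append(s)

    def passing_scores(n):
        return rng.uniform(2.1, 5.0, n), rng.uniform(0.0, 0.009, n)

    proteome: list[PsmRecord] = []
    kac: list[PsmRecord] = []
    for phase in phases:
        abcol = f"log10_{phase}"
        stcol = f"stoich_{phase}"
        for rep in range(1, cfg.n_replicates + 1):
            for prot, peps, rf in protein_peptides:
                if not peps:
                    continue
                noise = rng.normal(0.0, cfg.noise_sd, len(peps)) if cfg.noise_sd > 0 else np.zeros(len(peps))
                log_areas = prot[abcol] + rf + noise
                xc, qv = passing_scores(len(peps))
                for i, pep in enumerate(peps):
                    proteome.append(
                        PsmRecord(
                            peptide_sequence=pep.sequence,
                            protein_id=prot["protein"],
                            peptide_start=pep.start,
                            ms1_area=float(10.0 ** log_areas[i]),
                            xcorr=float(xc[i]),
                            q_value=float(qv[i]),
                            phase=phase,
                            replicate=rep,
                            fraction="proteome",
                        )
                    )
                for site in site_map.get(prot["protein"], ()):
                    stoich = float(site[stcol])
                    if stoich <= 0:
                        continue
                    pos = int(site["position"])
                    cover = [
                        (i, p) for i, p in enumerate(peps) if p.start <= pos <= p.end
                    ]
                    if not cover:
                        continue
                    i, pep = cover[0]
                    noise_k = rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
                    area = 10.0 ** (prot[abcol] + rf[i] + noise_k) * stoich * cfg.enrichment_gain
                    pos_in_pep = pos - pep.start + 1
                    ac_mods = frozenset({(pos_in_pep, "acetyl")})
                    xc1, qv1 = passing_scores(2)
                    m_idx = pep.sequence.find("M")
                    if m_idx >= 0 and cfg.oxidation_split_probability > 0 and rng.random() < cfg.oxidation_split_probability:
                        f = rng.uniform(0.2, 0.8)
                        ox_mods = ac_mods | {(m_idx + 1, "oxidation")}
                        parts = [(ac_mods, area * (1.0 - f)), (frozenset(ox_mods), area * f)]
                    else:
                        parts = [(ac_mods, area)]
                    for j, (mods, a) in enumerate(parts):
                        kac.append(
                            PsmRecord(
                                peptide_sequence=pep.sequence,
                                protein_id=prot["protein"],
                                peptide_start=pep.start,
                                modifications=mods,
                                ms1_area=float(a),
                                xcorr=float(xc1[j]),
                                q_value=float(qv1[j]),
                                phase=phase,
                                replicate=rep,
                                fraction="kac_eluate",
                            )
                        )

    # detection dropout, applied per table against its own area distribution
    if cfg.dropout_rate > 0:
        for records_name in ("proteome", "kac"):
            records = proteome if records_name == "proteome" else kac
            areas = np.array([r.ms1_area for r in records])
            drop = _dropout_mask(areas, cfg.dropout_rate, rng)
            kept = [r for r, d in zip(records, drop) if not d]
            if records_name == "proteome":
                proteome = kept
            else:
                kac = kept

    # contaminants: cRAP-prefixed accessions with failing filter scores
    n_cont = int(round(cfg.contaminant_fraction * len(proteome)))
    letters = list(AMINO_ACIDS + "KR")
    for i in range(n_cont):
        pep = "".join(rng.choice(letters, size=int(rng.integers(8, 16))))
        if rng.random() < 0.5:
            xc, qv = float(rng.uniform(2.1, 5.0)), float(rng.uniform(0.01, 0.5))
        else:
            xc, qv = float(rng.uniform(0.5, 2.0)), float(rng.uniform(0.0, 0.009))
        proteome.append(
            PsmRecord(
                peptide_sequence=pep,
                protein_id=f"cRAP_{i:03d}",
                peptide_start=None,
                ms1_area=float(10.0 ** rng.normal(2.0, 1.0)),
                xcorr=xc,
                q_value=qv,
                phase=phases[int(rng.integers(0, 2))],
                replicate=int(rng.integers(1, cfg.n_replicates + 1)),
                fraction="proteome",
                is_contaminant=True,
            )
        )

    fasta = list(zip(truth.proteins["protein"], truth.proteins["sequence"]))
    annotations = [
        afio.PathwayAnnotation(
            protein_id=pid, pathway_ids=frozenset(p for p in pw.split(";") if p)
        )
        for pid, pw in zip(truth.proteins["protein"], truth.proteins["pathways"])
    ]
    return SimulatedExperiment(
        fasta=fasta, proteome_psms=proteome, kac_psms=kac, annotations=annotations, truth=truth
    )
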