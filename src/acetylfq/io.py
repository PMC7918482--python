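"""Readers and writers for the files the pipeline consumes and emits.

The pipeline works from three kinds of external input:

* a protein sequence database in FASTA format,
* peptide-spectrum match (PSM) tables exported by a database search engine,
  one row per peptide-spectrum observation, for the total-proteome fraction
  and for the anti-acetyl-lysine (Kac) enrichment eluate,
* a pathway annotation table mapping protein IDs to functional pathways
  (KEGG-orthology style assignments consumed as a plain two-column table).

PSM tables use a documented canonical header (``peptide, protein, start,
mods, area, xcorr, qvalue, phase, replicate, fraction``); other exporter
layouts can be adapted through a column-name dialect mapping.  Modifications
are encoded as semicolon-joined tokens ``<residue><pos>(<kind>)`` with
1-based positions within the peptide, e.g. ``K5(acetyl);M2(oxidation)``, and
``N-term(acetyl)`` for an acetylated peptide N-terminus.

Readers validate every row; a reader never silently drops rows — every input
row is returned as a record (possibly contaminant-flagged) or reported as an
error, so ``n(records) + n(errors) == n(input rows)``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ValidationError",
    "PsmRecord",
    "PathwayAnnotation",
    "parse_mods",
    "format_mods",
    "read_fasta",
    "write_fasta",
    "read_psm_table",
    "write_psm_table",
    "read_pathway_table",
    "write_pathway_table",
    "psms_to_frame",
    "PHASES",
    "FRACTIONS",
    "NTERM",
    "CANONICAL_COLUMNS",
]

PHASES = ("exponential", "stationary")
FRACTIONS = ("proteome", "kac_eluate")

#: token used for a modification on the peptide N-terminus
NTERM = "N-term"

#: residue each modification kind is chemically restricted to
MOD_TARGETS = {"acetyl": "K", "oxidation": "M", "carbamidomethyl": "C"}

CANONICAL_COLUMNS = (
    "peptide",
    "protein",
    "start",
    "mods",
    "area",
    "xcorr",
    "qvalue",
    "phase",
    "replicate",
    "fraction",
)

DEFAULT_CONTAMINANT_PREFIX = "cRAP"


class ValidationError(ValueError):
    """Raised when an input file or record violates a documented invariant."""


_MOD_RE = re.compile(r"^([A-Z])(\d+)\((acetyl|oxidation|carbamidomethyl)\)$")
_NTERM_RE = re.compile(r"^N-term\((acetyl|oxidation|carbamidomethyl)\)$")


def parse_mods(text: str) -> frozenset[tuple[int | str, str]]:
    """Parse a modification string into a set of ``(position, kind)`` pairs.

    ``position`` is a 1-based index within the peptide, or the token
    ``"N-term"``.  An empty or whitespace-only string yields the empty set.
    """
    text = (text or "").strip()
    if not text:
        return frozenset()
    mods: set[tuple[int | str, str]] = set()
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        m = _NTERM_RE.match(token)
        if m:
            mods.add((NTERM, m.group(1)))
            continue
        m = _MOD_RE.match(token)
        if m is None:
            raise ValidationError(f"unparseable modification token {token!r}")
        mods.add((int(m.group(2)), m.group(3)))
    return frozenset(mods)


def format_mods(mods: Iterable[tuple[int | str, str]], peptide: str) -> str:
    """Render a modification set back into the canonical string form.

    The peptide sequence supplies the residue letter for each position.
    N-terminal tokens sort first; residue tokens sort by position.
    """

    def key(mod: tuple[int | str, str]):
        pos, kind = mod
        return (0, 0, kind) if pos == NTERM else (1, pos, kind)

    parts = []
    for pos, kind in sorted(mods, key=key):
        if pos == NTERM:
            parts.append(f"N-term({kind})")
        else:
            parts.append(f"{peptide[pos - 1]}{pos}({kind})")
    return ";".join(parts)


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum observation with its sample coordinates.

    Attributes
    ----------
    peptide_sequence : uppercase amino-acid string.
    protein_id : accession of the protein the search engine assigned.
    peptide_start : 1-based index of the peptide's first residue within the
        protein, or ``None`` when unknown.
    modifications : set of ``(position, kind)``; position is 1-based within
        the peptide or ``"N-term"``.
    ms1_area : integrated MS1 precursor peak area (arbitrary units, ≥ 0).
    xcorr : Sequest cross-correlation score.
    q_value : Percolator q-value (estimated FDR at acceptance), in [0, 1].
    phase : growth phase, ``"exponential"`` or ``"stationary"``.
    replicate : biological replicate number (≥ 1).
    fraction : ``"proteome"`` (total proteome) or ``"kac_eluate"``
        (anti-acetyl-lysine immunoaffinity eluate).
    is_contaminant : row matched the contaminant accession pattern and is
        flagged for exclusion by the PSM filter.
    """

    peptide_sequence: str
    protein_id: str
    ms1_area: float
    xcorr: float
    q_value: float
    phase: str
    replicate: int
    fraction: str
    peptide_start: int | None = None
    modifications: frozenset[tuple[int | str, str]] = field(default_factory=frozenset)
    is_contaminant: bool = False

    def validate(self) -> "PsmRecord":
        seq = self.peptide_sequence
        if not seq or not seq.isalpha() or seq != seq.upper():
            raise ValidationError(f"invalid peptide sequence {seq!r}")
        if not self.protein_id:
            raise ValidationError("empty protein_id")
        if not (self.ms1_area >= 0):
            raise ValidationError(f"negative MS1 area {self.ms1_area!r}")
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(f"q_value {self.q_value!r} outside [0, 1]")
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.fraction not in FRACTIONS:
            raise ValidationError(f"unknown fraction {self.fraction!r}")
        if self.replicate < 1:
            raise ValidationError(f"replicate {self.replicate!r} < 1")
        if self.peptide_start is not None and self.peptide_start < 1:
            raise ValidationError(f"peptide_start {self.peptide_start!r} < 1")
        for pos, kind in self.modifications:
            if kind not in MOD_TARGETS:
                raise ValidationError(f"unknown modification kind {kind!r}")
            if pos == NTERM:
                if kind != "acetyl":
                    raise ValidationError(f"N-terminal modification must be acetyl, got {kind!r}")
                continue
            if not (1 <= pos <= len(seq)):
                raise ValidationError(
                    f"modification position {pos} outside peptide of length {len(seq)}"
                )
            expected = MOD_TARGETS[kind]
            if seq[pos - 1] != expected:
                raise ValidationError(
                    f"{kind} at position {pos} requires {expected}, found {seq[pos - 1]}"
                )
        return self


@dataclass(frozen=True)
class PathwayAnnotation:
    """Pathway assignment for one protein; the set may be empty (unassigned)."""

    protein_id: str
    pathway_ids: frozenset[str] = field(default_factory=frozenset)
    genome_scope: bool = True


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a protein FASTA database into ``(protein_id, sequence)`` pairs.

    The ID is the first whitespace-delimited token of the header.  Sequences
    are uppercased and trailing ``*`` stop characters are stripped.  Duplicate
    IDs or empty sequences raise :class:`ValidationError` naming the record.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "")
        if not seq:
            raise ValidationError(f"FASTA record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA ID {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for pid, seq in entries:
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSM tables


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_psm_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    contaminant_prefix: str = DEFAULT_CONTAMINANT_PREFIX,
    sequences: Mapping[str, str] | None = None,
    errors: str = "raise",
) -> list[PsmRecord] | tuple[list[PsmRecord], list[str]]:
    """Read a delimited PSM table into validated :class:`PsmRecord` objects.

    Parameters
    ----------
    dialect : optional mapping from canonical column names to the names used
        in the file (for foreign exporter layouts).
    contaminant_prefix : rows whose protein ID starts with this prefix are
        returned with ``is_contaminant=True`` (flagged, not dropped), mirroring
        search-time exclusion against a contaminant (cRAP-style) database.
    sequences : optional protein_id → sequence mapping used to derive a
        missing ``start`` column by locating the peptide in its protein;
        ambiguous or absent matches are row errors.
    errors : ``"raise"`` aborts on the first bad row (message carries the
        1-based data row number); ``"collect"`` returns ``(records, errors)``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str, keep_default_na=False)
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        colmap.update(dialect)
    missing = [c for c in CANONICAL_COLUMNS if c != "start" and colmap[c] not in df.columns]
    if missing:
        raise ValidationError(f"PSM table {path} is missing required columns: {missing}")
    has_start = colmap["start"] in df.columns

    records: list[PsmRecord] = []
    row_errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            peptide = str(row[colmap["peptide"]]).strip().upper()
            protein = str(row[colmap["protein"]]).strip()
            start_txt = str(row[colmap["start"]]).strip() if has_start else ""
            start = int(start_txt) if start_txt else None
            if start is None and sequences is not None and protein in sequences:
                start = _locate_unique(sequences[protein], peptide)
            area = float(row[colmap["area"]])
            if area < 0:
                raise ValidationError(f"negative area {area}")
            rec = PsmRecord(
                peptide_sequence=peptide,
                protein_id=protein,
                peptide_start=start,
                modifications=parse_mods(str(row[colmap["mods"]])),
                ms1_area=area,
                xcorr=float(row[colmap["xcorr"]]),
                q_value=float(row[colmap["qvalue"]]),
                phase=str(row[colmap["phase"]]).strip(),
                replicate=int(row[colmap["replicate"]]),
                fraction=str(row[colmap["fraction"]]).strip(),
                is_contaminant=protein.startswith(contaminant_prefix),
            ).validate()
        except (ValidationError, ValueError) as exc:
            msg = f"row {i}: {exc}"
            if errors == "raise":
                raise ValidationError(msg) from None
            row_errors.append(msg)
            continue
        records.append(rec)
    if errors == "collect":
        return records, row_errors
    return records


def _locate_unique(protein_seq: str, peptide: str) -> int:
    first = protein_seq.find(peptide)
    if first < 0:
        raise ValidationError(f"peptide {peptide!r} not found in assigned protein")
    if protein_seq.find(peptide, first + 1) >= 0:
        raise ValidationError(f"peptide {peptide!r} occurs more than once in assigned protein")
    return first + 1


def _fmt_float(x: float) -> str:
    # repr round-trips doubles exactly, so write/read cycles are bit-stable
    return repr(float(x))


def write_psm_table(records: Iterable[PsmRecord], path: str | Path, comments: Sequence[str] = ()) -> None:
    """Write records in the canonical dialect (tab-separated, header line).

    Float fields are written with shortest round-trip representation so that
    ``read_psm_table(write_psm_table(x))`` reproduces every value bit-exactly.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write(sep.join(CANONICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                sep.join(
                    [
                        r.peptide_sequence,
                        r.protein_id,
                        "" if r.peptide_start is None else str(r.peptide_start),
                        format_mods(r.modifications, r.peptide_sequence),
                        _fmt_float(r.ms1_area),
                        _fmt_float(r.xcorr),
                        _fmt_float(r.q_value),
                        r.phase,
                        str(r.replicate),
                        r.fraction,
                    ]
                )
                + "\n"
            )


def psms_to_frame(records: Iterable[PsmRecord]) -> pd.DataFrame:
    """Tabulate records for the vectorised quantification steps."""
    rows = [
        {
            "peptide": r.peptide_sequence,
            "protein": r.protein_id,
            "start": r.peptide_start,
            "mods": r.modifications,
            "area": r.ms1_area,
            "xcorr": r.xcorr,
            "qvalue": r.q_value,
            "phase": r.phase,
            "replicate": r.replicate,
            "fraction": r.fraction,
            "contaminant": r.is_contaminant,
        }
        for r in records
    ]
    cols = ["peptide", "protein", "start", "mods", "area", "xcorr", "qvalue",
            "phase", "replicate", "fraction", "contaminant"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Pathway tables


def read_pathway_table(path: str | Path) -> list[PathwayAnnotation]:
    """Read a two-column (protein, ``;``-joined pathways) annotation table.

    An empty second column means "no pathway assigned"; the protein is kept
    with an empty set.  Duplicate protein IDs raise :class:`ValidationError`.
    A leading header row (first field ``protein``) is tolerated.
    """
    out: list[PathwayAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            pid = parts[0].strip()
            if lineno == 1 and pid.lower() == "protein":
                continue
            if pid in seen:
                raise ValidationError(f"duplicate protein_id {pid!r} in pathway table")
            seen.add(pid)
            raw = parts[1].strip() if len(parts) > 1 else ""
            pathways = frozenset(p.strip() for p in raw.split(";") if p.strip())
            out.append(PathwayAnnotation(protein_id=pid, pathway_ids=pathways))
    return out


def write_pathway_table(annotations: Iterable[PathwayAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tpathways\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{';'.join(sorted(a.pathway_ids))}\n")
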