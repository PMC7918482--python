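"""In-silico tryptic digestion and peptide-to-protein coordinate mapping.

Trypsin cleaves C-terminal to lysine (K) or arginine (R) unless the next
residue is proline — the classic KR-not-P rule that most search engines use
as their default.  The digest enumerates every peptide with 0 up to
``max_missed`` internal missed cleavage sites; the search settings this
pipeline mirrors allowed up to four.

All coordinates are 1-based and inclusive in protein space, matching the
K<position> site notation used when reporting acetylation sites.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import NTERM, ValidationError

__all__ = [
    "TrypticPeptide",
    "cleavage_sites",
    "tryptic_digest",
    "map_mod_to_protein",
    "PROTEIN_NTERM",
]

#: value returned for a modification sitting on the protein's own N-terminus
PROTEIN_NTERM = "protein-N-term"


@dataclass(frozen=True)
class TrypticPeptide:
    """A digestion product located within its parent protein.

    ``start``/``end`` are 1-based inclusive protein coordinates;
    ``missed_cleavages`` counts the internal cleavage sites the peptide spans.
    """

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


def cleavage_sites(sequence: str, residues: str = "KR", block_next: str = "P") -> list[int]:
    """0-based indices i such that trypsin cuts between residue i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in residues and sequence[i + 1] not in block_next
    ]


def tryptic_digest(
    sequence: str,
    max_missed: int = 4,
    protein_id: str = "",
    min_length: int = 1,
    residues: str = "KR",
    block_next: str = "P",
) -> list[TrypticPeptide]:
    """Enumerate tryptic peptides with 0..``max_missed`` missed cleavages.

    Returns peptides ordered by ``(start, end)`` without duplicates.  The
    cleavage rule is configurable (defaults: cut after K/R, blocked by a
    following P).  ``min_length`` filters short products, which fall below
    typical MS detectability.
    """
    if not sequence:
        raise ValidationError("cannot digest an empty sequence")
    if not sequence.isalpha():
        raise ValidationError(f"sequence contains non-alphabetic characters: {sequence!r}")
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    sequence = sequence.upper()
    # fragment boundaries: 0, each cut point + 1, len
    cuts = cleavage_sites(sequence, residues=residues, block_next=block_next)
    bounds = [0] + [c + 1 for c in cuts] + [len(sequence)]
    peptides: list[TrypticPeptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            s, e = bounds[i], bounds[j + 1]
            if e - s < min_length:
                continue
            peptides.append(
                TrypticPeptide(
                    protein_id=protein_id,
                    start=s + 1,
                    end=e,
                    sequence=sequence[s:e],
                    missed_cleavages=j - i,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def map_mod_to_protein(peptide: TrypticPeptide, mod_position: int | str) -> int | str:
    """Translate a within-peptide modification position to protein coordinates.

    Residue positions map to ``start + position − 1``.  The ``"N-term"``
    token maps to :data:`PROTEIN_NTERM` only when the peptide begins the
    protein (start == 1); for an internal peptide it denotes the peptide's
    own N-terminal residue and maps to ``start``.
    """
    if mod_position == NTERM:
        return PROTEIN_NTERM if peptide.start == 1 else peptide.start
    if not (1 <= int(mod_position) <= len(peptide.sequence)):
        raise ValidationError(
            f"modification position {mod_position} outside peptide {peptide.sequence!r}"
        )
    return peptide.start + int(mod_position) - 1
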