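"""Signal-peptide-conditional protein identification from PSM tables.

A venom protein is accepted when it is supported by at least three distinct
tryptic fragments above the confidence threshold, or at least two when a
secretion signal peptide was predicted for its precursor (secreted proteins
carry stronger prior evidence of genuinely being in venom).  Includes an
in-silico tryptic digester used by the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

from .masses import CANONICAL_RESIDUES, UnknownResidueError

__all__ = ["PSMRecord", "IdentificationDecision", "tryptic_digest", "accept_identification"]


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match: a tryptic fragment with % confidence."""

    protein_id: str
    peptide: str
    confidence: float

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        if not 0 <= self.confidence <= 100:
            raise ValueError(f"confidence {self.confidence} outside [0, 100]")


@dataclass(frozen=True)
class IdentificationDecision:
    protein_id: str
    n_confident_distinct_fragments: int
    signal_peptide_predicted: bool
    accepted: bool


def tryptic_digest(sequence: str, missed_cleavages: int = 0) -> List[str]:
    """Fragments of a tryptic digest, in N→C order.

    Trypsin cleaves C-terminal to Lys or Arg except when the next residue is
    Pro.  With ``missed_cleavages`` > 0 the list additionally contains every
    fragment spanning up to that many internal uncleaved sites, appended
    after the fully cleaved fragments.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be non-negative")
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, ch in enumerate(sequence):
        if ch not in CANONICAL_RESIDUES:
            raise UnknownResidueError(sequence, i)
    cuts = [0]
    for i, ch in enumerate(sequence[:-1]):
        if ch in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    base = [sequence[a:b] for a, b in zip(cuts, cuts[1:])]
    out = list(base)
    for span in range(2, missed_cleavages + 2):
        for i in range(len(base) - span + 1):
            out.append("".join(base[i : i + span]))
    return out


def accept_identification(
    psms: Sequence[PSMRecord],
    signal_peptide_predicted: bool,
    confidence_threshold: float = 95.0,
) -> IdentificationDecision:
    """Apply the 3-fragments / 2-with-signal-peptide acceptance rule.

    Counts *distinct* peptide sequences with confidence strictly above the
    threshold; duplicated spectra of the same fragment count once.
    """
    if not 0 < confidence_threshold < 100:
        raise ValueError("confidence_threshold must be in (0, 100)")
    ids = {p.protein_id for p in psms}
    if len(ids) > 1:
        raise ValueError(f"PSMs span multiple proteins: {sorted(ids)}")
    protein_id = next(iter(ids)) if ids else ""
    confident = {p.peptide for p in psms if p.confidence > confidence_threshold}
    n = len(confident)
    required = 2 if signal_peptide_predicted else 3
    return IdentificationDecision(
        protein_id=protein_id,
        n_confident_distinct_fragments=n,
        signal_peptide_predicted=signal_peptide_predicted,
        accepted=n >= required,
    )
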