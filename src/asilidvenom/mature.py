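"""Enumerate candidate mature peptides and reconcile them with intact masses.

Venom-gland precursors are secreted proteins: a signal peptide is cleaved,
and the remaining chain may be further processed — ragged N- or C-termini,
excision of individual domains from multidomain precursors (e.g. Kazal
proteins), and N-terminal pyroglutamate formation when the mature chain
starts with Gln.  This module enumerates those candidate forms, predicts
their intact monoisotopic masses, and matches them against deconvoluted
neutral-mass peak lists from whole-venom LC-MS.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .masses import (
    MassConstants,
    ModificationSet,
    ResidueMassTable,
    default_constants,
    peptide_mass,
)

__all__ = [
    "Precursor",
    "Provenance",
    "MatureCandidate",
    "Condition",
    "MassPeak",
    "FormMatch",
    "EnumerationParams",
    "enumerate_candidates",
    "match_candidates",
]


@dataclass(frozen=True)
class Precursor:
    """A full-length translated precursor with its processing annotations.

    ``signal_end`` is the 0-based index of the first mature residue
    (half-open signal interval ``[0, signal_end)``); ``domains`` are
    optional 0-based half-open intervals within the mature region, for
    multidomain precursors whose single domains occur as free peptides.
    ``expression`` is an FPKM-like transcript abundance.
    """

    id: str
    sequence: str
    signal_end: Optional[int]
    family: str = ""
    domains: Tuple[Tuple[int, int], ...] = ()
    expression: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "domains", tuple(tuple(d) for d in self.domains))
        if self.signal_end is not None:
            if not (0 <= self.signal_end < len(self.sequence)):
                raise ValueError(
                    f"{self.id}: signal_end {self.signal_end} outside sequence "
                    f"of length {len(self.sequence)}"
                )
        spans = sorted(self.domains)
        for (s, e) in spans:
            if not (
                (self.signal_end or 0) <= s < e <= len(self.sequence)
            ):
                raise ValueError(f"{self.id}: domain ({s}, {e}) outside mature region")
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{self.id}: overlapping domain intervals")
        if self.expression < 0:
            raise ValueError(f"{self.id}: expression must be non-negative")

    @property
    def mature_sequence(self) -> str:
        if self.signal_end is None:
            raise ValueError(f"{self.id}: no signal-peptide annotation")
        return self.sequence[self.signal_end:]


class Provenance(str, enum.Enum):
    SIGNAL_CLEAVED = "signal_cleaved"
    N_TRIMMED = "n_trimmed"
    C_TRIMMED = "c_trimmed"
    DOMAIN_EXCISED = "domain_excised"
    PYROGLU_VARIANT = "pyroglu_variant"


@dataclass(frozen=True)
class MatureCandidate:
    """One hypothesised mature form: a precursor sub-interval plus mods."""

    precursor_id: str
    start: int
    end: int
    sequence: str
    mods: ModificationSet
    predicted_mass: float
    provenance: Provenance

    def __post_init__(self):
        if not (self.start < self.end):
            raise ValueError("empty candidate interval")


class Condition(str, enum.Enum):
    NATIVE = "native"
    REDUCED_ALKYLATED = "reduced_alkylated"


@dataclass(frozen=True)
class MassPeak:
    """A deconvoluted neutral monoisotopic mass with intensity."""

    mass: float
    intensity: float
    condition: Condition = Condition.NATIVE

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.intensity <= 0:
            raise ValueError("intensity must be positive")
        object.__setattr__(self, "condition", Condition(self.condition))


@dataclass(frozen=True)
class FormMatch:
    candidate: MatureCandidate
    peak: MassPeak
    delta: float  # observed - predicted, Da


@dataclass(frozen=True)
class EnumerationParams:
    """Bounds on the processing hypotheses tried per precursor.

    N-terminal trims up to 4 residues cover the 2-residue heterogeneity
    observed between subtypes with margin; C-terminal trims default to 2.
    """

    max_n_trim: int = 4
    max_c_trim: int = 2
    allow_pyroglu: bool = True
    use_domains: bool = True

    def __post_init__(self):
        if self.max_n_trim < 0 or self.max_c_trim < 0:
            raise ValueError("trim limits must be non-negative")


def _native_mods(seq: str, pyroglu: bool = False) -> ModificationSet:
    # native venom peptides assumed fully oxidized
    return ModificationSet(n_disulfides=seq.count("C") // 2, pyroglu=pyroglu)


def enumerate_candidates(
    precursor: Precursor,
    params: EnumerationParams = EnumerationParams(),
    table: ResidueMassTable = None,
    constants: MassConstants = None,
) -> List[MatureCandidate]:
    """All candidate mature forms of one precursor.

    Emits the signal-cleaved chain, its N-terminal truncations up to
    ``max_n_trim`` and C-terminal truncations up to ``max_c_trim``
    (truncations are not combined), each annotated domain, and a
    pyroglutamate variant of every candidate whose first residue is Gln.
    Native-condition masses assume full oxidation of cysteines.
    """
    if precursor.signal_end is None:
        raise ValueError(
            f"precursor {precursor.id!r} lacks a signal-peptide cleavage "
            "annotation; mature forms cannot be enumerated"
        )
    L = len(precursor.sequence)
    s0 = precursor.signal_end
    intervals: List[Tuple[int, int, Provenance]] = [(s0, L, Provenance.SIGNAL_CLEAVED)]
    for k in range(1, params.max_n_trim + 1):
        if s0 + k < L:
            intervals.append((s0 + k, L, Provenance.N_TRIMMED))
    for k in range(1, params.max_c_trim + 1):
        if s0 < L - k:
            intervals.append((s0, L - k, Provenance.C_TRIMMED))
    if params.use_domains:
        for (ds, de) in precursor.domains:
            intervals.append((ds, de, Provenance.DOMAIN_EXCISED))

    out: List[MatureCandidate] = []
    seen = set()
    for start, end, prov in intervals:
        seq = precursor.sequence[start:end]
        variants = [(_native_mods(seq), prov)]
        if params.allow_pyroglu and seq.startswith("Q"):
            variants.append((_native_mods(seq, pyroglu=True), Provenance.PYROGLU_VARIANT))
        for mods, p in variants:
            key = (start, end, mods)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                MatureCandidate(
                    precursor_id=precursor.id,
                    start=start,
                    end=end,
                    sequence=seq,
                    mods=mods,
                    predicted_mass=peptide_mass(seq, mods, table=table, constants=constants),
                    provenance=p,
                )
            )
    return out


def candidate_mass_for_condition(
    candidate: MatureCandidate,
    condition: Condition,
    table: ResidueMassTable = None,
    constants: MassConstants = None,
) -> float:
    """Predicted mass of a candidate under an observation condition.

    Under ``reduced_alkylated`` every cysteine is reduced and capped with a
    hydroxyethyl group; pyroglutamate and custom deltas are retained.
    """
    if Condition(condition) is Condition.NATIVE:
        return candidate.predicted_mass
    seq = candidate.sequence
    mods = ModificationSet(
        n_disulfides=0,
        pyroglu=candidate.mods.pyroglu,
        n_cys_alkylated=seq.count("C"),
        custom_deltas=candidate.mods.custom_deltas,
    )
    return peptide_mass(seq, mods, table=table, constants=constants)


def match_candidates(
    candidates: Sequence[MatureCandidate],
    peaks: Sequence[MassPeak],
    tolerance: float = 0.15,
    table: ResidueMassTable = None,
    constants: MassConstants = None,
) -> List[FormMatch]:
    """Greedy one-to-one reconciliation of candidates with observed peaks.

    Peaks are visited in descending intensity (ascending mass on ties); each
    claims its best unused candidate within ``tolerance`` — smallest
    ``|observed - predicted|`` first, then fewer modifications, then the
    longer candidate.  The result is a partial injection: no peak or
    candidate is reported twice, and the outcome does not depend on the
    input ordering of either list.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    order = sorted(range(len(peaks)), key=lambda i: (-peaks[i].intensity, peaks[i].mass))
    used = set()
    matches: List[FormMatch] = []
    for i in order:
        peak = peaks[i]
        best_j = None
        best_key = None
        for j, cand in enumerate(candidates):
            if j in used:
                continue
            predicted = (
                cand.predicted_mass
                if peak.condition is Condition.NATIVE
                else candidate_mass_for_condition(cand, peak.condition, table, constants)
            )
            delta = peak.mass - predicted
            if abs(delta) > tolerance:
                continue
            key = (
                abs(delta),
                cand.mods.n_modifications,
                -(cand.end - cand.start),
                cand.precursor_id,
                cand.start,
                cand.end,
            )
            if best_key is None or key < best_key:
                best_key, best_j = key, j
        if best_j is not None:
            used.add(best_j)
            cand = candidates[best_j]
            predicted = (
                cand.predicted_mass
                if peak.condition is Condition.NATIVE
                else candidate_mass_for_condition(cand, peak.condition, table, constants)
            )
            matches.append(FormMatch(candidate=cand, peak=peak, delta=peak.mass - predicted))
    return matches
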