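"""Rational toxin nomenclature with subtype clustering.

Names follow the convention activity-prefix + family label + species
acronym + ordinal + subtype letter, e.g. ``U-Asilidin12-Dg3a``: unknown
activity (U-), Asilidin family 12, *Dolopus genitalis*, the 3rd
peptide/protein discovered in this species, subtype ``a``.  Precursors
sharing >90% amino-acid identity are subtypes: they share one ordinal and
are distinguished by letters in discovery order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from Bio import Align

from .mature import Precursor

__all__ = ["ToxinName", "percent_identity", "assign_names"]


@dataclass(frozen=True)
class ToxinName:
    activity_prefix: str
    family_label: str
    species_acronym: str
    ordinal: int
    subtype_letter: str = ""
    precursor_id: str = ""

    def render(self) -> str:
        family = self.family_label.replace("-", "")
        return (
            f"{self.activity_prefix}{family}-"
            f"{self.species_acronym}{self.ordinal}{self.subtype_letter}"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    # minuscule gap cost: maximises matches while breaking ties toward
    # compact alignments so the reported alignment length is deterministic
    aligner.open_gap_score = -1e-6
    aligner.extend_gap_score = -1e-6
    return aligner


def percent_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length x 100."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def assign_names(
    precursors: Sequence[Precursor],
    activity_prefixes: Sequence[str] = None,
    discovery_order: Sequence[int] = None,
    species_acronym: str = "Dg",
    identity_threshold: float = 90.0,
    letter_singletons: bool = False,
) -> List[ToxinName]:
    """Assign rational names to a discovery-ordered precursor repertoire.

    Single-linkage clusters at strictly >``identity_threshold``% full-precursor
    identity share one ordinal; members receive subtype letters a, b, c ...
    in discovery order (singleton clusters stay letterless unless
    ``letter_singletons``).  Ordinals run over clusters in order of each
    cluster's first-discovered member and are unique per species across all
    families.  Output order follows the input order.
    """
    n = len(precursors)
    if activity_prefixes is None:
        activity_prefixes = ["U-"] * n
    if discovery_order is None:
        discovery_order = list(range(n))
    if len(set(discovery_order)) != n:
        raise ValueError("discovery_order must be a total order (no ties)")

    # single-linkage union-find over >threshold pairs
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if percent_identity(precursors[i].sequence, precursors[j].sequence) > identity_threshold:
                parent[find(i)] = find(j)

    clusters = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    # ordinals follow the discovery order of each cluster's first member
    ordered = sorted(clusters.values(), key=lambda idx: min(discovery_order[i] for i in idx))

    names: List[Optional[ToxinName]] = [None] * n
    for ordinal, members in enumerate(ordered, start=1):
        members = sorted(members, key=lambda i: discovery_order[i])
        lettered = len(members) > 1 or letter_singletons
        for pos, i in enumerate(members):
            letter = chr(ord("a") + pos) if lettered else ""
            names[i] = ToxinName(
                activity_prefix=activity_prefixes[i],
                family_label=precursors[i].family,
                species_acronym=species_acronym,
                ordinal=ordinal,
                subtype_letter=letter,
                precursor_id=precursors[i].id,
            )
    return names
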