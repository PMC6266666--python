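"""Readers and writers for the pipeline's plain-text formats.

Precursors travel as FASTA with the structured header dialect
``>id|family|signal_end|expression`` (plus an optional sidecar TSV of
domain intervals); everything tabular is TSV with a header row, UTF-8,
"." decimal, masses printed to 4 decimals.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masses import CANONICAL_RESIDUES
from .mature import Condition, FormMatch, MassPeak, Precursor
from .identification import PSMRecord
from .nomenclature import ToxinName
from .quantstats import AbundanceRecord, DoseResponseObservation
from .rapairing import CysteineAssignment

__all__ = [
    "read_precursor_fasta",
    "write_precursor_fasta",
    "read_domains_tsv",
    "read_peaks_tsv",
    "write_peaks_tsv",
    "read_psm_tsv",
    "read_dose_response_tsv",
    "read_abundance_tsv",
    "write_assignments_tsv",
    "write_matches_tsv",
    "write_names_tsv",
]


def read_domains_tsv(path) -> Dict[str, List[Tuple[int, int]]]:
    """Sidecar domain intervals: columns ``id``, ``start``, ``end``."""
    df = pd.read_csv(path, sep="\t")
    for col in ("id", "start", "end"):
        if col not in df.columns:
            raise ValueError(f"{path}: domain table missing column {col!r}")
    out: Dict[str, List[Tuple[int, int]]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.id), []).append((int(row.start), int(row.end)))
    return out


def read_precursor_fasta(path, domains_path=None) -> List[Precursor]:
    """Parse precursors from the ``id|family|signal_end|expression`` dialect."""
    domains = read_domains_tsv(domains_path) if domains_path else {}
    out: List[Precursor] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        parts = rec.description.split("|")
        if len(parts) != 4:
            raise ValueError(
                f"{path}: record {i}: header must have 4 '|'-separated fields "
                f"(id|family|signal_end|expression), got {rec.description!r}"
            )
        pid, family, signal_end, expression = (p.strip() for p in parts)
        if not signal_end:
            raise ValueError(f"{path}: record {i} ({pid}): missing signal_end field")
        seq = str(rec.seq).upper()
        bad = [ch for ch in seq if ch not in CANONICAL_RESIDUES]
        if bad:
            raise ValueError(
                f"{path}: record {i} ({pid}): non-amino-acid characters {sorted(set(bad))}"
            )
        try:
            se = int(signal_end)
        except ValueError:
            raise ValueError(
                f"{path}: record {i} ({pid}): signal_end must be an integer, "
                f"got {signal_end!r}"
            ) from None
        out.append(
            Precursor(
                id=pid,
                sequence=seq,
                signal_end=se,
                family=family,
                domains=tuple(domains.get(pid, ())),
                expression=float(expression) if expression else 0.0,
            )
        )
    return out


def write_precursor_fasta(precursors: Sequence[Precursor], path) -> None:
    records = []
    for p in precursors:
        header = f"{p.id}|{p.family}|{p.signal_end}|{p.expression:g}"
        records.append(SeqRecord(Seq(p.sequence), id=header, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_peaks_tsv(path, condition: Optional[str] = None) -> List[MassPeak]:
    """Peak list TSV with columns ``mass``, ``intensity`` and optionally
    ``condition`` (overridden by the ``condition`` argument if given)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("mass", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: peak list missing column {col!r}")
    out = []
    for i, row in enumerate(df.itertuples(), start=2):
        cond = condition or getattr(row, "condition", Condition.NATIVE)
        try:
            out.append(MassPeak(float(row.mass), float(row.intensity), Condition(cond)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from None
    return out


def write_peaks_tsv(peaks: Sequence[MassPeak], path) -> None:
    df = pd.DataFrame(
        dict(
            mass=[round(p.mass, 4) for p in peaks],
            intensity=[p.intensity for p in peaks],
            condition=[p.condition.value for p in peaks],
        )
    )
    df.to_csv(path, sep="\t", index=False)


def read_psm_tsv(path) -> List[PSMRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "peptide", "confidence"):
        if col not in df.columns:
            raise ValueError(f"{path}: PSM table missing column {col!r}")
    out = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            out.append(PSMRecord(str(row.protein_id), str(row.peptide), float(row.confidence)))
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from None
    return out


def read_dose_response_tsv(path) -> List[DoseResponseObservation]:
    df = pd.read_csv(path, sep="\t")
    for col in ("dose", "n_injected", "n_paralysed", "timepoint"):
        if col not in df.columns:
            raise ValueError(f"{path}: dose-response table missing column {col!r}")
    out = []
    for i, row in enumerate(df.itertuples(), start=2):
        try:
            out.append(
                DoseResponseObservation(
                    float(row.dose), int(row.n_injected), int(row.n_paralysed), str(row.timepoint)
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from None
    return out


def read_abundance_tsv(path) -> List[AbundanceRecord]:
    df = pd.read_csv(path, sep="\t")
    for col in ("entity_id", "family_label", "precursor_count_intensity", "expression"):
        if col not in df.columns:
            raise ValueError(f"{path}: abundance table missing column {col!r}")
    return [
        AbundanceRecord(
            str(r.entity_id),
            str(r.family_label),
            float(r.precursor_count_intensity),
            float(r.expression),
        )
        for r in df.itertuples()
    ]


def write_assignments_tsv(assignments: Sequence[CysteineAssignment], path) -> None:
    df = pd.DataFrame(
        [
            dict(
                native_mass=round(a.native_mass, 4),
                ra_mass=round(a.ra_mass, 4),
                delta=round(a.delta, 4),
                n_cys=a.n_cys,
                native_rank=a.native_rank,
                ra_rank=a.ra_rank,
            )
            for a in assignments
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_matches_tsv(matches: Sequence[FormMatch], path) -> None:
    df = pd.DataFrame(
        [
            dict(
                precursor_id=m.candidate.precursor_id,
                start=m.candidate.start,
                end=m.candidate.end,
                provenance=m.candidate.provenance.value,
                n_disulfides=m.candidate.mods.n_disulfides,
                pyroglu=m.candidate.mods.pyroglu,
                predicted_mass=round(m.candidate.predicted_mass, 4),
                observed_mass=round(m.peak.mass, 4),
                delta=round(m.delta, 4),
                intensity=m.peak.intensity,
            )
            for m in matches
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def write_names_tsv(names: Sequence[ToxinName], path) -> None:
    df = pd.DataFrame(
        [
            dict(
                precursor_id=n.precursor_id,
                name=n.render(),
                activity_prefix=n.activity_prefix,
                family_label=n.family_label,
                species_acronym=n.species_acronym,
                ordinal=n.ordinal,
                subtype_letter=n.subtype_letter,
            )
            for n in names
        ]
    )
    df.to_csv(path, sep="\t", index=False)
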