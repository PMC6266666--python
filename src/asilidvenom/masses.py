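"""Monoisotopic mass arithmetic for venom peptides.

Predicted intact masses of mature venom peptides are computed from their
amino-acid sequence plus a small set of modifications that dominate
disulfide-rich venoms: intramolecular disulfide bonds, N-terminal
pyroglutamate (from Gln), and the reduction/alkylation (RA) chemistry used
to count cysteines (iodoethanol caps each reduced thiol with a hydroxyethyl
group, +C2H4O).

Conventions
-----------
All masses are neutral monoisotopic daltons.  The unmodified sequence mass
(``peptide_mass`` with no modifications) is the fully reduced, free-thiol
linear chain: the sum of standard residue masses plus one water.  Each
disulfide bond then *removes* two hydrogens, and each hydroxyethyl adduct
*adds* C2H4O to an (already reduced) cysteine.  Relative to the oxidized
native form, opening a disulfide and capping both thiols therefore shifts
the mass by ``delta_reduction_per_cys + delta_hydroxyethyl_per_cys``
(about +45.03 Da) per cysteine — the signature used to count cysteines from
paired native / reduced-alkylated peak lists.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence, Tuple

__all__ = [
    "ResidueMassTable",
    "MassConstants",
    "ModificationSet",
    "default_constants",
    "peptide_mass",
    "ra_mass",
    "shift_to_ncys",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class UnknownResidueError(ValueError):
    """A sequence contains a letter outside the 20 canonical residues."""

    def __init__(self, sequence: str, position: int):
        self.position = position
        self.residue = sequence[position]
        super().__init__(
            f"unknown residue {self.residue!r} at position {position} "
            f"(0-based) in sequence {sequence[:20]!r}..."
        )


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses for the 20 canonical amino acids."""

    residue_masses: dict
    water_mass: float
    proton_mass: float

    def __post_init__(self):
        keys = set(self.residue_masses)
        if keys != CANONICAL_RESIDUES:
            missing = sorted(CANONICAL_RESIDUES - keys)
            extra = sorted(keys - CANONICAL_RESIDUES)
            raise ValueError(
                f"residue table must cover the 20 canonical residues exactly "
                f"(missing {missing}, unexpected {extra})"
            )
        if any(m <= 0 for m in self.residue_masses.values()):
            raise ValueError("all residue masses must be positive")
        if min(self.residue_masses, key=self.residue_masses.get) != "G":
            raise ValueError("glycine must be the lightest residue")

    def __getitem__(self, residue: str) -> float:
        return self.residue_masses[residue]


@dataclass(frozen=True)
class MassConstants:
    """Modification mass deltas (Da, monoisotopic)."""

    delta_disulfide_per_bond: float  # loss of 2 H
    delta_pyroglu: float  # loss of NH3 from N-terminal Gln
    delta_hydroxyethyl_per_cys: float  # gain of C2H4O (iodoethanol adduct)
    delta_reduction_per_cys: float  # gain of 1 H per opened half-cystine

    def __post_init__(self):
        if self.delta_disulfide_per_bond >= 0:
            raise ValueError("disulfide formation must lose mass")
        if self.delta_pyroglu >= 0:
            raise ValueError("pyroglutamate formation must lose mass")
        if self.delta_hydroxyethyl_per_cys <= 0:
            raise ValueError("hydroxyethyl adduct must gain mass")

    @property
    def per_cys_ra_shift(self) -> float:
        """Mass gained per cysteine by reduction + hydroxyethyl alkylation,
        relative to the disulfide-bonded (oxidized) form (~45.03 Da)."""
        return self.delta_hydroxyethyl_per_cys + self.delta_reduction_per_cys


def _load_default() -> Tuple[ResidueMassTable, MassConstants]:
    text = resources.files("asilidvenom.data").joinpath("mass_constants.json").read_text()
    raw = json.loads(text)
    table = ResidueMassTable(
        residue_masses=dict(raw["residue_masses"]),
        water_mass=raw["water_mass"],
        proton_mass=raw["proton_mass"],
    )
    consts = MassConstants(
        delta_disulfide_per_bond=raw["delta_disulfide_per_bond"],
        delta_pyroglu=raw["delta_pyroglu"],
        delta_hydroxyethyl_per_cys=raw["delta_hydroxyethyl_per_cys"],
        delta_reduction_per_cys=raw["delta_reduction_per_cys"],
    )
    return table, consts


_DEFAULT_TABLE, _DEFAULT_CONSTANTS = _load_default()


def default_constants() -> Tuple[ResidueMassTable, MassConstants]:
    """The packaged residue-mass table and modification deltas."""
    return _DEFAULT_TABLE, _DEFAULT_CONSTANTS


def load_constants(path) -> Tuple[ResidueMassTable, MassConstants]:
    """Load an alternate mass-convention config (same JSON layout as the
    packaged default), for injecting non-standard constants."""
    with open(path) as fh:
        raw = json.load(fh)
    table = ResidueMassTable(
        residue_masses=dict(raw["residue_masses"]),
        water_mass=raw["water_mass"],
        proton_mass=raw["proton_mass"],
    )
    consts = MassConstants(
        delta_disulfide_per_bond=raw["delta_disulfide_per_bond"],
        delta_pyroglu=raw["delta_pyroglu"],
        delta_hydroxyethyl_per_cys=raw["delta_hydroxyethyl_per_cys"],
        delta_reduction_per_cys=raw["delta_reduction_per_cys"],
    )
    return table, consts


@dataclass(frozen=True)
class ModificationSet:
    """Modifications carried by one peptide form.

    ``n_disulfides`` intramolecular disulfide bonds, optional N-terminal
    pyroglutamate (sequence must start with Q), ``n_cys_alkylated``
    hydroxyethyl-capped cysteines, plus arbitrary labelled mass deltas.
    """

    n_disulfides: int = 0
    pyroglu: bool = False
    n_cys_alkylated: int = 0
    custom_deltas: Tuple[Tuple[str, float], ...] = ()

    def __post_init__(self):
        if self.n_disulfides < 0 or self.n_cys_alkylated < 0:
            raise ValueError("modification counts must be non-negative")
        object.__setattr__(self, "custom_deltas", tuple(self.custom_deltas))

    @property
    def n_modifications(self) -> int:
        return (
            self.n_disulfides
            + int(self.pyroglu)
            + self.n_cys_alkylated
            + len(self.custom_deltas)
        )

    def validate_for(self, sequence: str) -> None:
        n_cys = sequence.count("C")
        if self.n_disulfides > n_cys // 2:
            raise ValueError(
                f"{self.n_disulfides} disulfides impossible with {n_cys} cysteines"
            )
        if self.pyroglu and not sequence.startswith("Q"):
            raise ValueError(
                "pyroglutamate requires an N-terminal Gln; sequence starts "
                f"with {sequence[0]!r}"
            )
        if self.n_cys_alkylated > n_cys:
            raise ValueError(
                f"{self.n_cys_alkylated} alkylated cysteines exceeds the "
                f"{n_cys} present"
            )


NO_MODS = ModificationSet()


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, ch in enumerate(sequence):
        if ch not in CANONICAL_RESIDUES:
            raise UnknownResidueError(sequence, i)


def peptide_mass(
    sequence: str,
    mods: ModificationSet = NO_MODS,
    table: ResidueMassTable = None,
    constants: MassConstants = None,
) -> float:
    """Neutral monoisotopic mass of a peptide with the given modifications.

    The unmodified baseline is the reduced free-thiol chain (residues +
    water); modification deltas are purely additive.
    """
    table = table or _DEFAULT_TABLE
    constants = constants or _DEFAULT_CONSTANTS
    _check_sequence(sequence)
    mods.validate_for(sequence)
    m = sum(table[ch] for ch in sequence) + table.water_mass
    m += mods.n_disulfides * constants.delta_disulfide_per_bond
    if mods.pyroglu:
        m += constants.delta_pyroglu
    m += mods.n_cys_alkylated * constants.delta_hydroxyethyl_per_cys
    for _, delta in mods.custom_deltas:
        m += delta
    return m


def oxidized_mods(sequence: str, pyroglu: bool = False) -> ModificationSet:
    """Default native-form modifications: fully oxidized (all cysteines
    paired into floor(nCys/2) disulfides)."""
    return ModificationSet(n_disulfides=sequence.count("C") // 2, pyroglu=pyroglu)


def ra_mass(
    sequence: str,
    n_cys: Optional[int] = None,
    pyroglu: bool = False,
    table: ResidueMassTable = None,
    constants: MassConstants = None,
) -> float:
    """Mass after reduction and hydroxyethyl alkylation of every cysteine.

    Equals the fully reduced free-thiol mass plus one C2H4O adduct per
    cysteine.  ``n_cys``, when given, must equal the sequence's cysteine
    count (a consistency check for callers carrying counts separately).
    """
    _check_sequence(sequence)
    actual = sequence.count("C")
    if n_cys is not None and n_cys != actual:
        raise ValueError(f"n_cys={n_cys} but sequence contains {actual} cysteines")
    mods = ModificationSet(n_disulfides=0, pyroglu=pyroglu, n_cys_alkylated=actual)
    return peptide_mass(sequence, mods, table=table, constants=constants)


def shift_to_ncys(
    delta: float,
    tolerance: float,
    allowed: Iterable[int] = (0, 4, 6, 8),
    constants: MassConstants = None,
) -> Optional[int]:
    """Interpret a native→RA mass shift as a cysteine count.

    Returns the allowed count ``n`` minimizing ``|delta - n * per_cys_shift|``
    provided that residual is within ``tolerance``; ties break toward the
    smaller count.  Returns ``None`` when no allowed count fits.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    constants = constants or _DEFAULT_CONSTANTS
    shift = constants.per_cys_ra_shift
    best = None
    best_resid = math.inf
    for n in sorted(set(allowed)):
        resid = abs(delta - n * shift)
        # smaller n wins ties (within floating rounding of the residuals)
        if resid < best_resid - 1e-9:
            best, best_resid = n, resid
    return best if best_resid <= tolerance else None
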