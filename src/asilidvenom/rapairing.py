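"""Differential cysteine counting from native vs reduced/alkylated venom.

Reduction opens each disulfide (adding 1 H per cysteine) and iodoethanol
caps every free thiol with a hydroxyethyl group (+C2H4O), so a peptide with
n cysteines gains about n x 45.03 Da between the native and the
reduced/alkylated (RA) deconvoluted mass lists.  Pairing the most abundant
masses of the two lists by these characteristic shifts counts the cysteines
of each abundant venom peptide without any sequence knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

from .masses import MassConstants, default_constants, shift_to_ncys
from .mature import Condition, MassPeak

__all__ = ["CysteineAssignment", "PairingResult", "select_top_peaks", "pair_conditions"]

DEFAULT_ALLOWED_NCYS = frozenset({0, 4, 6, 8})


@dataclass(frozen=True)
class CysteineAssignment:
    """A native/RA peak pair interpreted as one peptide with n_cys cysteines."""

    native_mass: float
    ra_mass: float
    delta: float  # ra_mass - native_mass
    n_cys: int
    native_rank: int  # 1 = most intense among the selected native peaks
    ra_rank: int

    def __post_init__(self):
        if self.n_cys > 0 and self.delta < 0:
            raise ValueError("positive cysteine count requires a positive shift")


@dataclass(frozen=True)
class PairingResult:
    assignments: Tuple[CysteineAssignment, ...]
    unmatched_native: Tuple[MassPeak, ...]
    unmatched_ra: Tuple[MassPeak, ...]


def select_top_peaks(
    peaks: Sequence[MassPeak],
    top_n: int = 50,
    mass_range: Tuple[float, float] = (1000.0, 10000.0),
) -> List[MassPeak]:
    """The ``top_n`` most intense peaks within ``mass_range`` (inclusive),
    sorted by descending intensity with ascending-mass tie-break."""
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    low, high = mass_range
    if not low < high:
        raise ValueError("mass_range must satisfy low < high")
    in_range = [p for p in peaks if low <= p.mass <= high]
    in_range.sort(key=lambda p: (-p.intensity, p.mass))
    return in_range[:top_n]


def pair_conditions(
    native: Sequence[MassPeak],
    ra: Sequence[MassPeak],
    allowed_ncys: Iterable[int] = DEFAULT_ALLOWED_NCYS,
    tolerance: float = 0.1,
    constants: MassConstants = None,
) -> PairingResult:
    """Pair native peaks with their reduced/alkylated counterparts.

    Native peaks are visited in descending intensity; each claims the unused
    RA peak whose shift best matches an allowed cysteine count (smallest
    residual from ``n x per_cys_shift`` within ``tolerance``).  Each RA peak
    satisfies at most one native peak: a single molecular species yields one
    shifted product.  Both input lists are expected to be pre-filtered with
    :func:`select_top_peaks`; pass the full RA list instead to search
    shifted partners outside the RA top ranks.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    constants = constants or default_constants()[1]
    allowed = frozenset(allowed_ncys)
    shift = constants.per_cys_ra_shift

    native_sorted = sorted(native, key=lambda p: (-p.intensity, p.mass))
    ra_sorted = sorted(ra, key=lambda p: (-p.intensity, p.mass))
    native_rank = {id(p): r + 1 for r, p in enumerate(native_sorted)}
    ra_rank = {id(p): r + 1 for r, p in enumerate(ra_sorted)}

    used_ra = set()
    assignments: List[CysteineAssignment] = []
    matched_native = set()
    for p in native_sorted:
        best = None  # (residual, ra_rank, index, n_cys)
        for k, q in enumerate(ra_sorted):
            if k in used_ra:
                continue
            delta = q.mass - p.mass
            n = shift_to_ncys(delta, tolerance, allowed, constants)
            if n is None:
                continue
            if n > 0 and delta < 0:
                continue
            resid = abs(delta - n * shift)
            key = (resid, k)
            if best is None or key < best[0]:
                best = (key, k, n)
        if best is not None:
            _, k, n = best
            q = ra_sorted[k]
            used_ra.add(k)
            matched_native.add(id(p))
            assignments.append(
                CysteineAssignment(
                    native_mass=p.mass,
                    ra_mass=q.mass,
                    delta=q.mass - p.mass,
                    n_cys=n,
                    native_rank=native_rank[id(p)],
                    ra_rank=ra_rank[id(q)],
                )
            )
    unmatched_native = tuple(p for p in native_sorted if id(p) not in matched_native)
    unmatched_ra = tuple(q for k, q in enumerate(ra_sorted) if k not in used_ra)
    return PairingResult(tuple(assignments), unmatched_native, unmatched_ra)
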