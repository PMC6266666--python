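"""Synthetic venomics data with known ground truth.

Generates every input the analysis consumes — precursor repertoires with
signal peptides and fixed cysteine scaffolds, paired native/reduced-
alkylated intact-mass lists with decoy peaks, PSM tables, quantal
dose-response counts, and paired expression/intensity abundances — each
with a machine-readable truth table, so every downstream stage can be
tested against planted answers without any external data.

The default :class:`SyntheticVenomSpec` emulates the peptide repertoire of
an assassin-fly venom: four 6-cysteine families (CS-alpha/beta-like,
ICK-like, two Kazal/peritrophin-like) totalling 17 members, one 4-cysteine
family of 2, and one linear (cysteine-free) family of 2 — 21 true peptides
— plus 29 inert decoy masses, giving a 50-peak list per condition.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .identification import tryptic_digest
from .masses import ModificationSet, default_constants, peptide_mass, ra_mass
from .mature import Condition, MassPeak, Precursor
from .rapairing import DEFAULT_ALLOWED_NCYS

__all__ = [
    "FamilyProfile",
    "SyntheticVenomSpec",
    "generate_precursors",
    "generate_mass_lists",
    "generate_psm_table",
    "generate_dose_response",
    "generate_expression",
]

# residues sampled uniformly; cysteines are placed deliberately
ALPHABET_NO_CYS = "ADEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FamilyProfile:
    """One toxin family: member count, cysteine scaffold, size, abundance."""

    name: str
    n_members: int
    n_cys: int  # 0, 4, 6 or 8
    mature_length: Tuple[int, int]  # inclusive range
    signal_length: Tuple[int, int] = (18, 24)
    composition_share: float = 0.0  # percent of total venom abundance

    def __post_init__(self):
        if self.n_cys not in (0, 2, 4, 6, 8):
            raise ValueError(f"{self.name}: unsupported cysteine count {self.n_cys}")
        lo, hi = self.mature_length
        if lo < 2 * self.n_cys - 1:
            raise ValueError(
                f"{self.name}: mature length {lo} too short for {self.n_cys} "
                "non-adjacent cysteines"
            )


DEFAULT_FAMILIES = (
    FamilyProfile("Asilidin-12", 2, 6, (34, 38), composition_share=30.0),
    FamilyProfile("Asilidin-1", 6, 6, (27, 36), composition_share=25.0),
    FamilyProfile("Asilidin-14", 5, 6, (55, 65), composition_share=15.0),
    FamilyProfile("Asilidin-15", 4, 6, (55, 62), composition_share=10.0),
    FamilyProfile("Asilidin-3", 2, 4, (30, 50), composition_share=10.0),
    FamilyProfile("Asilidin-4", 2, 0, (40, 80), composition_share=10.0),
)

DEFAULT_PD50_TRUTH = {
    "5 s": (15.58, 2.5),
    "1 min": (3.07, 2.5),
    "60 min": (1.16, 2.5),
}


@dataclass(frozen=True)
class SyntheticVenomSpec:
    """Conditions of a simulated venom study.  ``seed`` is mandatory."""

    seed: int
    families: Tuple[FamilyProfile, ...] = DEFAULT_FAMILIES
    mass_noise_sd: float = 0.02  # Da, additive on deconvoluted masses
    n_decoy_peaks: int = 29  # per condition
    decoy_exclusion: float = 1.0  # Da kept clear of any true or shifted mass
    psm_confidence_mean: float = 98.0
    psm_confidence_sd: float = 2.0
    n_nonsecreted_proteins: int = 10
    n_decoy_proteins: int = 20
    expression_correlation_target: float = 0.51
    pd50_truth: Tuple[Tuple[str, Tuple[float, float]], ...] = tuple(
        DEFAULT_PD50_TRUTH.items()
    )
    doses: Tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
    n_per_dose: int = 20

    def __post_init__(self):
        object.__setattr__(self, "families", tuple(self.families))
        object.__setattr__(self, "pd50_truth", tuple(self.pd50_truth))
        total = sum(f.composition_share for f in self.families)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"composition shares must sum to 100 (got {total})")
        if self.mass_noise_sd < 0 or self.n_decoy_peaks < 0:
            raise ValueError("noise SD and decoy count must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET_NO_CYS), size=length))


def _place_cysteines(rng: np.random.Generator, length: int, n_cys: int) -> List[int]:
    """Random non-adjacent positions: choose from a compacted index space."""
    if n_cys == 0:
        return []
    if length < 2 * n_cys - 1:
        raise ValueError(f"cannot place {n_cys} non-adjacent cysteines in {length}")
    picks = rng.choice(length - (n_cys - 1), size=n_cys, replace=False)
    picks.sort()
    return [int(p) + i for i, p in enumerate(picks)]


def _mature_with_scaffold(rng: np.random.Generator, length: int, n_cys: int) -> str:
    seq = list(_random_sequence(rng, length))
    for pos in _place_cysteines(rng, length, n_cys):
        seq[pos] = "C"
    return "".join(seq)


def generate_precursors(
    spec: SyntheticVenomSpec, rng: Optional[np.random.Generator] = None
) -> Tuple[List[Precursor], pd.DataFrame]:
    """Simulate the precursor repertoire and its truth table.

    The first family with at least two members always contains a >90%-
    identity subtype pair (member 2 is member 1 with ~5% of residues
    substituted), exercising the nomenclature clustering.  Per-precursor
    abundance is the family's composition share split over members with
    log-normal jitter; expression is proportional with its own jitter.
    """
    rng = rng if rng is not None else spec.rng()
    precursors: List[Precursor] = []
    rows = []
    idx = 0
    pair_done = False
    for fam in spec.families:
        base_mature = None
        base_signal = None
        for m in range(fam.n_members):
            idx += 1
            pid = f"SYN{idx:03d}"
            if not pair_done and fam.n_members >= 2 and m == 1 and base_mature:
                # subtype: substitute ~5% of residues, never touching cysteines
                signal = base_signal
                mat = list(base_mature)
                n_sub = max(1, int(0.05 * (len(signal) + len(mat))))
                subst_sites = [i for i, ch in enumerate(mat) if ch != "C"]
                for i in rng.choice(subst_sites, size=n_sub, replace=False):
                    choices = [c for c in ALPHABET_NO_CYS if c != mat[i]]
                    mat[i] = str(rng.choice(choices))
                mature = "".join(mat)
                pair_done = True
            else:
                signal = _random_sequence(
                    rng, int(rng.integers(fam.signal_length[0], fam.signal_length[1] + 1))
                )
                length = int(rng.integers(fam.mature_length[0], fam.mature_length[1] + 1))
                mature = _mature_with_scaffold(rng, length, fam.n_cys)
                if m == 0:
                    base_mature, base_signal = mature, signal
            member_share = fam.composition_share / fam.n_members
            intensity = member_share * 1e4 * rng.lognormal(0.0, 0.3)
            expression = intensity * rng.lognormal(0.0, 0.4)
            seq = signal + mature
            precursors.append(
                Precursor(
                    id=pid,
                    sequence=seq,
                    signal_end=len(signal),
                    family=fam.name,
                    expression=expression,
                )
            )
            nat = peptide_mass(mature, mods=ModificationSet(n_disulfides=fam.n_cys // 2))
            rows.append(
                dict(
                    id=pid,
                    family=fam.name,
                    signal_end=len(signal),
                    mature_seq=mature,
                    n_cys=fam.n_cys,
                    native_mass=nat,
                    ra_mass=ra_mass(mature),
                    intensity=intensity,
                    expression=expression,
                    composition_share=member_share,
                )
            )
    return precursors, pd.DataFrame(rows)


def _draw_inert_decoys(
    rng: np.random.Generator,
    n: int,
    forbidden: Sequence[float],
    exclusion: float,
    mass_range: Tuple[float, float] = (1000.0, 10000.0),
) -> List[float]:
    """Uniform decoy masses kept at least ``exclusion`` Da from every
    forbidden mass (true masses and their cysteine-shift images)."""
    fb = np.sort(np.asarray(forbidden, dtype=float))
    out: List[float] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place inert decoys; exclusion too wide")
        m = float(rng.uniform(*mass_range))
        pool = np.concatenate([fb, np.asarray(out, dtype=float)]) if out else fb
        if pool.size and np.min(np.abs(pool - m)) < exclusion:
            continue
        out.append(m)
    return out


def generate_mass_lists(
    truth: pd.DataFrame,
    spec: SyntheticVenomSpec,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[MassPeak], List[MassPeak]]:
    """Native and reduced/alkylated deconvoluted peak lists.

    Each planted mature form yields a native peak at its oxidized mass and
    an RA peak at its alkylated mass, both with independent Gaussian mass
    noise and intensities set by the truth table.  Decoy peaks are placed
    so that no decoy sits within the exclusion zone of any true mass or of
    any mass reachable from an existing peak by an allowed cysteine shift:
    decoys exercise the top-N selection without ever forming a valid pair.
    """
    rng = rng if rng is not None else spec.rng()
    shift = default_constants()[1].per_cys_ra_shift
    native: List[MassPeak] = []
    ra: List[MassPeak] = []
    for row in truth.itertuples():
        nm = row.native_mass + rng.normal(0.0, spec.mass_noise_sd)
        rm = row.ra_mass + rng.normal(0.0, spec.mass_noise_sd)
        native.append(MassPeak(nm, row.intensity * rng.lognormal(0, 0.1), Condition.NATIVE))
        ra.append(MassPeak(rm, row.intensity * rng.lognormal(0, 0.1), Condition.REDUCED_ALKYLATED))

    # forbid decoys near any true mass or any allowed-shift image of it
    images: List[float] = []
    for m in list(truth.native_mass) + list(truth.ra_mass):
        for n_cys in DEFAULT_ALLOWED_NCYS:
            images.extend([m + n_cys * shift, m - n_cys * shift])
    decoy_native = _draw_inert_decoys(rng, spec.n_decoy_peaks, images, spec.decoy_exclusion)
    images2 = list(images)
    for m in decoy_native:
        for n_cys in DEFAULT_ALLOWED_NCYS:
            images2.extend([m + n_cys * shift, m - n_cys * shift])
    decoy_ra = _draw_inert_decoys(rng, spec.n_decoy_peaks, images2, spec.decoy_exclusion)

    med = float(truth.intensity.median()) if len(truth) else 1e4
    for m in decoy_native:
        native.append(MassPeak(m, med * 0.1 * rng.lognormal(0, 0.5), Condition.NATIVE))
    for m in decoy_ra:
        ra.append(MassPeak(m, med * 0.1 * rng.lognormal(0, 0.5), Condition.REDUCED_ALKYLATED))
    return native, ra


def generate_psm_table(
    precursors: Sequence[Precursor],
    spec: SyntheticVenomSpec,
    rng: Optional[np.random.Generator] = None,
    confidence_threshold: float = 95.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """PSM table plus identification truth.

    True venom precursors (signal peptide predicted) contribute 1-5 distinct
    tryptic fragments with confidences from the spec's Gaussian model;
    additional non-secreted proteins exercise the 3-fragment branch; decoy
    proteins carry only sub-threshold PSMs.  The truth table records, per
    protein, the number of distinct fragments drawn above the threshold and
    whether the acceptance rule should fire.
    """
    rng = rng if rng is not None else spec.rng()
    psm_rows = []
    truth_rows = []

    def _emit(pid: str, sequence: str, signal: bool):
        frags = [f for f in tryptic_digest(sequence, missed_cleavages=1) if len(f) >= 5]
        frags = sorted(set(frags))
        if not frags:
            frags = [sequence]
        k = int(rng.integers(1, 6))
        k = min(k, len(frags))
        chosen = list(rng.choice(frags, size=k, replace=False))
        n_conf = 0
        for pep in chosen:
            conf = float(np.clip(rng.normal(spec.psm_confidence_mean, spec.psm_confidence_sd), 0, 100))
            if conf > confidence_threshold:
                n_conf += 1
            psm_rows.append(dict(protein_id=pid, peptide=pep, confidence=conf))
        required = 2 if signal else 3
        truth_rows.append(
            dict(
                protein_id=pid,
                signal_peptide_predicted=signal,
                n_fragments_planted=k,
                n_confident_planted=n_conf,
                expected_accepted=n_conf >= required,
            )
        )

    for p in precursors:
        _emit(p.id, p.mature_sequence, signal=True)
    for i in range(spec.n_nonsecreted_proteins):
        seq = _mature_with_scaffold(rng, int(rng.integers(80, 200)), 0)
        _emit(f"CELL{i + 1:03d}", seq, signal=False)
    for i in range(spec.n_decoy_proteins):
        pid = f"DECOY{i + 1:03d}"
        seq = _mature_with_scaffold(rng, int(rng.integers(80, 200)), 0)
        frags = [f for f in tryptic_digest(seq) if len(f) >= 5] or [seq]
        for pep in rng.choice(frags, size=min(3, len(frags)), replace=False):
            psm_rows.append(
                dict(protein_id=pid, peptide=pep, confidence=float(rng.uniform(50, 90)))
            )
        truth_rows.append(
            dict(
                protein_id=pid,
                signal_peptide_predicted=False,
                n_fragments_planted=0,
                n_confident_planted=0,
                expected_accepted=False,
            )
        )
    return pd.DataFrame(psm_rows), pd.DataFrame(truth_rows)


def paralysis_probability(dose: float, pd50: float, slope: float) -> float:
    """Logistic response in log10 dose: P = expit(slope * log10(dose/PD50))."""
    if dose <= 0:
        return 0.0
    eta = slope * (math.log10(dose) - math.log10(pd50))
    return 1.0 / (1.0 + math.exp(-eta))


def generate_dose_response(
    spec: SyntheticVenomSpec, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Binomial paralysis counts at each dose and timepoint."""
    rng = rng if rng is not None else spec.rng()
    rows = []
    for timepoint, (pd50, slope) in spec.pd50_truth:
        for dose in spec.doses:
            p = paralysis_probability(dose, pd50, slope)
            rows.append(
                dict(
                    dose=dose,
                    n_injected=spec.n_per_dose,
                    n_paralysed=int(rng.binomial(spec.n_per_dose, p)),
                    timepoint=timepoint,
                )
            )
    return pd.DataFrame(rows)


def generate_expression(
    spec: SyntheticVenomSpec,
    n_records: int = 56,
    rng: Optional[np.random.Generator] = None,
    exact: bool = True,
) -> pd.DataFrame:
    """Paired (intensity, expression) abundances at a target correlation.

    Values are log-normal; the Pearson correlation on the log10 scale is
    controlled.  With ``exact=True`` (default) the drawn sample is rotated
    so its sample correlation equals the target exactly — the planted value
    is then recoverable from a single table.  With ``exact=False`` the pair
    is drawn i.i.d. from a bivariate normal with *population* correlation
    equal to the target, so the sample value fluctuates as in a real study.
    """
    rng = rng if rng is not None else spec.rng()
    r = spec.expression_correlation_target
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation target must lie in [-1, 1]")
    u = rng.standard_normal(n_records)
    w = rng.standard_normal(n_records)
    if exact and n_records >= 3:
        u = (u - u.mean()) / u.std()
        w = w - w.mean()
        w -= u * (w @ u) / (u @ u)  # orthogonalize against u
        w /= w.std()
        v = r * u + math.sqrt(max(0.0, 1.0 - r * r)) * w
    else:
        v = r * u + math.sqrt(max(0.0, 1.0 - r * r)) * w
    intensity = 10.0 ** (5.0 + 0.8 * u)
    expression = 10.0 ** (3.0 + 0.6 * v)
    return pd.DataFrame(
        dict(
            entity_id=[f"ENZ{i + 1:03d}" for i in range(n_records)],
            family_label=["enzyme"] * n_records,
            precursor_count_intensity=intensity,
            expression=expression,
        )
    )
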