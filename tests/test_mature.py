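"""Mature-form enumeration and intact-mass reconciliation."""

import itertools

import numpy as np
import pytest

from asilidvenom.masses import ModificationSet, peptide_mass
from asilidvenom.mature import (
    Condition,
    EnumerationParams,
    MassPeak,
    Precursor,
    Provenance,
    enumerate_candidates,
    match_candidates,
)
from asilidvenom.reference import DOLOPUS_PEPTIDES, predicted_native_mass
from asilidvenom.synthetic import FamilyProfile, SyntheticVenomSpec, generate_mass_lists, generate_precursors

SIGNAL = "MKTFVLLALVAGVLA"  # 15-residue signal peptide


def _precursor(mature, domains=(), pid="P1", family="F"):
    return Precursor(
        id=pid, sequence=SIGNAL + mature, signal_end=len(SIGNAL), family=family, domains=domains
    )


class TestEnumeration:
    def test_n_terminal_heterogeneity_covers_known_subforms(self):
        """Trimming two N-terminal residues of the 33-mer mature region
        yields the observed 31-mer subform."""
        full = "KNDRECKKIAEVCYRHEECCSFQCPSYWGKCVS"
        p = _precursor(full)
        cands = enumerate_candidates(p, EnumerationParams(max_n_trim=2, max_c_trim=0))
        seqs = {c.sequence for c in cands}
        assert full in seqs
        assert "DRECKKIAEVCYRHEECCSFQCPSYWGKCVS" in seqs

    def test_no_trims_single_candidate(self):
        p = _precursor("ACDEFGHIK")
        cands = enumerate_candidates(
            p, EnumerationParams(max_n_trim=0, max_c_trim=0, allow_pyroglu=False)
        )
        assert len(cands) == 1
        assert cands[0].provenance is Provenance.SIGNAL_CLEAVED
        assert cands[0].sequence == "ACDEFGHIK"

    def test_candidate_count_formula(self):
        """Count = 1 (full) + n_trims + c_trims + n_domains + pyroGlu variants."""
        mature = "ACDEFGHIKLMNPSTVWYAAAA"
        s = len(SIGNAL)
        domains = ((s + 2, s + 8), (s + 8, s + 12), (s + 12, s + 16), (s + 16, s + 20))
        p = _precursor(mature, domains=domains)
        params = EnumerationParams(max_n_trim=3, max_c_trim=2, allow_pyroglu=True)
        cands = enumerate_candidates(p, params)
        # no candidate starts with Q here, so no pyroGlu variants
        assert len(cands) == 1 + 3 + 2 + 4

    def test_pyroglu_variant_emitted_for_gln_start(self):
        p = _precursor("QDCNPEGARCSSDSDCCYSECIGSLCQP")
        cands = enumerate_candidates(p, EnumerationParams(max_n_trim=0, max_c_trim=0))
        pyro = [c for c in cands if c.mods.pyroglu]
        assert len(pyro) == 1
        assert pyro[0].provenance is Provenance.PYROGLU_VARIANT

    def test_predicted_mass_consistent_with_slice(self):
        p = _precursor("ITCDLIGNERLCVLHCLAKGFRGGWCDGRKVCNCRR")
        for c in enumerate_candidates(p):
            assert c.sequence == p.sequence[c.start:c.end]
            assert c.predicted_mass == pytest.approx(peptide_mass(c.sequence, c.mods))

    def test_missing_signal_annotation_rejected(self):
        p = Precursor(id="X", sequence="MKTACDEFGHIK", signal_end=None)
        with pytest.raises(ValueError, match="signal"):
            enumerate_candidates(p)

    def test_no_duplicate_candidates(self):
        p = _precursor("QACDEFGHIKLM", domains=((len(SIGNAL), len(SIGNAL) + 12),))
        cands = enumerate_candidates(p)
        keys = [(c.start, c.end, c.mods) for c in cands]
        assert len(keys) == len(set(keys))


def _brute_force_max_matching(candidates, peaks, tolerance):
    """Oracle: maximum-cardinality candidate-peak assignment by enumeration."""
    edges = [
        (i, j)
        for i, p in enumerate(peaks)
        for j, c in enumerate(candidates)
        if abs(p.mass - c.predicted_mass) <= tolerance
    ]
    best = 0
    for r in range(len(edges), 0, -1):
        for combo in itertools.combinations(edges, r):
            if len({i for i, _ in combo}) == r and len({j for _, j in combo}) == r:
                return r
    return best


class TestMatching:
    def test_known_native_peak_matches_with_expected_delta(self):
        rec = DOLOPUS_PEPTIDES[0]  # most abundant CS-alpha/beta peptide
        p = _precursor(rec.sequence, pid=rec.name)
        cands = enumerate_candidates(p, EnumerationParams(0, 0))
        peak = MassPeak(4057.87, 100.0, Condition.NATIVE)
        matches = match_candidates(cands, [peak], tolerance=0.15)
        assert len(matches) == 1
        assert matches[0].delta == pytest.approx(4057.87 - predicted_native_mass(rec), abs=1e-6)
        assert matches[0].delta == pytest.approx(-0.10, abs=0.05)

    def test_exact_peak_gives_zero_delta(self):
        p = _precursor("ACDEFGHIK")
        cands = enumerate_candidates(p, EnumerationParams(0, 0))
        peak = MassPeak(cands[0].predicted_mass, 1.0)
        (m,) = match_candidates(cands, [peak], tolerance=0.15)
        assert m.delta == 0.0

    def test_planted_candidates_and_decoys(self):
        """10 planted masses + 5 decoys >=1 Da away: all 10 matched, 0 decoys;
        matches the brute-force maximum assignment."""
        rng = np.random.default_rng(7)
        cands = []
        peaks = []
        base = 2000.0
        for k in range(10):
            seq = "".join(rng.choice(list("ADEFGHIKLMNPQRSTVWY"), size=20 + k))
            c = enumerate_candidates(
                _precursor(seq, pid=f"P{k}"), EnumerationParams(0, 0, allow_pyroglu=False)
            )[0]
            cands.append(c)
            peaks.append(MassPeak(c.predicted_mass + rng.normal(0, 0.02), float(rng.uniform(1, 100))))
        true_masses = [c.predicted_mass for c in cands]
        for k in range(5):
            while True:
                m = float(rng.uniform(1500, 4000))
                if min(abs(m - t) for t in true_masses) >= 1.0:
                    break
            peaks.append(MassPeak(m, float(rng.uniform(1, 100))))
        matches = match_candidates(cands, peaks, tolerance=0.15)
        assert len(matches) == 10
        assert len(matches) == _brute_force_max_matching(cands, peaks, 0.15)
        matched_peaks = {id(m.peak) for m in matches}
        assert all(id(p) in matched_peaks for p in peaks[:10])

    def test_partial_injection_and_permutation_invariance(self):
        rng = np.random.default_rng(11)
        cands = []
        for k in range(6):
            seq = "".join(rng.choice(list("ADEFGHIKLMNPQRSTVWY"), size=18))
            cands.append(
                enumerate_candidates(
                    _precursor(seq, pid=f"Q{k}"), EnumerationParams(0, 0, allow_pyroglu=False)
                )[0]
            )
        peaks = [MassPeak(c.predicted_mass + 0.01, float(i + 1)) for i, c in enumerate(cands)]
        peaks.append(MassPeak(cands[0].predicted_mass + 0.02, 50.0))  # competing peak
        ref = match_candidates(cands, peaks, tolerance=0.15)
        assert len({id(m.peak) for m in ref}) == len(ref)
        assert len({id(m.candidate) for m in ref}) == len(ref)
        for perm_seed in (1, 2, 3):
            prng = np.random.default_rng(perm_seed)
            c2 = list(cands)
            p2 = list(peaks)
            prng.shuffle(c2)
            prng.shuffle(p2)
            got = match_candidates(c2, p2, tolerance=0.15)
            key = lambda ms: sorted((m.candidate.precursor_id, round(m.peak.mass, 6)) for m in ms)
            assert key(got) == key(ref)

    def test_empty_inputs_give_empty_output(self):
        assert match_candidates([], [], tolerance=0.1) == []

    def test_planted_form_recovery_on_synthetic_venom(self):
        """>=95% of 100 planted mature forms are matched back to the correct
        precursor interval at 0.02 Da noise and 0.15 Da tolerance."""
        spec = SyntheticVenomSpec(
            seed=42,
            families=(
                FamilyProfile("F6", 50, 6, (27, 60), composition_share=50.0),
                FamilyProfile("F4", 25, 4, (30, 50), composition_share=25.0),
                FamilyProfile("F0", 25, 0, (40, 80), composition_share=25.0),
            ),
            n_decoy_peaks=20,
        )
        rng = spec.rng()
        precursors, truth = generate_precursors(spec, rng)
        native, _ = generate_mass_lists(truth, spec, rng)
        cands = []
        for p in precursors:
            cands.extend(enumerate_candidates(p))
        matches = match_candidates(cands, native, tolerance=0.15)
        expected = {
            row.id: (row.signal_end, row.signal_end + len(row.mature_seq))
            for row in truth.itertuples()
        }
        correct = sum(
            1
            for m in matches
            if m.candidate.provenance is Provenance.SIGNAL_CLEAVED
            and expected.get(m.candidate.precursor_id) == (m.candidate.start, m.candidate.end)
        )
        assert correct >= 95


def test_published_measured_masses_reconcile(peptide_records):
    """Every repertoire peptide with a printed untreated measured mass
    matches its sequence at 0.15 Da, except the one internally inconsistent
    record, which must NOT match."""
    for rec in peptide_records:
        if rec.measured_native is None:
            continue
        delta = rec.measured_native - predicted_native_mass(rec)
        if rec.measured_inconsistent:
            assert abs(delta) > 0.15
        else:
            assert abs(delta) <= 0.15
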