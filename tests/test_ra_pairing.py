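"""Native vs reduced/alkylated pairing and cysteine counting."""

from collections import Counter

import numpy as np
import pytest

from asilidvenom.masses import default_constants, shift_to_ncys
from asilidvenom.mature import Condition, MassPeak
from asilidvenom.rapairing import pair_conditions, select_top_peaks
from asilidvenom.synthetic import SyntheticVenomSpec, generate_mass_lists, generate_precursors

SHIFT = default_constants()[1].per_cys_ra_shift


def _peaks(masses_intensities, condition=Condition.NATIVE):
    return [MassPeak(m, i, condition) for m, i in masses_intensities]


class TestTopPeakSelection:
    def test_top_n_within_range(self):
        rng = np.random.default_rng(3)
        peaks = _peaks(
            [(float(m), float(i)) for m, i in zip(rng.uniform(200, 20000, 200), rng.uniform(1, 1000, 200))]
        )
        top = select_top_peaks(peaks, top_n=50, mass_range=(1000, 10000))
        assert len(top) == 50
        assert all(1000 <= p.mass <= 10000 for p in top)
        floor = min(p.intensity for p in top)
        excluded = [p for p in peaks if 1000 <= p.mass <= 10000 and p not in top]
        assert all(p.intensity <= floor for p in excluded)
        # sorted by descending intensity
        assert all(a.intensity >= b.intensity for a, b in zip(top, top[1:]))

    def test_fewer_in_range_than_top_n(self):
        peaks = _peaks([(1500.0, 1.0), (2500.0, 2.0), (50.0, 99.0)])
        top = select_top_peaks(peaks, top_n=50, mass_range=(1000, 10000))
        assert len(top) == 2

    def test_equal_intensity_tie_breaks_by_mass(self):
        peaks = _peaks([(3000.0, 5.0), (2000.0, 5.0)])
        top = select_top_peaks(peaks, top_n=2, mass_range=(1000, 10000))
        assert [p.mass for p in top] == [2000.0, 3000.0]


class TestPairing:
    def test_known_six_cysteine_pair(self):
        """The measured native/RA pair of the most abundant venom peptide
        (4057.87 / 4328.04) is assigned six cysteines."""
        native = _peaks([(4057.87, 100.0)])
        ra = _peaks([(4328.04, 90.0)], Condition.REDUCED_ALKYLATED)
        result = pair_conditions(native, ra, tolerance=0.10)
        assert len(result.assignments) == 1
        a = result.assignments[0]
        assert a.n_cys == 6
        assert a.delta == pytest.approx(270.17, abs=0.01)
        assert a.native_rank == 1 and a.ra_rank == 1

    def test_peak_without_partner_is_unmatched(self):
        native = _peaks([(5000.0, 10.0)])
        ra = _peaks([(5100.0, 10.0)], Condition.REDUCED_ALKYLATED)
        result = pair_conditions(native, ra, tolerance=0.10)
        assert not result.assignments
        assert len(result.unmatched_native) == 1
        assert len(result.unmatched_ra) == 1

    def test_each_ra_peak_used_at_most_once(self):
        native = _peaks([(4000.0, 10.0), (4000.05, 9.0)])
        ra = _peaks([(4000.0 + 6 * SHIFT, 5.0)], Condition.REDUCED_ALKYLATED)
        result = pair_conditions(native, ra, tolerance=0.10)
        assert len(result.assignments) == 1
        # the more intense native peak claims the single RA partner
        assert result.assignments[0].native_mass == 4000.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        masses = rng.uniform(1500, 9000, 12)
        ncys = rng.choice([0, 4, 6, 8], 12)
        native = _peaks([(float(m), float(i)) for m, i in zip(masses, rng.uniform(1, 100, 12))])
        ra = _peaks(
            [
                (float(m + n * SHIFT + rng.normal(0, 0.01)), float(i))
                for m, n, i in zip(masses, ncys, rng.uniform(1, 100, 12))
            ],
            Condition.REDUCED_ALKYLATED,
        )
        ref = pair_conditions(native, ra, tolerance=0.1)
        for seed in (1, 2):
            prng = np.random.default_rng(seed)
            n2, r2 = list(native), list(ra)
            prng.shuffle(n2)
            prng.shuffle(r2)
            got = pair_conditions(n2, r2, tolerance=0.1)
            assert sorted((a.native_mass, a.ra_mass, a.n_cys) for a in got.assignments) == sorted(
                (a.native_mass, a.ra_mass, a.n_cys) for a in ref.assignments
            )

    def test_matches_brute_force_oracle(self):
        """Greedy pairing equals an exhaustive all-pairs scan on small lists
        across many seeds."""

        def oracle(native, ra, tol):
            nat = sorted(native, key=lambda p: (-p.intensity, p.mass))
            pool = sorted(ra, key=lambda p: (-p.intensity, p.mass))
            used, out = set(), []
            for p in nat:
                cands = []
                for k, q in enumerate(pool):
                    if k in used:
                        continue
                    n = shift_to_ncys(q.mass - p.mass, tol)
                    if n is None or (n > 0 and q.mass < p.mass):
                        continue
                    cands.append((abs(q.mass - p.mass - n * SHIFT), k, n))
                if cands:
                    resid, k, n = min(cands)
                    used.add(k)
                    out.append((p.mass, pool[k].mass, n))
            return sorted(out)

        for seed in range(30):
            rng = np.random.default_rng(seed)
            nn, nr = rng.integers(3, 20), rng.integers(3, 20)
            native = _peaks(
                [(float(m), float(i)) for m, i in zip(rng.uniform(1000, 9000, nn), rng.uniform(1, 100, nn))]
            )
            ra = _peaks(
                [
                    (float(m + rng.choice([0, 4, 6, 8]) * SHIFT + rng.normal(0, 0.02)), float(i))
                    for m, i in zip(rng.uniform(1000, 9000, nr)[: len(native)], rng.uniform(1, 100, nr))
                ],
                Condition.REDUCED_ALKYLATED,
            )
            got = pair_conditions(native, ra, tolerance=0.1)
            assert sorted((a.native_mass, a.ra_mass, a.n_cys) for a in got.assignments) == oracle(
                native, ra, 0.1
            )

    def test_planted_shifts_recovered_over_many_trials(self):
        """Planting n x per-Cys shifts always returns n when the tolerance is
        at least 3x the mass noise (100 trials)."""
        for trial in range(100):
            rng = np.random.default_rng(1000 + trial)
            n = int(rng.choice([0, 4, 6, 8]))
            m = float(rng.uniform(1500, 8000))
            noise = rng.normal(0, 0.01, 2)
            native = _peaks([(m + noise[0], 10.0)])
            ra = _peaks([(m + n * SHIFT + noise[1], 10.0)], Condition.REDUCED_ALKYLATED)
            result = pair_conditions(native, ra, tolerance=0.06)
            assert len(result.assignments) == 1
            assert result.assignments[0].n_cys == n


def test_scenario_17_6cys_2_4cys_2_unchanged(venom_spec):
    """The default synthetic venom (17 six-Cys, 2 four-Cys, 2 linear
    peptides among 29 decoys per condition) is fully resolved by the
    top-50 / 1-10 kDa pairing."""
    rng = venom_spec.rng()
    _, truth = generate_precursors(venom_spec, rng)
    native, ra = generate_mass_lists(truth, venom_spec, rng)
    result = pair_conditions(
        select_top_peaks(native, 50, (1000, 10000)),
        select_top_peaks(ra, 50, (1000, 10000)),
        tolerance=0.1,
    )
    counts = Counter(a.n_cys for a in result.assignments)
    assert counts == {6: 17, 4: 2, 0: 2}
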