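"""Predict intact masses of a disulfide-rich venom peptide.

The most abundant Dolopus genitalis venom peptide is a 36-residue
CS-alpha/beta defensin with six cysteines (three disulfide bonds).  Its
native mass, its mass after reduction + hydroxyethyl alkylation (RA), and
the per-cysteine RA shift are all predictable from the sequence alone.
"""

from asilidvenom import ModificationSet, default_constants, peptide_mass, ra_mass

seq = "ITCDLIGNERLCVLHCLAKGFRGGWCDGRKVCNCRR"  # U-Asilidin12-Dg3a

native = peptide_mass(seq, ModificationSet(n_disulfides=3))
after_ra = ra_mass(seq)
shift = default_constants()[1].per_cys_ra_shift

print(f"native (3 disulfides): {native:.2f} Da")   # ~4057.94, measured 4057.87
print(f"after RA:              {after_ra:.2f} Da")  # ~4328.14, measured 4328.04
print(f"RA - native:           {after_ra - native:.2f} Da = 6 x {shift:.3f}")
# The ~270.2 Da difference is the fingerprint of six cysteines: +1 H per
# opened half-cystine and +C2H4O per hydroxyethyl cap.
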