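"""Reconcile precursor-derived mature-form hypotheses with observed masses.

A precursor's mature region may appear in venom as the full signal-cleaved
chain, N/C-trimmed subforms, excised domains, or a pyroglutamate variant.
Here the 33-residue ICK peptide and its 31-residue N-trimmed subtype are
both recovered from their observed native masses.
"""

from asilidvenom import (
    EnumerationParams,
    MassPeak,
    Precursor,
    enumerate_candidates,
    match_candidates,
)

precursor = Precursor(
    id="Dg10",
    sequence="MKTFVLLALVAGVLA" + "KNDRECKKIAEVCYRHEECCSFQCPSYWGKCVS",
    signal_end=15,
    family="Asilidin-1",
)
candidates = enumerate_candidates(precursor, EnumerationParams(max_n_trim=4, max_c_trim=2))
print(f"{len(candidates)} candidate mature forms")

observed = [MassPeak(3921.57, 78.0), MassPeak(3679.45, 11.0)]  # measured masses
for m in match_candidates(candidates, observed, tolerance=0.15):
    c = m.candidate
    print(f"  peak {m.peak.mass:8.2f} -> residues {c.start}-{c.end} "
          f"({c.provenance.value}), predicted {c.predicted_mass:8.2f}, "
          f"delta {m.delta:+.3f} Da")
# Both peaks land on the correct intervals: the full mature form and the
# subform starting two residues later (the Dg10a/Dg10b pair).
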