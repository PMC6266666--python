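"""Protein identification from tryptic-fragment evidence.

A protein is accepted with >=3 distinct tryptic fragments above 95%
confidence, or >=2 when a secretion signal peptide was predicted for it.
"""

from asilidvenom import PSMRecord, accept_identification, tryptic_digest

print("digest:", tryptic_digest("AKRPGKDDCSR"))  # no cleavage before proline

psms = [
    PSMRecord("Dg21", "SDFCPEVCPLLYKPVCGSYGDIK", 99.0),
    PSMRecord("Dg21", "ANCKFGEAWEK", 97.2),
    PSMRecord("Dg21", "ANCKFGEAWEK", 96.1),  # duplicate spectrum, counts once
]
for signal in (False, True):
    d = accept_identification(psms, signal_peptide_predicted=signal)
    print(f"signal={signal}: {d.n_confident_distinct_fragments} distinct "
          f"confident fragments -> accepted={d.accepted}")
# 2 distinct fragments reject the protein without a signal peptide but
# accept it with one: secretion evidence lowers the required fragment count.
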