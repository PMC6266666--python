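# Methods

## Mass model

All masses are neutral monoisotopic daltons. The residue table is the
standard 20 canonical monoisotopic residue masses to 5 decimal places
(glycine 57.02146 … tryptophan 186.07931), water 18.01056. The unmodified
baseline of `peptide_mass` is the fully reduced, free-thiol linear chain;
modifications are purely additive deltas:

| modification | delta (Da) | chemistry |
|---|---|---|
| disulfide bond | −2.01566 per bond | loss of 2 H |
| pyroglutamate (from N-terminal Gln) | −17.02655 | loss of NH3 |
| hydroxyethyl cap (iodoethanol) | +44.02621 per Cys | gain of C2H4O |
| reduction of a half-cystine | +1.00783 per Cys | gain of 1 H |

The per-cysteine reduction/alkylation (RA) shift relative to the oxidized
native form is 45.03404 Da. Constants live in a single JSON config
(`asilidvenom/data/mass_constants.json`) and alternate conventions can be
injected via `load_constants`; the disulfide delta is kept exactly equal to
−2× the reduction delta so that opening bonds and counting per-cysteine
shifts are mutually consistent.

Native venom peptides are assumed fully oxidized (⌊nCys/2⌋ disulfides)
unless overridden: disulfide-rich venom peptides are secreted in their
folded, oxidized state, and the uniform RA shifts observed across the
repertoire support it. Pyroglutamate from Glu (−18.01 Da) is not
implemented; only the Gln form occurs in the data this package targets.
Isotope patterns, average masses and charge-state deconvolution are out of
scope — input peak lists are already neutral monoisotopic.

The published predicted masses of the *D. genitalis* repertoire reproduce
within 0.05 Da with these constants but sit uniformly ≈ 0.03–0.04 Da below
the printed values, and the printed 6-Cys RA−native difference is 270.18 Da
where these constants give 270.204. Two 2-decimal roundings plus a slightly
different constant set in the original processing software explain the gap;
0.05 Da is therefore the reproduction tolerance rather than exact equality.
Two repertoire records (the ICK Dg29 and Kazal domain 4 of Dg51) have
printed *measured* native masses ≈ 0.89 Da above their own predicted
values (consistent with deamidation or a transcription slip); they are
flagged `measured_inconsistent` and excluded from measured-mass
reconciliation, while their predicted masses participate normally.

## Cysteine counting by RA pairing

`select_top_peaks` keeps the `top_n` (default 50) most intense peaks in
1–10 kDa (ties broken toward lower mass); `pair_conditions` then visits
native peaks in descending intensity and lets each claim the unused RA peak
whose shift best matches an allowed cysteine count (default {0, 4, 6, 8} —
the scaffolds present in asilid venom peptides). A candidate shift is
accepted when its residual from n × 45.034 Da is within the tolerance
(default 0.1 Da); ties in `shift_to_ncys` break toward the smaller count
(within 1e-9 Da, absorbing float rounding). Each RA peak satisfies at most
one native peak — one molecular species yields one shifted product — and
"unchanged" (0-Cys) pairs require the same mass in both lists within
tolerance. By default the RA partner must itself survive the top-N filter;
passing the full RA list to `pair_conditions` searches outside the top
ranks instead (CLI `--search-full-ra`).

## Mature-form enumeration and matching

Coordinates are 0-based half-open on the precursor translation; the signal
peptide occupies `[0, signal_end)`. Enumeration emits the signal-cleaved
chain, N-terminal truncations up to `max_n_trim` (default 4) and
C-terminal truncations up to `max_c_trim` (default 2) of it — trims are
not combined — each annotated domain interval (for multidomain Kazal-type
precursors), and a pyroglutamate variant of any candidate starting with
Gln. The trim defaults cover the 2-residue N-terminal subtype
heterogeneity seen in real repertoires with margin.

Matching is greedy: peaks in descending intensity order (ascending mass on
ties) each claim the best unused candidate within tolerance — smallest
|observed − predicted|, then fewer modifications, then the longer
candidate, with interval coordinates as the final deterministic tie-break.
The result is a partial injection, invariant to input permutations. The
default intact-mass tolerance is 0.15 Da — wider than fragment-level search
tolerances because printed predicted/measured gaps on intact deconvoluted
masses reach ≈ 0.13 Da. Greedy intensity-ranked assignment mirrors how
abundance-ranked peak lists are read in practice; tests compare it against
a brute-force maximum assignment on small instances.

## Identification rule

"Detected tryptic fragments" are distinct peptide sequences (not spectra),
counted when confidence is strictly greater than the threshold (default
95%). Acceptance requires 3 such fragments, or 2 when a secretion signal
peptide is predicted for the precursor; signal-peptide status is an input
flag, and fragments shared between homologous precursors count for every
protein whose PSM table lists them. The bundled tryptic digester cleaves
C-terminal to K/R except before P and enumerates missed-cleavage fragments
in N→C order; it exists so synthetic PSM tables can be generated, and is
cross-checked in tests against an independent regex-based cleaver.

## Nomenclature

Percent identity is computed on full precursor sequences by global
alignment maximizing matches (match 1, mismatch 0), with an infinitesimal
gap cost (−1e-6) that breaks ties toward compact alignments so the
alignment length — the identity denominator — is deterministic. Subtypes
are single-linkage clusters at strictly > 90% identity: members share one
ordinal and take letters a, b, c… in discovery order; singleton clusters
are letterless by default. Ordinals are unique per species across all
families, increasing with the discovery order of each cluster's first
member.

## PD50 estimation

The dose–response model is binomial with a logistic link on log10 dose
(probit optional) — the standard quantal-assay formulation; the PD50 is
10^(−β0/β1) and its 95% CI comes from delta-method propagation of the GLM
covariance on the log10 scale. Requires ≥ 3 distinct positive doses.
Complete separation (every dose all-or-none) admits no finite slope: the
fit is flagged unstable and the PD50 is reported as the interval between
the highest fully non-paralysing and lowest fully paralysing dose, with
the geometric midpoint as the point value. A helper converts venom
concentration to per-fly dose at the 2.1 μL injection volume of the
microapplicator, and `per_gram` normalises per-animal doses by body mass
(the μg/g figures quoted for blowflies imply a 25 mg fly).

Correlation between expression and proteomic intensity is Pearson's r with
the two-sided t-transform p-value (n − 2 df), on raw values by default
with a log10 option, since published values of this statistic rarely state
the transform.

## Synthetic-data generator

Defaults emulate the peptide repertoire of an asilid venom study: six
families — a dominant 2-member 6-Cys CS-α/β-like family containing a > 90%
identity subtype pair, a 6-member 6-Cys ICK-like family, 5- and 4-member
6-Cys Kazal/peritrophin-like families, a 2-member 4-Cys family and a
2-member linear family — 21 true peptides (17 × 6-Cys, 2 × 4-Cys,
2 × 0-Cys), with 29 decoy masses per condition so the native top-50 list
holds exactly 50 peaks. Composition shares (30/25/15/10/10/10%) are split
over members with log-normal jitter (σ = 0.3). Sequences are drawn
uniformly from the 19 non-cysteine residues and cysteines are inserted at
random non-adjacent positions, giving exact scaffold control.

Mass noise is additive Gaussian, default SD 0.02 Da (0.01 Da in the
cysteine-census scenario) — sub-tolerance, so planted recovery is
well-posed while tie-breaking is exercised. Decoys are drawn uniformly in
1–10 kDa but rejected within 1 Da of any true mass *or any allowed
cysteine-shift image of an existing peak*, so decoys are inert: they can
displace peaks in the top-N ranking but never form a valid pair. PSM
confidences are Gaussian (mean 98, SD 2, clipped to [0, 100]) over 1–5
distinct tryptic fragments per true protein; non-secreted proteins
exercise the 3-fragment branch and decoy proteins carry only 50–90%
confidences. Dose–response counts are binomial draws from the logistic
model at the published PD50s (15.58 / 3.07 / 1.16 μg per fly at 5 s /
1 min / 60 min, slope 2.5) over doses 0.5–16 μg, 20 flies per dose.

The expression generator plants the target Pearson correlation (default
0.51, n = 56) on the log10 scale. By default the drawn Gaussian pair is
orthogonalized and rotated so the *sample* correlation equals the target
exactly, making the planted value recoverable from a single table — at
n = 56 the sampling SD of r under i.i.d. draws is ≈ 0.1, so a population-
level target would not be identifiable from one table. `exact=False`
switches to i.i.d. bivariate-normal sampling with the target as the
population correlation, used for null-distribution checks.

All generators consume a single `numpy.random.Generator` seeded from the
spec (seed mandatory), in a fixed stream order (precursors → mass lists →
PSMs → dose–response → abundance when run as a pipeline), so a seed fully
determines every output.

### What the generator does not emulate

Real deconvolution artefacts (isotope mis-picks, adducts, charge-state
errors), correlated mass errors, ragged-terminus mixtures at partial
intensity, homologous-fragment sharing across proteins, and overdispersed
(non-binomial) assay counts. Passing tests therefore demonstrate that the
inference logic is correct under the stated noise model, not that the
pipeline is robust to every instrument pathology.

## Problem sizes in tests

Simulation-based tests use 21–100 planted peptides, 150–200 seeds for the
PD50 and correlation recovery checks, and ≤ 20-peak lists for brute-force
oracle comparisons; the full suite runs in a few seconds on one CPU.

## Known limitations

- Only pyroGlu-from-Gln, disulfides and hydroxyethyl adducts are modelled;
  other PTMs must be supplied as `custom_deltas`.
- Greedy matching is not globally optimal under heavy peak overlap; the
  brute-force oracle in tests bounds the difference on small instances.
- Identity-based subtype clustering is O(n²) pairwise alignments — fine
  for repertoires of hundreds, not for proteome-scale inputs.
- PD50 CIs rely on the asymptotic GLM covariance; with very few partial-
  response doses they can undercover.
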