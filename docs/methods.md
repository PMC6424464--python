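# Methods

## Scope and model

`photosite` implements the data-analysis half of a middle-down LC-MS/MS
photoaffinity-labeling experiment on a membrane receptor: given subunit
sequences, an adduct registry and centroided LC-MS/MS runs, it finds
candidate photolabeled transmembrane peptides at the MS1 level, localizes
the covalent adduct to a residue or minimal residue interval from b/y
fragment ladders at the MS2 level, quantifies labeling efficiency and
competition from extracted-ion-chromatogram (XIC) areas, and maps
localized residues onto annotated binding-site clusters.  A companion
module computes the standard two-electrode voltage-clamp summary
quantities (potentiation response ratio, direct activation, constitutive
open probability).  A synthetic-data generator emits runs with known
ground truth so every stage is testable end to end without instrument
data.

All masses are monoisotopic; ions are positive-mode [M+zH]z+ with proton
mass 1.00728 Da and water 18.01056 Da.  The residue table ships as package
data (5-decimal values) rather than being hard-coded per call site, and
the chemistry section of a JSON config can override residues,
modifications and adducts.

## Chemistry conventions

* **Digestion.** Trypsin cleaves C-terminal to K or R but not before P
  (the conventional proline exception), with up to a configurable number
  of missed cleavages (default 3).  Peptides carry 1-based inclusive
  protein coordinates taken from the FASTA record as given; local-to-
  protein conversion is pure offset arithmetic.
* **Adduct registry defaults.** KK123 +372.16, KK200 +462.27, KK202
  +500.31, KK123 with light click tag +672.4322 and heavy tag +682.44 Da.
  The heavy/light doublet spacing defaults to the difference of the tag
  masses (10.0078 Da); a nominal 10.07 Da spacing sometimes quoted for
  this tag pair is available as an explicit override because the two
  conventions disagree at the second decimal.  Back-calculating the
  printed KK123-labeled precursor from its m/z suggests an effective
  adduct mass nearer 372.27 than the registry's 372.16; the registry
  keeps the search-parameter value and the ~0.03 m/z residual is absorbed
  by the worked-example tolerance.
* **Cys alkylation.** NEM is +125.04768 Da.  The NEM+DTT adduct has no
  universally printed mass; the default +279.05994 Da (sum of the NEM and
  DTT monoisotopic additions) is a convention of this package and is
  overridable in config.
* One photoreagent adduct per peptide; average masses, isotope fine
  structure, non-tryptic enzymes and cross-links are out of scope.

## MS1 screening

Candidates are enumerated as (digest peptide x adduct x charge)
theoretical precursors.  For each, the XIC within ±30 ppm (default) is
extracted and local maxima above an intensity floor (5x the median
nonzero XIC intensity — scale-free, so screening is invariant to global
intensity rescaling) become features, with bounds at the nearest flanking
minima and trapezoidal areas.  A candidate is kept when the labeled
feature's apex elutes at least 1.0 min (default) after the unlabeled
peptide's apex — covalent sterol addition increases hydrophobicity, so
labeled peptides elute later on reversed phase; the direction is firm,
the magnitude is not, hence a deliberately permissive default against a
generator default shift of 10 min.  Candidates with no detectable
unlabeled reference are kept but flagged `no_reference`.

Heavy/light click-tag doublets are sought among equal-charge features
whose neutral-mass difference matches the tag spacing within the
precursor ppm tolerance (absolute floor 0.01 Da) and whose apexes
co-elute within 0.2 min — "identical retention" is interpreted as apex
agreement within this tolerance.  Pairing is greedy by smallest combined
normalized mass + retention error with ascending-m/z tie-break, each
feature joining at most one pair, which makes the result deterministic
under permutation of the feature list.  The light/heavy intensity ratio
is recorded but never filtered on (1:1 mixing is typical but not
guaranteed).

## MS2 localization

For a peptide of length L with one adduct, every placement 1..L is a
candidate.  Fragment masses follow the standard b/y formulas (b_i = sum of
the first i residues + z protons; y_i adds water), with positioned fixed
modifications counted when they fall inside the fragment span and the
adduct counted when the placement does.  Fragment charges 1..min(z−1, 3)
are considered; fragment matching is ±0.1 Da absolute (no ppm mode at
MS2); a/x/c/z ions are not generated.

Each theoretical ion is looked up at both its plain and adduct-shifted
mass.  Matches then pass **competitive peak assignment**: a peak supports
only the ion form(s) that explain it with the smallest mass error, so an
ion that is coincidentally isobaric with another fragment's peak (within
the 0.1 Da window this is common enough to matter) cannot manufacture
site evidence.  Surviving matches are classified:

* **adduct-bearing** (adduct-shifted mass): constrains the site to the
  fragment's residue span;
* **neutral loss**: a plain-mass match whose adduct-bearing counterpart
  (same series/index/charge) is also matched — the intact ion exists, so
  the plain peak is its adduct loss; it supports peptide identity with
  zero localization weight;
* **adduct-free** (plain-mass match, no counterpart): excludes the
  fragment's span.

If no adduct-bearing ion matches at all, the spectrum carries no
positional evidence — a precursor known to bear the adduct whose
fragments all appear at unmodified masses has lost the adduct everywhere
— and the whole peptide [1, L] is reported.  This resolution of the
plain-mass ambiguity is a design choice of this package: the three rules
cannot be applied per ion in isolation because an adduct-free and a
neutral-loss ion are the same peak.

Each placement is scored by the number of *distinct peaks* matching ions
consistent with it (distinct peaks, so isobaric ions sharing a peak are
recorded but never double-counted).  The result is the minimal interval
covering all placements of maximal score: ties widen the interval rather
than force an arbitrary residue, which is how a three-residue stretch or
an either/or residue pair is reported when the bracketing ions are
missing.  One-sided evidence (only a constraining ion, or only
exclusions) is accepted and yields the correspondingly wider interval.
Bracketing "site-defining" pairs — adjacent same-series ions whose adduct
status flips — are reported alongside.  A precursor m/z inconsistent with
peptide+adduct raises a warning, not a rejection.

Heavy/light overlay verification re-matches the assigned ladder in both
spectra and demands that every common adduct-bearing fragment shift by
(tag spacing)/charge within tolerance and every common adduct-free
fragment stay put; a fragment found at the *wrong* position (unshifted
where a shift is expected, or vice versa) falsifies the assignment, and
no common fragment at all is inconclusive and reported `inconsistent`.

## Quantification

Labeling efficiency = 100 x (labeled XIC area) / (unlabeled XIC area),
compared at the same charge state (the charge with the largest unlabeled
feature area) to avoid ionization-efficiency confounds between charge
states; no correction is attempted for ionization differences between
labeled and unlabeled forms — the metric is a raw area ratio.  Areas are
trapezoidal integrals between feature bounds; standalone chromatogram
integration subtracts a constant 10th-percentile baseline (robust,
deterministic, adequate for ratio quantities) and clips negatives.  An
undetected labeled feature gives 0% flagged `not_detected`; a missing
unlabeled reference is an error (no denominator).  Competition
(protection) is the percent reduction of the arm-mean efficiency,
reported with per-arm mean ± SD and n, plus per-replicate reductions;
inferential statistics are deliberately out of scope.

## Synthetic-data generator

The generator is the study-conditions oracle, not a tuning knob.  MS1
scans are emitted on a fixed grid (default 0.05 min, a 3-s survey cycle)
with Gaussian elution profiles (default sigma 0.2 min, a realistic
nano-LC peak width); the labeled form appears at the adduct-shifted mass
with amplitude ratio = efficiency/100 (equal widths, so the area ratio
equals the configured efficiency exactly) and apex shifted by +10 min by
default — a fixed shift rather than a hydrophobicity regression, since
only the direction of the shift is established.  Paired species split the
labeled amplitude 1:1 (configurable) between light and heavy forms offset
by (tag spacing)/z.  One MS2 spectrum per labeled species (two when
paired) is emitted at the labeled apex: each ladder ion appears with
probability = completeness (default 0.8), adduct-bearing ions gain a
plain-mass neutral-loss duplicate with the configured fraction (default
0.3 — neutral loss is prominent for sterol adducts), and noise peaks
(default 10) are uniform in m/z over 100–2000 with log-uniform intensity
below the base peak.  Configured efficiencies in tests span 0.06–3.0%,
the experimentally observed range.  Output is byte-deterministic under a
fixed seed.

What the generator does *not* emulate — isotope envelopes, profile-mode
peaks, chimeric MS2, mass-calibration drift, detector saturation,
ionization suppression — bounds what passing tests show: they validate
the tolerance logic, the localization combinatorics and the ratio
arithmetic, not robustness to real-instrument artifacts.

The ephys table generator draws per-cell signed currents (−60 mV
convention: GABA-elicited responses negative, the picrotoxin shift of the
holding current positive) from normal distributions truncated at zero for
magnitudes, so configured ratio quantities round-trip exactly at zero SD
and are recovered to within sampling error otherwise.

## Electrophysiology summaries

Potentiation ratio = I(GABA+modulator)/I(GABA); direct activation =
I(modulator alone)/I(saturating GABA + propofol), reported as a fraction
(a flag switches the denominator to saturating GABA alone, since both
conventions appear in practice; the propofol-anchored one is the
default); P_o,const = I_PTX/(I_PTX − I_GABA+propofol), applied literally
to signed currents, which places it in [0, 1] under the stated sign
convention.  Summaries are mean ± SD (n−1) with n per construct; a single
cell reports SD 0 with n = 1 flagged.

## Cluster reporting

Cluster assignment is a pure sequence-coordinate lookup against a TSV
annotation; the shipped table encodes the three clusters of the
alpha1/beta3 receptor study (beta3(+)/alpha1(−) intersubunit: beta3
L294 and G308/R309; alpha1 intrasubunit: N408 and Y415; beta3
intrasubunit: Y442 and VKA 278–280).  The VKA stretch appears elsewhere
with an alternative numbering (226–228); the annotation uses 278–280 and
notes the conflict.  Intervals intersecting no annotation are
`unassigned`; several clusters, `ambiguous` with the list.  No 3-D
structure handling is performed.

## Numerical choices and problem sizes

Tolerances: 30 ppm precursor, 0.1 Da fragment, 0.2 min co-elution,
0.01 Da doublet floor, 1e-9 on competitive-assignment error ties.
The test suite exercises the oracle-equivalence sweep at 1,000 random
peptides (length ≤ 12), site recovery at 500 seeded trials (completeness
0.6, 20 noise peaks) plus 100 noise-free trials, and efficiency recovery
over 20 runs spanning 0.06–3.0%; these sizes keep the full suite in a few
seconds while the binomial margins stay comfortable.

## Known limitations

Centroid data only; no isotope-envelope charge inference, no untargeted
feature discovery, no FDR control against decoys, no cross-run alignment,
no open modification search, and at most one adduct per peptide.  The
competitive peak-assignment rule assumes the best mass explanation is the
true one; with exact isobars (equal error) both interpretations are kept,
which can widen intervals on adversarial inputs.
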