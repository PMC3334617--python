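# Methods

## Model and assumptions

The package analyses paired-condition LC-MS experiments in which one
condition is metabolically labeled with ¹⁵N. Its working assumptions:

- High-resolution, centroided MS1 (Orbitrap-class, ~1 ppm mass
  precision); unit-resolution MS2 (ion trap) is sufficient because
  precursor mass and nitrogen count carry the discriminating
  information.
- Tryptic digestion (cleavage after K/R, not before P), fixed
  carbamidomethylation of cysteine (+57.02146 Da). The carbamidomethyl
  group is reagent-derived, so its nitrogen is never ¹⁵N-labeled: it
  adds mass but does not contribute to the labeling shift.
- Labeling is high but possibly incomplete: each nitrogen of a heavy
  peptide is ¹⁵N independently with probability `e` (the enrichment),
  giving a binomial envelope of satellites spaced `0.99703489341 / z`
  below the fully labeled monoisotopic peak.
- A light/heavy pair of one peptide shares its charge state and
  co-elutes approximately; small retention shifts between channels are
  absorbed by the pairing rule (candidate apex anywhere within the query
  XIC's span — deliberately asymmetric, as a candidate trace may be
  shorter than the query).

Isotope constants: Δ¹⁵N = 0.99703489341 Da, Δ¹³C = 1.00335483781 Da per
unit, d = Δ¹³C − Δ¹⁵N = 0.0063199444 Da. The distinguishability limit
`floor((d / p) × 10⁶ / z)` gives the highest m/z at which an instrument
of precision `p` ppm can tell a one-unit ¹⁵N spacing from a ¹³C spacing
(6319 at 1 ppm, z = 1; 1579 at z = 4). Above the limit the ambiguity is
resolved conservatively: a neighbour at either spacing is treated as a
¹³C neighbour, trading sensitivity for specificity.

## Stage-by-stage procedure and numerical choices

**XIC detection** (`xic.extract_xics`). Greedy most-intense-first
seeding; each XIC grows scan-by-scan in both directions, collecting the
nearest unclaimed peak within `tol_ppm` of the running intensity-weighted
mean m/z and tolerating up to `max_gap_scans` consecutive missing scans.
Peaks are claimed exclusively, so the peak partition is disjoint.
Intensity ties in seeding break to lower m/z, making extraction fully
deterministic. Defaults: `tol_ppm = 4` (comfortably above the ~0.3 ppm
error of a trace-averaged m/z at 1 ppm per-peak precision), `min_scans =
3`, `max_gap_scans = 1`.

**Charge assignment** (`xic.assign_charge`). The charge is the *largest*
z in `charge_range` (default 1–4) with a co-eluting neighbour at
`mz + Δ¹³C/z`. Largest-z-first is deliberate: isotope spacings alias
downward, never upward — a true charge-2 envelope always shows its
second ¹³C satellite at exactly the charge-1 spacing, so "smallest ppm
error" degenerates to a coin flip between the true z and its alias,
while a true low-z species has no peak at any tighter spacing. The
neighbour must carry at least 10% of the query's apex intensity
(`satellite_intensity_ratio`): a genuine +1 satellite of a tryptic
peptide holds ≳25% of its parent (n_C × 0.0107 for n_C ≥ 25), so faint
chance co-elutions cannot set the charge.

**Monoisotopic classification** (`xic.classify_isotope_status`). Exactly
the positive/negative ¹³C-neighbour rule: a negative-shift neighbour at
any tested z demotes the XIC to an isotope peak; otherwise a
positive-shift neighbour makes it monoisotopic; with neither it is
"¹⁵N or undetermined". Below the distinguishability limit, a neighbour
at the ¹⁵N spacing is *not* counted as a ¹³C neighbour — this is what
keeps incompletely-labeled envelopes from masking the heavy
monoisotopic peak. One guard augments the printed rule: a negative-shift
neighbour only demotes when its apex intensity is ≥ 50% of the query's
(`parent_intensity_ratio`). Physically a +1 ¹³C satellite is always
smaller than its parent below ~93 carbons (i.e. everywhere in tryptic
bottom-up data), so an intense XIC cannot be the satellite of a faint
one; without the guard, chance co-elutions of other peptides' faint
satellites demote a few percent of true monoisotopic XICs. Note that
incomplete-labeling satellites themselves classify as monoisotopic under
this rule (they have a positive ¹³C neighbour and no negative one);
they are "monoisotopic" in the pairable sense and almost always remain
unpaired because their implied mass matches no database entry.

**Pairing** (`pairing.pair_xics`). Monoisotopic XICs with known charge
are visited in decreasing intensity order. The neutral mass
`(mz − 1.00727646688) × z` queries both databases at ±3 ppm; every
returned nitrogen count N nominates one candidate position (upward for
an unlabeled-database hit, downward for a labeled one). A candidate XIC
must match the position within ±3 ppm, share the charge, and have its
retention apex inside the query's span. Exactly one distinct candidate
XIC across all nominations forms a pair (candidate multiplicity is
counted over XICs, not database entries); two or more mark the query
multiply coupled. Passes repeat until no pair forms, so an ambiguity can
resolve once a competing candidate has been consumed — multiply-coupled
XICs are re-evaluated, never force-paired. Requiring equal charge is an
addition over the bare rule: a ¹⁴N/¹⁵N pair of one peptide necessarily
shares z, and the restriction removes cross-charge coincidences.

**MS/MS search** (`msms_search`). Theoretical spectra are singly
protonated b/y ladders (doubly charged ladders added for precursor
charge ≥ 3); labeled ladders shift each fragment by its own residue
nitrogen sum × Δ¹⁵N. Score: `(M/L) × Σ log₂(I_m)` with L theoretical
peaks, M matched peaks (nearest observed peak within ±0.5 Da, each
observed peak used once); matched intensities below 2 contribute log₂ =
0 but still count toward M, preventing negative contributions from
sub-unit intensities. Precursor window ±10 ppm. With a pair-derived
nitrogen constraint, same-mass candidates with a different nitrogen
count are removed before scoring. Spectra on unpaired monoisotopic XICs
are searched against both databases without the constraint; the best
score sets sequence and label (ties prefer unlabeled and are flagged).
Spectra on non-monoisotopic XICs gain a secondary attachment to the
nearest co-eluting monoisotopic XIC at a positive k × Δ¹⁵N/z shift.

**FDR** (`msms_search.estimate_qvalues`). Concatenated reverse decoys
(whole-protein reversal before digestion, preserving cleavage-site
statistics). The estimator is D/T: FDR(s) = #decoys ≥ s / #targets ≥ s,
with tied scores counted as one threshold group; q-value = minimum FDR
over thresholds at or below the PSM's score, guarded to 1 when no
target clears a threshold. Exact score ties between a target and a
decoy rank the decoy first: an ambiguous best match must surface as
estimated contamination rather than a free identification. Acceptance
is peptide-level (best PSM per sequence/label) at q ≤ 0.01; decoys are
never reported.

**Quantification** (`quant`). Pair ratio = log₂ of the configured
numerator channel's area over the other (`orientation` makes forward
and label-swap designs one code path; a swap negates true log₂ ratios).
Measurements of one peptide across charge states and fractions are
collated to a median; protein ratio = median of per-peptide medians
(median-of-medians rather than pooled measurements — robust to one
charge state dominating). CVs are computed on linear-scale ratios with
the sample standard deviation. Peptides mapping to more than one
protein are excluded from rollup by default (`count_in_all` optional).
Split-half consistency and replicate correlation use Spearman rank
correlation with average-rank ties; the split is seeded and
bit-reproducible.

## The synthetic-data generator

`synthetic.simulate_run` emulates exactly the features the method
reasons about: Gaussian elution profiles (sd 0.08 min) sampled on a
regular MS1 grid (0.03 min), natural ¹³C envelopes on both channels,
binomial incomplete-labeling envelopes on the heavy channel
(enrichment 0.98 by default), independent per-peak m/z error
(sd 1 ppm), per-scan multiplicative log-normal intensity noise
(CV 0.1), and top-7 data-dependent MS2 with 0.3-min dynamic exclusion.
MS2 spectra are idealized b/y ladders plus uniform noise peaks —
sufficient to exercise scoring and FDR, not instrument-realistic.

The canonical study conditions are 50 random proteins × 6 clean tryptic
peptides (7–13 residues, neutral mass ≤ 1450 Da; charge 2 below
1250 Da, else 3), true protein log₂ ratios ~ N(0, 1.5), 15-min
gradient. The mass cap and charge rule keep every species below the
4-ppm distinguishability limit for its charge, mirroring how the real
instrument's ~1-ppm precision kept real peptides below theirs.

Channel normalisation: heavy-channel isotopologue weights are
normalised to the fully labeled species, so the configured ratio is
carried by the monoisotopic pair — the quantity the method actually
measures — and the incomplete-labeling satellites add heavy-channel
signal on top. (Normalising total channel area instead would build a
deterministic e^N bias into every recovered ratio that only a
partial-labeling ratio correction — out of scope here — could remove.)
The truth manifest records the per-species areas actually emitted.

What the simulator does *not* emulate, hence what passing tests do not
show about real data: chromatographic drift between channels beyond an
optional fixed offset, peak-shape asymmetry, ²H/¹⁸O/³⁴S fine structure,
co-fragmentation chimeras, charge states above 3, variable
modifications, and realistic MS2 fragmentation intensities.

## Benchmarks

`benchmarks.fdr_calibration` checks that the decoy-estimated q ≤ 0.05
cutoff delivers a realised false-discovery proportion of ~0.05 under
spectrum-level target/decoy competition with a 50/50 mixture of true
and null spectra (n = 2000). Note that the *marginal* fraction of
targets reaching q ≤ 0.05 under a complete null is near zero, not 0.05:
with equal target/decoy counts from one distribution the running D/T
ratio hovers near 1 at every threshold.

`benchmarks.nitrogen_constraint_benchmark` demonstrates the specificity
gain of the nitrogen constraint. Under ¹⁵N labeling, an Asn→Asp variant
of a peptide is an exact doppelganger at ion-trap tolerance: its
labeled precursor differs by 0.013 Da (inside ±10 ppm above ~1302 Da)
and every labeled fragment by the same 0.013 Da — only the nitrogen
count (one fewer) separates them. The benchmark injects such variants
as decoy entries so every undecidable match is visible to the FDR
estimate: without the constraint the search collapses under its own
ambiguity; with it (wrong-N candidates filtered before scoring) the
identifications return.

`benchmarks.label_swap_study` runs forward and label-swapped replicates
of one ground truth end to end and correlates their ratio tables after
negation.

## Known limitations

- Chimeric XICs (two species within the extraction tolerance) are
  attributed entirely to the dominant species; no envelope demixing is
  attempted. Rarely (~1 pair per 300 peptides, seed-dependent) two
  incomplete-labeling satellites of different peptides satisfy the
  database-mass + shifted-position + co-elution test and form a
  spurious pair — the known mis-pairing failure mode of this family of
  methods.
- The reported ratio is the monoisotopic pair-area ratio; no correction
  for incomplete labeling or envelope truncation is applied.
- The mzML layer is compact by design: plain or indexed mzML 1.1,
  gzip, 32/64-bit float arrays, zlib or no compression. Vendor raw
  formats and mzIdentML export are out of scope.
- Fixed modifications only; one enzyme; no semi-tryptic search.
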