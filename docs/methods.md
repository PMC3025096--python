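# Methods

## Scope and model of the experiment

The package analyses a two-condition shotgun phosphoproteomics design: whole
lens extracts from one normal and one cataractous human lens, trypsin
digested, phosphopeptide-enriched, and run on a nanoLC Q-TOF instrument over
a 120-min gradient with data-dependent acquisition in the m/z 400–1600 full
scan window. Identification is assumed to have been done upstream by a search
engine; the package consumes its outputs (scored target/decoy PSM tables and
per-run identification lists) together with centroided MS1 feature tables,
and produces FDR-filtered identification sets, phosphosite-level abundance
fold-changes, and catalog summary statistics.

## Peptide chemistry

Masses are monoisotopic throughout. The residue table carries the 20 standard
residues; the physical constants are water 18.010565 Da, proton 1.007276 Da,
phosphorylation +79.966331 Da (S/T/Y only), Met oxidation +15.994915 Da —
community-standard values, chosen because they reproduce observed Q-TOF m/z
within instrument error. A peptide's neutral mass is the residue sum plus one
water plus modification deltas; m/z = (M + z·proton)/z. Digestion follows
the trypsin rule — cleave after K or R, suppressed before proline — with
fragments reported in 1-based inclusive parent coordinates and 0..k missed
cleavages enumerated combinatorially; the N-terminal Met is retained, since
the packaged catalogs number sites on the Met-included sequence. Site
designations (`Ser-19`) are derived as fragment start + within-peptide
offset − 1.

m/z concordance checks assume one phosphate per catalog row (every
differential-catalog row lists a single site). For Met-containing peptides
the check additionally scans 0..#Met oxidations and reports the count that
minimises the absolute deviation: oxidation is a variable modification in
the upstream search, and three catalog rows are only consistent with one
oxidised Met (deviations of +15.99/z otherwise). Tolerances: the packaged
catalog values are *observed* m/z, so concordance is judged at ±0.05 Th in
bulk (median < 0.02 Th) and ±0.02 Th for the two benchmark rows; the largest
bulk deviation observed is ≈0.035 Th.

## Target-decoy FDR

The estimator is D/T — decoy matches over target matches above the score
threshold, with a *strict* inequality at the cut — matching a separate decoy
search design (one search against targets, one against a same-size decoy
database). The 2D/(T+D) concatenated-search variant is deliberately not
used. Decoy generation offers deterministic per-protein reversal (default)
and seeded shuffling; both preserve length and residue composition.
`threshold_for_fdr` scans observed target scores ascending and returns the
smallest score whose passing set (score ≥ candidate, i.e. the strict cut
just below it) achieves the requested FDR, so ties resolve toward the larger
passing set. Degenerate cases signal distinct errors: no passing targets
(undefined FDR) and unreachable alpha.

The calibration claim tested is unbiasedness: with false matches split
50/50 between targets and decoys, the passing decoy count and the passing
false-target count are exchangeable binomial draws, so the pooled decoy
estimate is compared to the pooled true false proportion within the 95%
interval for the *difference* of two binomial counts (comparing one count
against the other's confidence interval alone would reject a perfectly
calibrated estimator far more often than the nominal rate).

## Retention-time alignment

Each run is aligned to a reference run (by default the first control run)
using anchors: peptides identified in both runs, pairing their identified
elution times. The model is a linear map plus additive segment corrections.
The linear part is a Theil–Sen fit (median of pairwise slopes) rather than
ordinary least squares: local chromatographic shifts affecting a minority of
anchors tilt an OLS line, smearing the shift across the whole gradient,
whereas the robust line leaves local aberrations to the segment stage. With
exactly two anchors both estimators reduce to the interpolating line.
Segment corrections are the median residual of anchors falling in each
10-min window of the reference gradient (zero where a window has no
anchors); 10 min balances resolution against anchor sparsity on a 120-min
gradient. Under simulated distortions (slope 0.95–1.05, intercept ±2 min, up
to three ≤0.6-min bumps, 0.05-min anchor jitter, ≥50 anchors) the
post-correction median absolute residual stays below 0.1 min.

Inversion (needed for cross-assignment) inverts the linear part exactly and
subtracts the segment offset looked up at the reference-side time; this is
approximate at segment boundaries but exact in the interior, and XIC windows
(±1 min) dwarf the approximation error.

## Quantitation

The global peptide list is keyed by sequence + modification positions +
charge — two charge states of one peptide are distinct entries, as in the
packaged differential catalog. Consensus m/z is the median of observations;
entries whose observations disagree by more than the match tolerance are
flagged. For each entry and run the expected apex is the identified time in
that run, or the median reference-frame time mapped back through the run's
alignment (flagged cross-assigned). The XIC collects points within ±0.05 Th
and ±1.0 min (sized to Q-TOF mass accuracy and to peak width ≈ 0.1 min σ on
this gradient) and is integrated trapezoidally; one-point or empty traces
count as zero area. Condition abundance is the mean over replicate runs —
single-replicate conditions are the expected case here — and the fold-change
is case/control, reported only when both sides have signal. No between-run
intensity normalisation is applied by default (the upstream design describes
none); a total-ion-current scaling option exists but is off.

## Synthetic data

The generator reproduces the study conditions rather than a configurable
benchmark: one normal and one cataract run, 120-min gradient, m/z 400–1600
acceptance window. Defaults, chosen once: 50 phosphopeptides drawn from
tryptic digests of 20 random proteins (uniform residue composition, length
150–400), one phosphosite per peptide on a random S/T/Y, charge 2+ with
probability 0.6 else 3+, peptides closer than 0.12 Th in m/z rejected to
keep XICs unambiguous; apex times uniform over the gradient with a 5-min
margin; control amplitudes log-normal (ln-mean 11.5, ln-sd 0.5, i.e. ~10^5
counts); true ratios log-uniform on [0.25, 4] — two-fold regulation both
ways with headroom, matching the differential catalog's ratio range; case
runs distorted by slope 1.02, intercept −0.5 min and a +0.4-min bump on
[40, 60) min; chromatographic peaks Gaussian with σ = 0.1 min sampled every
0.01 min (~80 points/peak, enough for 1%-accurate trapezoidal areas);
per-point multiplicative log-normal noise with unit mean at CV 10%;
identification dropout 10% with 0.02-min identified-RT jitter; PSM scores
true N(60, 12) and false N(25, 8) with half the false matches landing on
decoys. All randomness flows from one mandatory seed through a single
`numpy` generator, so outputs are bit-reproducible.

What the simulator does *not* model — isotope envelopes, co-eluting
interference beyond the m/z separation guard, MS2 spectra, nonlinear
gradient warps, intensity-dependent dropout — bounds what the recovery tests
show: they validate the pipeline's arithmetic and its robustness to the
modelled distortions and noise, not performance on matrix effects or
chimeric spectra in real data.

## Numerical and degenerate-input choices

Fold classification is inclusive (≥2.0 increased, ≤0.5 decreased) with
median aggregation over multiple observations of one site; median is
order- and multiplicity-invariant. Site uniqueness is (accession,
designation). Catalog validation warns and never drops: the packaged full
catalog contains one internally inconsistent published row (aldolase C,
designation Ser-26 against fragment 116–129), preserved as printed.
Residue percentages are reported both at 0.1% precision (71.2/24.7/4.1 on
the full catalog) and nearest-integer; the integer tyrosine share is 4%.
The catalog's historical 15-up/13-down split is not reproducible from the
printed ratios under any strict two-fold boundary (this pipeline's rule
gives 14/12/2) and is treated as a documented discrepancy. Empty catalogs,
inverted fragment ranges, nonpositive ratios, charges < 1, unknown residues,
modifications on disallowed residues, inverted or out-of-gradient XIC
windows, and degenerate anchor sets are all rejected with specific errors.

## Problem sizes

The test suite and analysis scripts run on deliberately small instances:
50-peptide simulations (~16k feature points across two runs), 100-replicate
PSM calibrations at 400 PSMs each, and 50-sequence digestion oracles. These
sizes already give sub-3% quantitation error and stable calibration
statistics; the machinery itself is vectorised and scales linearly in
points and peptides.
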