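# Methods

## Exact masses and adduct m/z

Monoisotopic element masses and natural abundances are embedded as
constants (IUPAC 2021 values for H, C, N, O, S, Se, Na, P).  The
*monoisotopic* mass of an element is defined as the mass of its most
abundant natural isotope; for every tabulated element except selenium this
is also the lightest isotope, while for selenium it is Se-80
(79.9165218 Da).  Ion m/z applies an electron correction of one electron
mass (5.4858×10⁻⁴ Da) per unit of charge:

    m/z = (M_neutral + M_adduct − z·m_e) / |z|

Both conventions are forced by the printed values: all six reported ion
masses (156.077, 198.124, 333.123, 230.096, 317.128, 381.067) reproduce at
three decimals only with the electron correction (the uncorrected
selenium sulfoxide cation rounds to 381.068) and only with Se-80 as the
selenium principal isotope.  Whether the original vendor software applied
the electron correction to its theoretical envelopes is not documented;
we apply it uniformly and note the ~1 mDa ambiguity, far below the 0.01 Da
envelope merge resolution.

## Isotope envelopes

The envelope of an ion is the convolution of per-element isotope
distributions.  Each element's distribution for *n* atoms is computed
exactly as a multinomial expansion over isotope compositions; element
distributions are then convolved pairwise, dropping species below 10⁻¹⁵
abundance.  After conversion to m/z, centroids closer than
``merge_window`` (default 0.01 Da) are merged single-linkage into their
abundance-weighted mean — i.e. fine structure (e.g. ¹³C vs ²H
substitutions, 2.9 mDa apart) is collapsed to one centroid per nominal
isotopologue, matching unit-resolution display — and species below
``prune`` (default 10⁻⁵) of the total are removed before renormalizing
abundances to sum to 1.  Correctness is checked against an independent
brute-force enumeration over all per-atom isotope assignments (test
suite), which agrees to 10⁻⁹ abundance for formulas up to 20 atoms.

Envelope similarity is a cosine: peaks of the two envelopes are paired
greedily by ascending m/z distance within ``mz_tol`` (default 0.01 Da),
unmatched peaks contribute zeros, and the score is the normalized dot
product of the paired abundance vectors — bounded in [0, 1] and symmetric.
An ``align_base`` mode first shifts one envelope so the base peaks
coincide, which is how an S-form peak is tested against the Se-form
envelope of the same scaffold.  The aligned S-vs-Se cross score is ≈0.87:
both envelopes are dominated by their base peak, so no plain cosine can
drive the cross score near zero, but 0.87 is cleanly separated from
self-match scores (≥0.999 on generated data) — the verification threshold
``min_score`` is therefore set at 0.95, between the two populations.

## Synthetic instrument model

The generator emulates the study's 30-min HILIC gradient on an
Orbitrap-class instrument with MS1 centroid scans every 0.05 min (≥8
points across a 0.08-min-sigma peak, enough for stable trapezoidal
integration).  For each metabolite with a positive ground-truth amount it
emits a Gaussian elution profile (apex at the published retention time,
default σ = 0.08 min) whose total XIC area is

    area = amount × response_factor × lognormal(σ=response_cv)
                 × lognormal(σ=run_scale_cv, shared per run)

with ``response_factor`` defaulting to 4.4×10⁹ area units per mol for all
compounds (cross-compound response is unknown; only EGT is calibrated
absolutely, so equal response is the neutral default and the value is
chosen so pipeline-normalized areas land near the published normalized
peak-area matrix).  ``response_cv`` (default 2 %) models per-compound
response variability; ``run_scale_cv`` (default 10 %) is a shared
injection/extraction scale factor that hits analytes and internal
standards alike and is exactly the variation internal-standard
normalization is designed to cancel.  Within each scan the ion's
theoretical isotope envelope (pruned at 10⁻⁴) is emitted with each
centroid's m/z jittered by a relative error of σ = 2 ppm, and random noise
centroids are added (Poisson rate 20 per scan, uniform over m/z 100–600,
exponential intensities of mean 1).  Internal standards (10 nmol HEPES and
PIPES per metabolome sample; 250 pmol each in calibration injections) are
emitted identically.  All randomness derives from one seed plus a CRC of
the run identity, so a fixed seed yields byte-identical output.

Ground-truth amounts are anchored to the published data: deletion-panel
amounts are the printed normalized areas divided by the response factor;
overexpression amounts derive from the published intracellular
concentrations (0.3 / 32.4 / 181.2 / 1606.3 µM for WT / P81 / P41 / P3
under vegetative growth) through the cell-count and volume model below;
selenium-panel and time-course amounts encode the qualitative structure of
the study (Se branch only in egt1⁺-competent strains; trace selenoneine
<1 % of EGT in starved WT; elevated hercynylselenocysteine — and no
selenium sulfoxide intermediate — when egt2 is deleted; monotone EGT
accumulation over 20 days of starvation with a 5-day saturation constant).
Vegetative samples are 40 ml at 3.3×10⁶ cells/ml; starved samples 40 ml at
10⁷ cells/ml.

What the generator does *not* emulate: retention-time drift, ion
suppression and matrix effects, detector saturation, profile-mode peak
shapes, MS2 spectra, and intensity-dependent centroid mass error.  Passing
tests therefore demonstrate the pipeline's correctness on idealized
centroid data with known truth, not robustness to every artifact of real
chromatography.

## Targeted quantification

XICs sum centroid intensities within ±``tol_ppm`` (default 5 ppm,
Orbitrap-class accuracy consistent with 3-decimal m/z reporting) of the
target m/z, one point per scan with zeros kept.  Peak integration searches
±``rt_window`` (default 0.5 min) around the expected retention time; the
apex is the highest point that also shows minimal chromatographic width
(≥3 consecutive scans above 5 % of the apex), which rejects single noise
centroids.  Peaks are declared not detected when no such apex exceeds
``min_snr`` (default 3) times a robust baseline (median + 1.4826·MAD of
the whole trace).  Bounds extend from the apex down to the local baseline,
bridging up to two consecutive dropout scans (a 2 ppm-jittered centroid
falls outside a 5 ppm window ~1.2 % of the time, leaving spurious zeros);
interior zeros are filled by a log-quadratic fit through neighbouring
points (a Gaussian peak is a parabola in log intensity) before trapezoidal
integration.  Because the extraction window captures essentially only the
monoisotopic peak while the compound's signal is spread over its envelope,
measured areas are divided by the theoretical envelope fraction inside the
window; this keeps the single-compound (EGT) calibration applicable across
targets with different envelopes, most importantly S vs Se compounds.

Internal-standard normalization implements the weighted contribution of
the two spiked standards as a weighted mean of per-standard recovery
ratios, scale = Σₛ wₛ·(refₛ/obsₛ), default weights 0.5/0.5 (the weighting
scheme is not further specified in the source protocol; equal weights are
the symmetric default and are exposed in configuration).  Reference areas
can be taken from a designated reference run or, the pipeline default,
from the known spike amounts times a nominal response — the latter keeps
normalized areas comparable between metabolome samples (10 nmol spikes)
and calibration injections (250 pmol spikes).  A standard that is not
detected makes the run unusable (error), and normalized areas are exactly
invariant under any global intensity rescaling of a run.

The calibration curve is fitted by least squares in log₁₀–log₁₀ space —
over a series spanning seven orders of magnitude a linear-space fit would
be dominated entirely by the top point; the fitted slope on generated data
is ~1, i.e. a power law indistinguishable from proportionality.  The model
stores its fitted amount range and R²; inversion of areas outside the
range carries an extrapolation warning, and zero areas map to zero with a
not-detected flag.  Intracellular concentration is
amount / (n_cells × V_cell), with V_cell = 148.5 µm³ for vegetative cells
and 1/3 or 2/3 of that under nitrogen or glucose starvation respectively;
overexpression strains are vegetative and use the full volume.

## Pathway calling

Each mutant row of the strain × metabolite matrix is classified against
the same-condition wild-type row: ratio ≤ ``absent_frac`` (default 0.05)
→ absent; ≥ ``accum_fold`` (default 5) → accumulated; ≤ 0.5 → reduced;
otherwise normal; both values ≈ 0 → normal.  The source study reports
presence/absence and accumulation qualitatively, so these numeric cutoffs
are this package's own, configurable defaults; status assignment is
monotone in the mutant value.  The pathway is modelled as the two-step
chain (step 1, *egt1⁺*: histidine → hercynine → hercynylcysteine
sulfoxide; step 2, *egt2⁺*: sulfoxide → EGT) with the selenium branch
(hercynine → hercynylselenocysteine → selenoneine) evaluated
independently, so a strain can be blocked on one branch only.  The blocked
step is the earliest whose product is absent or reduced while its
substrate is normal or accumulated — "reduced" products count as block
evidence because residual flux exists (hercynylcysteine sulfoxide converts
to EGT slowly even without Egt2, via PLP chemistry).  Contradictory
chains (a downstream metabolite normal above an absent upstream one) are
flagged inconsistent and produce no call.  Conditions are never pooled;
each (strain, condition) row yields its own call.

## File formats and numerical choices

Runs are written either as a centroid-list CSV
(``scan_rt_min,mz,intensity``) or as minimal centroided MS1 mzML
(uncompressed 64-bit float arrays, standard PSI-MS cvParams); the bundled
mzML reader (lxml-based) accepts 32/64-bit and zlib-compressed arrays and
second- or minute-valued scan times.  Scans are re-sorted (with a warning)
if unsorted; a file without MS1 scans is an error.  Degenerate inputs are
handled explicitly throughout: empty formulas have mass zero, charge-zero
envelopes and non-positive tolerances are errors, flat-zero XICs are not
detected with area exactly 0, and calibration requires ≥3 strictly
positive points with a positive slope.

## Problem sizes

Default analyses run the 9-run deletion panel (601 scans/run), the 8-point
calibration series, and 20-seed replicate suites for recovery and
Se-identity checks; these sizes give stable statistics (≥500 recovery
comparisons, ≥900 zero-truth detection decisions) while a full suite run
completes in well under a minute on one CPU.

## Known limitations

Absolute quantification assumes the analyte responds like the EGT
standard; real cross-compound response factors differ and would require
per-compound standards.  The block caller assumes a single lesion per
branch and reports ambiguity rather than resolving multi-hit genotypes.
Envelope verification compares shapes at unit resolution and cannot
exploit isotope fine structure.  The normalization's reference-response
mode presumes the nominal IS response is stable between batches; the
reference-run mode should be preferred when a batch drifts.
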