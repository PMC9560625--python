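# Methods

This note documents the models, parameter choices and numerical decisions
behind `zooms_screen`, and what the synthetic-data tests do and do not
demonstrate about real screening data.

## Spectral model and preprocessing

Spectra are singly-charged MALDI-ToF profiles over 700–3500 *m/z*; charge
deconvolution is out of scope, which is the usual situation for ZooMS
tryptic collagen fingerprints. Replicates of a sample are linearly
resampled onto a uniform grid (default step **0.02 Th**, well below the
~1 Th isotope spacing and fine enough that centroid accuracy is limited by
noise, not the grid) and averaged pointwise before peak picking. An
alternative would be to pick peaks per replicate and intersect the peak
lists; profile averaging was chosen because it also stabilises the
deamidation envelopes, and the per-replicate route offers no advantage for
the downstream marker matching at ±0.2 Th.

Processing chain and defaults:

- **Smoothing**: Savitzky–Golay, order 2, window spanning 0.2 Th
  (11 points at the default grid). A fractional pass count *c* is defined
  as ⌊*c*⌋ full passes plus a convex blend with one further pass
  (*c* = 1.5 → mean of the 1-pass and 2-pass outputs); the default is 1.5
  cycles. Negative excursions introduced by the polynomial fit are clipped
  to zero so the non-negativity invariant survives the chain.
- **Baseline**: the axis is cut into **100** equal segments; each segment
  anchors the baseline at its minimum (optionally raised by a configurable
  fraction of the segment's intensity range, default 0); the baseline is
  the piecewise-linear interpolation through the anchors and is subtracted
  with clipping at zero. Anchoring at minima means the corrected noise band
  sits slightly above zero — which is why S/N is *not* measured against the
  corrected trace (below).
- **Noise**: 1.4826 × the median absolute deviation around the local
  median, in 100 Th blocks, interpolated across block centres. The
  estimate is taken on the **raw profile before smoothing**: smoothing
  narrows the noise band by roughly the square root of the window length,
  and an S/N threshold applied against post-smoothing MAD would pass large
  numbers of noise maxima. The same raw-noise scale gates the deamidation
  fits.
- **Peak picking**: local maxima with S/N ≥ **3.5** and intensity ≥
  **0.5%** of the base peak. The centroid is the intensity-weighted mean of
  the contiguous points above **80%** of the apex ("picking height").
- **Deisotoping**: peaks spaced by **1.00235 Th** (average peptide isotope
  spacing, charge 1) within ±**0.05 Th** are clustered greedily from low
  *m/z*, with several clusters open simultaneously so interleaved envelopes
  separate. A peak that would extend a cluster beyond its third member with
  *rising* intensity starts a new cluster instead (overlapping-envelope
  split). The cluster head is the monoisotopic peak and carries the whole
  envelope.

## Marker database and assignment rules

Markers are data, not code: a TSV of (taxon, series, monoisotopic mass,
diagnostic flag) plus a second TSV of named ambiguity groups whose members
may themselves be groups (expanded recursively). Group-level rows — e.g. an
order-wide peptide registered under `Ungulata`, or the 1453.7-class peptide
registered directly under its multi-taxon category — let one row express
"present in every member". The shipped example table is illustrative; all
identification is relative to whatever table the user loads.

Assignment from the matched diagnostic markers (matching tolerance
**0.2 Th**, configurable; the non-diagnostic deamidation targets never
drive assignment):

1. score each label by its number of distinct matched diagnostic peaks;
2. a unique label with ≥ `min_diagnostic` (**2**) matches that strictly
   dominates all competitors is assigned directly — one diagnostic peptide
   is deliberately not enough for a species call;
3. tied leaders escalate to the smallest registered group covering them
   (aurochs/bison and bear/lynx resolve this way by construction);
4. a single matched diagnostic peak yields the group registered for that
   peptide and sets `needs_morphological_review` — the software never
   attempts the size/cortical-thickness exclusion a zooarchaeologist would
   apply, it only flags where that review is required;
5. labels that resolve only at order level yield that order label;
6. otherwise the sample is `undetermined`.

Ties are never broken by peak intensity: relative MALDI intensities are not
reliable abundance proxies across taxa, and escalation to a group is the
honest output. The batch success rate is `100 × determined / tested`,
rounded half-up to an integer.

## %Gln deamidation model

Deamidation converts a glutamine side-chain amide to a carboxylate; on
monoisotopic masses the elemental change +O −N −H adds **+0.98402 Da**
(the module computes the constant from NIST masses rather than hard-coding
it). Because the shift is ~0.016 Th below the +1 isotope spacing, the
native and deamidated envelopes of a target peptide interleave, and the
deamidated fraction must be deconvolved from the combined envelope.

The observed intensities at positions `mono + j·1.00235`, `j = 0..k`
(**k = 5** isotope positions plus one extra to capture the shifted
component), are modelled as `c·[α·E₀ + (1−α)·E₁]` with `E₀` the theoretical
envelope, `E₁` its copy displaced one position. The two non-negative
amplitudes are estimated by NNLS and `α = a/(a+b)`, clipped to [0, 1] —
a deterministic equivalent of stochastic optimisers used for this task,
guarded in the tests by a 0.001-step grid-search oracle. Residuals are
unweighted; with only six positions and multiplicative noise of a few
percent, weighting makes no measurable difference to recovery. `α` is
exactly invariant to intensity scaling.

A single deamidation event is modelled even for peptides with several Gln
sites: the 0–1 `%Gln` scale is precisely the two-component mixture weight,
and a multi-site model would not be identifiable from five isotope
positions. Envelopes come from an averagine composition scaled to the
peptide mass (elemental compositions can be stored per target and override
it); at these masses the averagine approximation changes the envelope by
far less than the noise level. The default targets are the collagen
peptides at *m/z* **1105.6** and **1706.7**, reported separately per
peptide (no pooling).

A fit is **usable** only when the first occupied envelope position has
S/N ≥ 3.5 against the raw-profile noise; for a fully deamidated sample that
position is the shifted monoisotopic peak, so α = 0 is still measurable.
Unusable fits are excluded from the site aggregates (n, mean, median,
2·sd/√n with sample sd; reported to 2 decimals). The extraction protocol
(acid demineralisation vs ambic-only) is carried as metadata and reported
alongside, but no correction is applied: protocol-induced deamidation is a
known confounder that belongs in interpretation, not in the estimator.

## Quantification conventions

Fragments are determinate (taxon + element), indeterminate (element only)
or unidentified. `determinate_pct` is 100 × NISP/NR rounded **half-up** to
one decimal; per-taxon %NISP uses the taxon's order-group NISP as
denominator while group %NISP uses total NISP — the two-level convention of
standard faunal tables — and whole-number percentages print without a
trailing ".0". Molecular determinations are added to the combined NISP
table only for specimens not already morphologically determined; conflicts
warn and morphology wins. MNI is deliberately out of scope (it needs
element/side/age conventions that are not part of the screening layer).

The selection filter keeps morphologically unidentified fragments > 2 cm
with visible trabeculae, known in-situ position and acceptable cortical
bone, under a 3-level taphonomy allowance (none / moderate = at most one of
{combustion, manganese, concretion} / heavy = any); "moderate" is the
default since screening practice tolerates scarce alteration.

## Synthetic data: what it does and does not emulate

The generator renders Gaussian peaks (constant width σ = 0.08 Th) with
theoretical isotope envelopes at every marker the chosen taxon inherits
from its lineage, the two deamidation targets as the α-mixture, a smooth
decaying polynomial baseline, and additive Gaussian noise; the peak scale
is set by a target monoisotopic S/N (default 20). Degradation is a single
mechanism: each marker (targets included) is dropped independently with a
configurable probability, optionally with raised noise. Everything is
reproducible from (seed, config).

This emulates the *observable* consequences of poor collagen preservation —
fewer surviving peptides, lower success rates, missing deamidation
envelopes — without modelling collagen chemistry, ToF resolution drift,
matrix clusters, adducts, calibration error or ionisation suppression.
Passing tests therefore demonstrate that the algorithms are correct under
the stated spectral model, not that the pipeline is robust to every
instrument artefact; with real spectra the matching tolerance and S/N
threshold are the parameters to revisit first. Default site presets span
dropout 0.69–0.90 and site-mean %Gln 0.38–0.29, the preservation range
typical of Middle–Upper Palaeolithic screening contexts.

Problem sizes used in the test suite and acceptance script — 100-sample
clean assemblages for taxon recovery, 50 samples per site over 10–20 seeds
for the degradation ordering, 50 noise draws per α level for %Gln recovery
— were chosen as the smallest sizes at which the binomial/recovery margins
are decisive.

## Known limitations

- Assignment quality is bounded by the marker table; the shipped table is
  a synthetic illustration, not a reference resource.
- No mass recalibration: systematic calibration error larger than the
  matching tolerance defeats identification.
- The %Gln estimator assumes the target peptide is not overlapped by an
  unrelated peptide within the matching tolerance.
- mzML support covers profile spectra with 32/64-bit float arrays (zlib or
  uncompressed); vendor raw formats are not read.
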