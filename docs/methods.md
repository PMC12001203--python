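# Methods

This note records the models, defaults and design choices behind the
package, and what the synthetic-data experiments do and do not demonstrate.

## Reaction-array enumeration

Routes are configuration data: an ordered list of stages, each naming a
reaction-SMARTS rule, the block list feeding each reactant slot, and the
molecular formula removed by the step (empty for pure additions).  Branched
routes hold parallel sub-routes whose product sets are combined by a final
merge stage, so a campaign like "two parallel two-step routes merged by
esterification" is expressible without code.

Correctness is defined as *mass bookkeeping*, not chemistry: for every
product the enumerator checks

    mono(product) = Σ mono(blocks) − Σ mono(leaving groups)   (tol 1e-6 Da)

and records violations per combination.  Whether a rule is synthetically
sensible is out of scope; rules that fail to apply to a combination are
reported as skipped, never fatal.  Combinations are visited in lexicographic
block-id order, so output tables are byte-reproducible.

Masses come from an internal, versioned isotope table (monoisotopic = most
abundant isotope; average = standard atomic weights) rather than from a
toolkit, so that the bookkeeping is self-contained; tests cross-check
against an independent implementation.  Adduct m/z is (M + Δ)/|z| with the
proton mass 1.007276466 Da; the adduct list is user configuration with
[M+H]+ as the only default, since positive-mode protonation is the one ion
every reaction-monitoring method accepts.

Racemic building blocks produce racemic products: stereoisomers that differ
only at unassigned centres collapse to a single flat-SMILES target (they
share a mass and hence a QC verdict), with the enantiomer SMILES kept in the
target's provenance.

Product-set clustering uses circular (Morgan) fingerprints, radius 2 and
2048 bits — the de-facto standard parameters, recorded in the dendrogram
metadata — with average linkage on 1 − Tanimoto.  Linkage is delegated to
scipy's agglomerative implementation; with real-valued Tanimoto distances
exact ties have measure zero, so no additional tie-breaking policy is
imposed.

## LC-MS quality control

The verdict pipeline is: TIC → peak finding → per-peak spectrum
aggregation → expected-ion matching → verdict.

- **Peak finding** thresholds prominence at 5% of the TIC maximum and width
  at 2 scans (both configurable); peak bounds are the prominence bases.
  Fractional thresholds transfer across instruments with different absolute
  intensity scales.
- **Aggregation** defaults to summing all centroids in the peak window,
  merged into clusters no wider than half the m/z tolerance
  (intensity-weighted m/z); this is robust to apex jitter.  Returning the
  apex scan alone is available as `spectrum_aggregation="apex"`.
- **Tolerance** defaults to 0.3 Da — unit-resolution LC-MS as used for
  reaction monitoring.
- **Significance floor**: a matched signal must exceed the `noise_quantile`
  (default 0.9) quantile of all centroid intensities in the run.  This
  implements the requirement that the matched ion be a *significant* signal
  rather than a baseline fluctuation that happens to fall inside the
  tolerance window; setting the quantile to 0 disables it.
- **Verdict**: success iff any peak yields a within-tolerance match.
  Matches that are not the base peak of their spectrum are flagged
  `confidence="minor"` but still count as success — review of automated
  vs human disagreements shows rank-based rejection manufactures false
  negatives.

Per-iteration report rows carry the agreement percentage with the human
annotation and the confusion-cell counts; campaign totals average the
percentage columns across iterations (unweighted) and sum the count columns,
rounding half-up at the printed precision while retaining raw means.

mzML I/O is self-contained (`bspa.mzml_io`): the reader supports centroided
spectra with 32/64-bit base64 arrays, plain or zlib-compressed, seconds or
minutes retention-time units, indexed or plain documents; profile-mode
spectra are rejected with an explicit error unless the caller asserts the
data are centroided.  The writer emits plain mzML 1.1 with 64-bit
uncompressed arrays so that files round-trip bit-exactly.

## Synthetic LC-MS campaigns

A simulated run places each species' adduct isotopologue ladder on a 5 s ×
300 s scan grid with a Gaussian elution profile (default σ = 8 s), plus
Poisson-distributed decoy ions at uniform random m/z in 100–1000 Da.
Defaults: product abundance 2×10⁵ counts, decoy mean intensity 2×10⁴
(signal-to-baseline 10), jitter sd 5×10³, 2 decoys per spectrum.  The
isotope envelope is binomial over the carbon count with P(¹³C) = 0.0107 and
1.00336 Da spacing — carbon-only, which is adequate for ±0.3 Da matching but
underestimates M+1/M+2 for S- or Cl-rich species.  Not modelled, hence not
demonstrated by passing tests: chromatographic tailing and drift, ion
suppression, co-eluting isobars, profile-mode peak shapes, and realistic
CRM side-product ladders (decoys are random, not chemically related to the
product).

All randomness flows through explicit integer seeds; campaigns are
byte-identical under a fixed seed, including the written mzML.

## Replicate-density stereochemistry calls

Each candidate enantiomer defines a probe from the shared piperazine ring
carbon to its methyl carbon (C–C bond, 1.54 Å).  Density is interpolated
trilinearly at evenly spaced points including both endpoints and reduced to
the mean over strictly positive samples ("mean positive density"); the
clamped alternative (mean of max(ρ,0) over all samples) is not used because
the positive-conditional mean matches how map protrusions are read, but the
profile array is returned so callers can compute either.

The call applies a paired Student t-test to the per-replicate differences
d_i = r_i − s_i: t = mean(d)/(sd(d)/√k), df = k − 1.  The default mode
tests both one-sided hypotheses at α (default 0.01) and calls whichever
rejects; these mirrored tests spend α per direction and hence 2α
family-wise.  `alternative="two-sided"` instead requires the two-sided
p-value below α before calling the sign, bounding the family-wise
false-call rate by α itself.  Degenerate inputs are defined explicitly:
zero spread with non-zero mean reports infinite t with p = 0 and a
degenerate flag; zero spread with zero mean reports t = 0, p = 0.5.
Replicate sets of size one are rejected — single maps cannot be called.

Probes sample 41 points per bond by default.  On null simulations the
11-point profile makes the k = 3 paired t mildly anticonservative
(family-wise false-call ≈ 2.8% vs the nominal 2%), because the
positive-part mean over so few correlated samples is coarse; 41 points
restore nominal calibration (≈1.7% measured over 1000 trials) at unchanged
power.

**Synthetic maps.**  A fixture grid is a Gaussian blob of peak height
`effect` and width σ = 0.9 Å centred on the true methyl position, plus
white voxel noise N(0, noise_sd), on a 61³ orthogonal grid of 0.15 Å pitch.
The two candidate methyl positions are mirror images at the tetrahedral
half-angle (54.75°) from the shared ring carbon, and the whole molecular
frame sits in a fixed generic orientation: axis-aligned bonds interact
pathologically with the voxel lattice (interpolated noise variance then
depends on the lattice phase of the probe), which a generic rotation
removes.  The 0.15 Å pitch is the *noise decorrelation scale* of the
synthetic maps — real event-map noise decorrelates at the resolution scale,
not the voxel scale, so the pitch here is a noise-model parameter rather
than a claim about real map sampling; this is the main respect in which the
fixtures are easier than real maps.  These geometry defaults were fixed by
an a-priori power analysis targeting the regime of interest (peak
signal-to-noise 4, three replicates), where the measured true-call power is
≈0.98 at α = 0.01.

Maps are written and read as CCP4/MRC volumes (orthogonal cells only; the
Cartesian origin lives in the MRC ORIGIN header words).  Triclinic cells
would need a fractionalisation transform and are noted as an extension.

## Campaign accounting

Funnel rates divide each stage count by the preceding stage's count; a zero
denominator yields an explicit "undefined", never 0.  Display rounding is
half-up, whole percent for the synthesis and dataset stages and one decimal
for the crystallographic hit rate, matching how such figures are
conventionally printed.  Resource totals scale per-target manual figures by
target counts; the year conversion uses 365 days; saving fractions are
automated/manual and the solvent fold-reduction manual/automated.  Because
printed tables round per-row, recomputed totals can differ from a printed
total in the last digit (e.g. automated solvent 18.66 L recomputed vs
18.70 L printed from rounded rows); raw values are therefore always kept
alongside rounded ones and totals are computed from raw inputs.

## Problem sizes used in the standard runs

The shipped experiments use a 100-sample campaign (50% spiked) for LC-MS
recovery and 100 trials × 3 replicate 61³ maps for each of the
stereochemistry power and null experiments; the largest example iteration
enumerated in full is the 1024-target two-step array.  These sizes give
binomial standard errors of a few percent on the recovered rates, which is
tight enough to distinguish the designed operating points (recall ≈ 1,
false-positive rate ≈ 0; call power ≈ 0.98, null calls ≈ 2%) from failure
modes.

## Known limitations

- Chemistry beyond mass bookkeeping is unvalidated by design; the example
  block lists are homologous series, not vendor catalogues.
- The QC layer does no quantification, calibration, retention-time
  prediction or MS2 work, and cannot deconvolve co-eluting species.
- The isotope model ignores N/S/Cl heavy isotopes.
- Density calls assume orthogonal cells and white noise; correlated map
  noise would lower the effective number of independent bond samples and
  hence the call power relative to the synthetic fixtures.
- The published per-iteration LC-MS success rates and bound-structure
  counts are instrument- and beamline-derived inputs, not quantities this
  package can recompute.
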