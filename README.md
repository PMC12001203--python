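# bspa

Computational readout layer for **binding-site purification of actives
(B-SPA)** screening campaigns: crude-reaction-mixture (CRM) array synthesis
followed by high-throughput protein crystallography, with LC-MS as the only
chemistry quality control.

In a B-SPA campaign, hundreds to thousands of multi-step reactions are run
robotically in parallel and the *unpurified* mixtures are soaked straight
into protein crystals — the binding site itself purifies the active species.
The desk-side work this package covers:

- **`bspa.chem`** — enumerate configuration-driven reaction arrays
  (reaction-SMARTS rules applied over building-block lists, including
  branched routes merged by a final step) into expected products, with
  Hill formulas, monoisotopic/average masses and expected adduct m/z values
  from a versioned isotope table.
- **`bspa.qc`** — MSCheck-style LC-MS quality control: build the total ion
  chromatogram (TIC) from mzML, find peaks, aggregate the spectra under each
  peak, search them for the expected molecular ion, and assign a yes/no
  success verdict per sample.  Verdicts reconcile against human annotations
  into TP/TN/FP/FN categories and per-iteration report tables.
- **`bspa.similarity`** — Tanimoto similarity of circular fingerprints
  (radius 2, 2048 bits) and average-linkage dendrograms of product sets,
  exported as Newick.
- **`bspa.density`** — stereochemistry assignment from replicate event maps:
  trilinear density profiles along the candidate methyl C–C bond, the
  mean-positive-density statistic, and a paired Student t-test across
  replicates to call (R) vs (S).
- **`bspa.report`** — campaign accounting: funnel success rates
  (synthesis → LC-MS success → usable datasets → bound products) and
  manual-vs-automated resource totals with saving fractions.
- **`bspa.simulate`** — labelled synthetic data (centroided MS1 campaigns as
  standard mzML; density-map fixtures as CCP4/MRC) so every layer is
  testable without an instrument or beamline.

## The statistics at the core

**Success verdict.** A sample succeeds when some TIC peak's aggregated
spectrum holds a significant signal within the m/z tolerance (default
0.3 Da) of an expected ion m/z = (M + Δ)/|z|.  A match that is not the base
peak of its spectrum is flagged `minor` but still counts — human review
shows such matches are usually real product.

**Stereochemistry vote.**  For replicate structures i = 1..k, let r_i and
s_i be the mean positive density along the candidate bond under the (R) and
(S) hypotheses.  With d_i = r_i − s_i,

    t = mean(d) / (sd(d) / √k),   df = k − 1,

and the enantiomer is called when the one-sided tail probability falls below
α (default 0.01) in either direction.  Single structures cannot be called —
the power comes from pairing across replicates.

**Report totals.** Campaign summary percentage columns are arithmetic means
of per-iteration percentages (not sample-weighted), rounded half-up;
count columns are sums.  Raw unrounded values are always kept in the
machine-readable output.

## Worked example

Simulate a small labelled campaign, enumerate the first example iteration
(58 urea products on a furan-carbonyl piperazine core), QC the campaign
against those targets, and call a stereocentre from three simulated maps:

```
$ bspa simulate lcms --n 8 --spike 0.5 --seed 7 --out campaign
8 runs written to campaign

$ bspa enumerate --route src/bspa/examples/routes/iter1.yaml \
      --blocks blocks.csv --out targets.csv --newick tree.nwk
58 targets written to targets.csv (0 combinations skipped)
dendrogram written to tree.nwk

$ bspa qc --runs campaign --targets targets.csv --out qcreport
4/8 samples succeeded; report in qcreport

$ head -3 qcreport/verdicts.csv
sample_id,status,confidence,n_matches,best_rank,observed_mz,human_label,note
S0000,success,prominent,1,1,300.1343,,
S0001,fail,,0,,,,

$ bspa simulate maps --true R --effect 4 --noise 1 --replicates 3 --seed 7 --out maps
3 maps written to maps

$ bspa stereo --maps maps/replicate_1.map --maps maps/replicate_2.map \
      --maps maps/replicate_3.map --probes maps/probes.json \
      --alpha 0.01 --out call.json
call: R (t=75.236, p=8.831e-05)
```

Exactly the 4 spiked samples of the 8 succeed QC (`S0000` matched its
expected [M+H]+ ion at m/z 300.13 as the base peak of its elution peak), and
the three replicate maps — individually noisy — jointly call the (R)
enantiomer far below the 1% level.

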