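# mfakit

Marker frequency analysis (MFA) of bacterial replication profiles on
circular chromosomes, together with a synthetic replication-dynamics
simulator so every stage of the analysis is testable without real
sequencing data.

The package covers the full desk-scale workflow:

* **genome model** — circular coordinates, equal-width windows
  (default 10,000 over a 4.64 Mb W3110-like chromosome), masked
  intervals, named marker loci, polar Ter sites, inversions and
  amplifications, with exact coordinate transforms through inversions.
* **simulator** (`mfakit.simulate`, `mfakit.presets`) — a
  firing-fraction / fork-extent population mixture producing expected
  copy-number curves for log-phase gradients from the main origin,
  run-out profiles with secondary (cSDR-type) origins confined by polar
  Ter/Tus traps, head-on transcription-barrier "steps", amplifications
  and inversions; Poisson coverage sampling with lognormal window bias;
  qPCR Ct replicate generation.
* **MFA core** (`mfakit.mfa`) — read binning, library-size-scaled
  log2 normalization against a control track, and a circular loess
  (tricube, degree 0/1/2, optional bisquare robustness) with span 0.1
  by default.
* **feature detection** (`mfakit.features`) — origin peaks (circular
  prominence with narrow-span position refinement), amplified-segment
  calling with changepoint edge refinement, Ter asymmetry, and step
  scores across annotated operons.
* **marker ratios** (`mfakit.ratios`) — NGS window ratios (e.g.
  qseC/lepA) with Poisson error propagation and qPCR 2^-dCt replicate
  ratios, plus method concordance.
* **I/O + CLI** (`mfakit.io`, `mfakit.cli`) — bedGraph coverage, BED
  annotations/calls, TSV profiles and Ct tables, JSON truth/features,
  YAML scenario configs, with a provenance block in every output.

## CLI

```bash
# simulate a preset scenario -> coverage.bedgraph + truth.json + scenario.yaml
mfakit simulate --preset rnhA_runout --seed 1 --outdir out/rnhA
mfakit simulate --preset wt_runout   --seed 42 --outdir out/ctl

# normalize against the run-out control and loess-smooth
mfakit profile --sample out/rnhA/coverage.bedgraph \
               --control out/ctl/coverage.bedgraph \
               --genome out/rnhA/scenario.yaml --out out/profile.tsv

# call peaks / amplified segments
mfakit detect --profile out/profile.tsv --genome out/rnhA/scenario.yaml \
              --outdir out/features

# marker copy ratios (NGS track or qPCR Ct table)
mfakit ratio --coverage out/rnhA/coverage.bedgraph \
             --marker-a qseC --marker-b lepA --out out/ratio.tsv
mfakit ratio --ct ct.tsv --marker-a ydcM --marker-b lepA --out out/qpcr.tsv

# plot-ready TSV (Mb coordinates)
mfakit report --profile out/profile.tsv --out out/report.tsv
```

Presets: `wt_log`, `wt_runout`, `wt_stationary`, `rnhA_runout`
(origins at 1.52/1.83/2.23/2.54 Mb between/outside the TerA/TerB
traps), `topAtopB_runout` (dominant terminus origin, bumps, x3
amplification over 2.99–3.24 Mb), `rnhA_inv` (multi-origin run-out on a
chromosome carrying the 1.39–2.28 Mb inversion, reported in reference
coordinates).

## Notes on modeling choices

* Origin firing fractions and fork-extent scales in the presets are
  free parameters tuned for clearly resolvable peaks; they are not
  measurements.
* Peak *detection* runs on the span-0.1 loess; peak *positions* are
  refined on a narrow local smooth of the raw profile, because a wide
  smoothing kernel biases the argmax of sharp peaks sitting on sloped
  backgrounds.
* Inversions are simulated on the physical genome (in-segment elements
  relocated, polarities flipped) and reported back in reference
  coordinates by reversing the inverted block of windows.
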