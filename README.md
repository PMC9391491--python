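# growthctrl

A desk-scale, coarse-grained simulator of bacterial growth-rate control.
It reimplements the core regulatory submodels that couple amino-acid supply
to translation and transcription in *E. coli*:

- **Amino-acid biosynthesis** (`growthctrl.biosynthesis`) — a single-step
  reaction network rooted at glutamate with end-product inhibition and
  upstream saturation; forward/loss rate constants and environmental
  exchange rates are fitted jointly against minimal- and rich-media mass
  balances.
- **Amino-acid transport** (`growthctrl.transport`) — pooled importer /
  exporter kinetics calibrated from two anchor points (rich-media exchange
  and zero exchange at the export K_M).
- **Phenomenological supply** (`growthctrl.pheno_supply`) — the
  enzyme-independent fallback supply law with closed-form constants from
  two anchor fractions.
- **tRNA charging** (`growthctrl.charging`) — synthetase charging and
  ribosome elongation kinetics relaxed to steady state within each
  timestep (stiff ODE integration), with optional sub-timestep coupling of
  the amino-acid pools and a ppGpp-dependent Hill cap on the elongation
  rate (translational GTPase inhibition).
- **ppGpp kinetics** (`growthctrl.ppgpp`) — RelA synthesis sensing
  uncharged-tRNA-bound ribosomes with inter-species competition, SpoT
  synthesis/hydrolysis with uncharged-tRNA inhibition, per-species
  prevalence adjustments, and the analytic SpoT calibration from a 30 s
  decay half-life and an 11.4 µM knockout steady state.
- **ppGpp-regulated transcription** (`growthctrl.transcription`) —
  Hill-2 ppGpp–RNAP binding, growth-law fitting of the binding constant,
  per-gene free/bound expression decomposition, cross-condition matching,
  and ppGpp-dependent basal recruitment with gene-dosage scaling.
- **Transcriptional attenuation** (`growthctrl.attenuation`) —
  charged-tRNA-dependent stop probabilities, strength constants
  back-calculated from fold changes, basal-probability compensation, and
  seeded stochastic termination.
- **NCA fold changes** (`growthctrl.nca`) — topology-constrained
  factorization of a log2 expression compendium by alternating constrained
  least squares, dual-regulator splitting, activity-extreme sets and
  regulator→gene fold-change extraction.
- **Host cell** (`growthctrl.cell`) — a reduced cell that couples all
  submodels per timestep (transcription → RNA decay → supply/charging →
  ppGpp → pools → volume growth), supports media-shift schedules and
  ppGpp clamps with a 0.01 µM/s ramp, and computes the analysis metrics
  (growth rate, RNA degradation rate, capacities, inhibition metrics).
- **Fixtures** (`growthctrl.fixtures`) — deterministic synthetic-data
  generators (toy networks with round-trippable demands, growth-law
  tables, planted expression compendia) and a fully parameterized
  4-amino-acid default cell built by running the package's own fitting
  pipeline.

Units throughout: concentrations in µM, times in s, rates in µM/s,
masses in fg, volumes in fL.

## CLI

```sh
growthctrl fixtures --kind aa-network --seed 0 --out-dir fixtures/
growthctrl fit-params --minimal fixtures/minimal.csv --rich fixtures/rich.csv \
    --network network.yaml --out params.json
growthctrl simulate --media rich --duration 600 --seed 0 --out series.csv
growthctrl shift --shift-at 1500 --from-media rich --to-media minimal \
    --duration 5100 --seed 0 --out shift.csv
```

`simulate` and `shift` run the default toy cell and write a tidy CSV time
series plus a JSON manifest (seed, options, shift events).  Simulation
option flags (e.g. `ppgpp_regulation: false`, `supply_mode`) can be set in
a YAML config passed with `--config`.

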