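# icenuc

Statistics and sequence-engineering tools for bacterial ice nucleation
protein (INP) studies built on droplet-freezing assays:

- **assay_io** — delimited droplet-freezing tables (with `#meta` header
  metadata), FASTA/GenBank sequences, YAML configs; strict unit and schema
  validation (°C everywhere, 0-based half-open coordinates internally).
- **freezing_analysis** — cumulative frozen-fraction curves (f_ice), T50
  by the step-function convention, bootstrap confidence intervals with an
  instrument-uncertainty floor (±0.3 °C), heterogeneous/homogeneous splits.
- **nucleation_spectrum** — cumulative nucleators per litre
  (K(T) = −ln(1 − f_ice)/V) and per gram of cells (Nm), with dilution-series
  merging and explicit lower-bound handling at saturation.
- **dilution_poisson** — zero-truncated Poisson occupancy inference from the
  fraction of droplets freezing only homogeneously (λ = −ln f_hom), Wilson
  intervals, and dilution-series consistency fitting.
- **repeat_analysis** — 16-residue tandem-repeat frame detection, per-repeat
  Hamming identity against the consensus coil `AGYGSTQTAGEESSLT`, sequence
  logos (frequencies + information bits), and coil classification
  (water-organizing / R-coil / other).
- **construct_ops** — in-silico construct engineering on 48-bp repeat genes:
  paired same-phase excision with chimeric-coil accounting, block
  insertion/replacement with uninterrupted-run bookkeeping, motif mutations,
  and restriction-site pair verification (uniqueness, spacing mod 48, frame).
- **simulator** — stochastic droplet-assay generator under the singular
  approximation (Poisson nucleator loading, per-construct characteristic
  temperatures, apparatus-specific homogeneous backgrounds, optional potent
  subpopulation) and synthetic repeat-gene generation with tunable
  divergence and silent restriction-site pairs.

## CLI

All subcommands emit a versioned JSON run report (seeded runs record their
seed):

```sh
icenuc curve    --input assay.csv --output curve.tsv
icenuc t50      --input assay.csv --seed 0
icenuc spectrum --input assay.csv
icenuc dilution --input series.csv          # dilution_factor,n_frozen_het,n_total
icenuc repeats  --input protein.fa
icenuc simulate --config sim.yaml --seed 1 --output table.csv
icenuc construct new    --n-water 54 --n-rcoil 11 --output c65.json
icenuc construct excise --construct c65.json --repeat-i 10 --repeat-j 57 --phase 4
icenuc construct insert --construct c65.json --start-repeat 10 --n-replaced 19
icenuc construct mutate --construct c65.json --repeat-from 19 --repeat-to 41 \
    --motif TxT --sub 6=S --sub 8=KY
icenuc construct sites  --construct c65.json --enzyme SacI=GAGCTC
```

Droplet tables are plain delimited text; see `icenuc.assay_io` for the
schema (`droplet_id,freeze_temp_C,excluded` plus `#meta key: value` lines).

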