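# meaconn

Functional-connectivity and directionality analysis for two-compartment
microelectrode-array (MEA) recordings, e.g. midbrain–striatum assembloids
cultured over an 8×8 electrode grid split by a microfluidic divider.

The pipeline goes from spike events (or raw voltage traces) to:

- **pairwise synchrony** via the spike time tiling coefficient (STTC,
  Δt = 10 ms default);
- **conduction delay** from a 0.5 ms-binned cross-correlogram, gated by a
  mean + 5 SD significance rule (plus a minimum-coincidence guard for sparse
  histograms);
- **propagation speed** = inter-electrode distance / |delay|;
- **directionality vectors** per electrode (vector sums of accepted-pair
  displacements, acceptance = significant delay AND STTC ≥ 0.3), the
  assembloid-level vector, its vertical (y) / lateral (|x|) decomposition,
  and the **connection-established verdict** (|y| ≥ 2 inter-electrode
  distances by default);
- **basal activity metrics** (spike counts, mean ISI, burst frequency via the
  max-interval method) and a **statistics layer** (batch normalisation to
  batch means, IQR-proximity outlier removal, Shapiro-routed Welch/Wilcoxon
  or ANOVA+Tukey / Kruskal–Wallis+Dunn+Benjamini–Hochberg);
- a **synthetic recording generator**: two Poisson/bursting compartments
  coupled by distance-dependent conduction delays with an adjustable
  forward/backward transmission bias, with full ground truth for
  parameter-recovery testing.

## CLI

The `meaconn` entry point (equivalently `python -m meaconn`) exposes the
pipeline stages:

```sh
# synthetic fixture suite (null / forward / backward / shifted_pair)
meaconn simulate --out fixtures/ --seed 1

# spike detection from raw traces (CSV matrix, one column per electrode)
meaconn detect --traces traces.csv --sample-rate 12500 --out spikes.csv

# pairwise STTC / delay / speed table
meaconn connect --spikes fixtures/forward.csv --pitch-um 300 \
    --boundary-row 5 --duration 180 --out pairwise.csv

# directionality field + establishment verdict
meaconn direction --spikes fixtures/forward.csv --pairwise pairwise.csv \
    --pitch-um 300 --boundary-row 5 --duration 180 --out field.json

# grouped statistics on a long-format table (columns: value, group[, batch])
meaconn stats --table rates.csv --out report.json
```

`--pitch-um` is required (the physical inter-electrode pitch is
hardware-specific and has no safe default). Analysis knobs live in a flat
YAML config passed with `--config`; every key of `AnalysisConfig` can be
overridden there.

Electrodes are addressed `R<row>C<col>` (1-based). Row 1 is the MO-side edge;
the y axis is oriented MO → StrO positive, so a positive vertical component
means net signal flow from the midbrain toward the striatum compartment.

## Layout

| module | contents |
| --- | --- |
| `meaconn.core` | `SpikeTrain`, `ElectrodeGrid`, `Recording`, `AnalysisConfig`, result types |
| `meaconn.io` | spike-list CSV dialect, pairwise CSV, directionality JSON, raw-trace matrix |
| `meaconn.detection` | rolling MAD noise estimate, 6-SD adaptive-threshold spike detection |
| `meaconn.connectivity` | tiling fraction, STTC, cross-correlogram, significant delay, speed, pairwise table |
| `meaconn.direction` | pair/electrode/assembloid vectors, establishment verdict, maturation summaries |
| `meaconn.stats` | basal metrics, batch normalisation, IQR filter, routed hypothesis tests, Dunn + BH |
| `meaconn.simulate` | Poisson/burst background, delayed-copy connections, fixture suite, ground truth |
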