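# epivertex

A stochastic 2D vertex model of an epithelial monolayer with
Ornstein–Uhlenbeck fluctuating junction tensions, the summary statistics
that characterize its T1 (neighbor-exchange) dynamics, and an
image-analysis pipeline that tracks junctions and detects neighbor
exchanges in skeletonized time-lapse movies.

## What is in here

| module | role |
| --- | --- |
| `epivertex.tissue` | polygonal mesh on a periodic box: honeycomb/Voronoi construction, geometry, topology validation, the T1 flip |
| `epivertex.dynamics` | tissue energy and forces, truncated-normal extrinsic tension draws, OU tension dynamics, Euler integration, threshold-triggered (force-gated) T1 handling, simulation driver |
| `epivertex.observables` | T1 rates, topological disorder, polygon fractions, CV of junction lengths, auto-/cross-correlation curves and exponential fits, cumulative event curves, event-aligned length profiles |
| `epivertex.trackpipe` | skeleton parsing, pixel-chain junction lengths, drift registration, optimal midpoint tracking, cell (face) detection, T1 event detection, intensity measurement with bleaching normalization, persistence segments, quartet aspect ratios, Kaplan–Meier reversal survival |
| `epivertex.fixtures` | ground-truth generators: calibrated stochastic intensity traces and rasterized skeleton/intensity movies from simulated tissues |
| `epivertex.config` / `epivertex.io` / `epivertex.cli` | YAML config schema, TIFF/TSV readers and writers, run manifests, command-line interface |

Wild-type defaults (in units of the characteristic cell length, the
reference tension and minutes): packing time 4.4 min, tension/area
elasticity ratio 0.025, preferred-area SD 0.19, extrinsic tension SD
1.07, intrinsic/extrinsic ratio 0.08/0.13, tension persistence time
2.2 min. The T1 threshold length (0.07) is the one calibrated knob; it
is tuned so that the default parameter set reproduces a T1 rate of
8.5e-4 events/min/junction.

## CLI

```sh
epivertex run --config cfg.yaml --out run1          # simulate one trajectory
epivertex sweep --ratios 0.5,1.0,1.5,2.0            # gamma/gamma0 sweep
epivertex stats --run-dir run1                      # frame/run statistics
epivertex analyze --skeleton skel.tif --intensity int.tif
epivertex fluct --tracks analysis_output/junction_tracks.tsv
epivertex fixtures --kind traces                    # synthetic fixtures
```

Configs are flat YAML; every run directory receives the resolved config
and a manifest with file digests. All table outputs are tab-separated
text; image stacks are 8-bit TIFF.

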