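# morphoflow

Quantitative analysis of epithelial tubule dynamics from live imaging:

* **Coarse-grained 3D PIV** (`morphoflow.velocimetry`) — zero-mean
  normalized cross-correlation of interrogation windows (default
  window (32,32,7) px, overlap (8,8,3), search margin (10,10,3)) with
  per-axis 3-point sub-voxel peak refinement, mean-speed summaries,
  per-node motion-similarity maps against in-plane 4-neighbours, and
  line-based coherence profiles across the tissue long axis.
* **Cluster-dispersal statistics** (`morphoflow.dispersal`) —
  identification of 4–8-cell clusters sharing a convergent point
  (15 px radius), the *standard distance* dispersion statistic, linear
  and quadratic trend fits, ANCOVA slope-homogeneity comparison,
  two-sample Hotelling T² tests on quadratic coefficient vectors with
  Benjamini–Hochberg FDR adjustment, rosette detection (≥5 cells
  sharing a vertex), and track speed.
* **Morphometry** (`morphoflow.morphometry`) — polygon
  cross-sectional area (shoelace, with self-intersection rejection),
  relative narrowing over time, division angles folded to [0°, 90°],
  and Mann–Whitney tubule-diameter comparisons.
* **Tip counting** (`morphoflow.tipcount`) — maximum intensity
  projection, rolling-ball background subtraction, Gaussian blur,
  Otsu/fixed threshold, skeletonization, spur pruning, and an
  endpoint census where each skeleton pixel with exactly one
  8-connected neighbour counts as one branching tip.
* **Synthetic data** (`morphoflow.synthdata`) — seeded generators
  with stored ground truth for every input the analyses assume:
  advected particle-texture movies under prescribed velocity fields,
  clustered trajectories whose standard-distance-vs-time curve follows
  prescribed linear/quadratic dynamics exactly at zero noise,
  branching-tree images with known tip counts, and division-angle
  samples.
* **IO & pipeline** (`morphoflow.io`, `morphoflow.pipeline`,
  `morphoflow.cli`) — TIFF volume and trajectory-CSV readers
  (including the TrackMate table dialect), tidy CSV/JSON outputs,
  provenance records, and deterministic end-to-end presets.

Everything runs on synthetic data; no external imaging data is needed.

## CLI

```sh
morphoflow simulate --what flow --out movie.tif --displacement 3,2,1 --n-frames 2
morphoflow piv movie.tif --out field.csv --window 32,32,7 --overlap 8,8,3 --margin 10,10,3
morphoflow similarity movie.tif --out sim.csv --n-lines 3
morphoflow simulate --what clusters --out tracks.csv --model linear:0.2,5 --n-frames 15
morphoflow dispersal --tracks tracks.csv --region trunk --radius 15 --seed 7 --out disp.json
morphoflow simulate --what tree --out tree.tif --seed 11
morphoflow tips tree.tif --threshold otsu --prune 5
morphoflow run --preset trunk-demo --seed 1 --outdir out/
```

`morphoflow run` executes a full preset (synthesis → dispersal →
trend fits → group inference) and writes `report.json`, `series.csv`,
the trajectory tables, and `provenance.json`; identical config + seed
produces byte-identical numeric outputs.

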