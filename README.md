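# axonzip

Biophysical analysis of axon shaft "zippering": the progressive adhesion of
neighbouring axons into bundles, driven by the competition between axon-axon
adhesion and mechanical tension.

The package provides:

- **`axonzip.statics`** — force balance of a two-axon zipper: equilibrium
  angles (symmetric `S = 2T(1 - cos(beta/2))` and the general asymmetric
  case), configuration energy and vertex force, equilibrium vertex search,
  loop-stability classification, and the adhesion-energy-per-area estimate.
- **`axonzip.dynamics`** — overdamped equation of motion for the zipper
  vertex, `F = H u`, with elongation-viscosity, vertex-localized and
  substrate friction channels; trajectory simulation under tension
  perturbation protocols; the linear fit of zippering velocity against
  `1 - cos(beta/2)` with slope `-2T/eta_Z` and intercept `S/eta_Z`; and the
  `S/T`, `eta_Z` and dissipation-rate inferences.
- **`axonzip.bfp`** — Biomembrane Force Probe analysis: red-blood-cell
  probe stiffness from geometry and aspiration pressure, force-plateau
  detection, the `F_perp` vs `sin(delta)` tension regression (slope `2T`),
  and the population tension density as a Gaussian mixture.
- **`axonzip.distributions`** — kernel density estimation, the
  change-of-variables transform from a tension distribution to an
  equilibrium-angle distribution, two adhesion-strength estimators
  (correlation matching over a 1 pN grid; independent joint screening into
  1 pN bins), fascicle scaling (`mean ~ n`, `sd ~ sqrt(n)`, `S ~ sqrt(n)`)
  with the predicted median-angle shift, and the crossing-probability CDF.
- **`axonzip.network`** — planar graphs of segmented axon networks
  (CSV/JSON polyline exports): total length, junction counts, bounded-face
  ("chordless loop") areas, sharpest-of-three zipper angles, per-frame
  time-series statistics with the angle-length Pearson correlation, and
  vertex-type percentages.
- **`axonzip.synthetic`** — seeded generators for every pipeline input:
  tension/angle samples with a planted adhesion strength, BFP plateau
  staircases with realistic noise, and coarsening / stable / de-coarsening
  network time-lapses with planted ground truth manifests.

Units: lengths in um, forces and tensions in nN (1 nN = 1 nJ/m), time in s;
angles are reported in degrees. See `axonzip/units.py`.

## CLI

A single `axonzip` entry point with subcommands:

```sh
# integrate the vertex equation of motion
axonzip simulate-zipper --geometry -10 10 10 10 0 -40 0 0 \
    --t1 1.0 --t2 1.5 -s 0.2 --eta-z 1.0 --eta-par 1 --eta-perp 1 \
    --dt 0.1 --t-end 2000 --out traj.csv

# plateau detection + tension fit on a probe recording
axonzip analyze-bfp --input recording.csv --rp 0.8 --rc 1.0 --r0 2.5 \
    --dp 220 --out tension.json

# adhesion-strength estimates from tension samples and angle samples
axonzip estimate-adhesion --tensions tensions.csv --angles angles.csv \
    --out adhesion.json

# predicted angle distributions for rescaled fascicles
axonzip predict-angles --mean-t 0.68 --sd-t 0.25 -s 0.17 --n 1.5 \
    --out angles.csv

# coarsening statistics on a directory of per-frame segmentation files
axonzip analyze-network --input-dir frames/ --out-csv stats.csv \
    --out-json summary.json

# synthetic data with a ground-truth manifest
axonzip gen-synthetic --scenario coarsening --seed 1 --out-dir synth/
```

Segmentation CSV schema: columns `frame, polyline_id, point_index, x, y`
plus an optional `kind` column (rows marked `crossing` annotate overlap
points that do not join the graph). A JSON dialect mirrors it:
`{"timestamp": .., "polylines": [{"id": .., "points": [[x, y], ..]}],
"crossings": [[x, y], ..]}`.

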