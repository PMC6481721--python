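# decyto

Deformability cytometry analysis for cells transiting linear microchannels.

Flow-induced deformation is a label-free, whole-cell mechanical phenotype:
cancer cells with different metastatic potential, or cells treated with
cytoskeleton-targeting drugs, differ measurably in how much they deform
while squeezing through a channel slightly narrower than themselves.
`decyto` turns high-speed brightfield recordings of such transits (or
pre-extracted per-frame event tables) into single-cell readouts and
population statistics:

* **Segmentation** — temporal-median background subtraction, Otsu
  detection, and *subpixel* contour measurement (area, perimeter, centroid)
  of every object in every frame.
* **Tracking** — velocity-gated nearest-neighbour linking; each cell gets
  one ID on entering the region of interest; frames with two cells in the
  test section are flagged and excluded from deformation readouts.
* **Shape metrics** — the deformation index

      DI = 1 − 2√(πA) / p

  (A projected area, p perimeter): 0 for a circle, rising with elongation.
* **Per-cell summaries** — undeformed diameter D_c from pre-entry frames,
  confinement D_c/D_h against the duct's hydraulic diameter
  D_h = 2WH/(W+H), and DI_max, the maximum deformation before the exit
  plane, as the deformability readout.
* **Population statistics** — confinement gating (0.85 < D_c/D_h < 0.95),
  one-tailed Mann-Whitney U comparisons with significance tiers,
  nonparametric dose-response C_min determination, DI-vs-pressure linear
  fits, kernel-density event contours, boxplot summaries, and rigid-bead
  manifold QC (velocity uniformity across channels).
* **Synthetic data** — a ground-truthed transit-video generator (rigid
  beads and deformable "bullet" cells with planted log-normal DI
  populations), so the entire chain is testable without experimental data.

The science, model assumptions, parameter defaults, and known limitations
are documented in [docs/methods.md](docs/methods.md).

## Worked example

Render a synthetic recording of rigid calibration beads (15.13 µm ± 6 %)
and measure them end-to-end:

```python
from decyto import (ChannelGeometry, PopulationSpec, TransitSimulation,
                    default_strip_acquisition, measure_stack)

geom = ChannelGeometry()                      # 18 x 19.8 x 230 um duct
acq = default_strip_acquisition()             # 0.97 um/px, 15 000 fps strip
sim = TransitSimulation(PopulationSpec.beads(), geom, acq,
                        duration_s=0.3, seed=11)
records, tracks, counts = measure_stack(sim, geom, acq, "beads")
beads = [r for r in records if r.accepted]
print(counts)
print(f"max DI = {max(r.di_max for r in beads):.4f}")
print(f"mean diameter = {sum(r.dc_um for r in beads)/len(beads):.2f} um")
```

prints

```
{'frames': 4500, 'observations': 769, 'dropped_observations': 0,
 'tracks': 31, 'cells_accepted': 31, 'cells_rejected': 0}
max DI = 0.0064
mean diameter = 14.93 um
```

Thirty-one beads transited in 0.3 s; every one was segmented, tracked and
summarised.  The maximum measured DI of 0.0064 is the pipeline's error
floor on these renderings — rigid spheres should read zero, and anything a
real instrument reads on beads (here well under the conventional 0.024
ceiling) bounds how small a cell deformation can be trusted.  The
recovered mean diameter matches this sample's planted diameters (drawn
from a 15.13 µm ± 6 % population) to within 0.05 µm.

The same flow works from the shell:

```
decyto simulate --spec beads.yaml --seed 11 --duration 0.3 --out fixtures/
decyto run --input fixtures/sample.tif --out results/
decyto analyze --cells results/cells.csv --design design.yaml --out analysis/
decyto qc --beads bead_velocities.csv --tolerance 0.03
```

`run` writes `cells.csv` (one row per cell: D_c, confinement, DI_max,
velocity, rejection reason), `tracks.csv` (per-frame rows), and a
`manifest.json` capturing config, input checksums and seeds; re-running
with the same inputs reproduces the CSVs byte-for-byte.

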