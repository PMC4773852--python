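# fiberorient

Quantification of tumor-induced remote collagen network orientation and the
endothelial response to it, from label-free microscopy.

A tumor spheroid embedded in a 3D collagen I gel pulls on the surrounding
fiber network and re-orients it radially — far beyond the zone the tumor
cells ever reach.  `fiberorient` reimplements the image-analysis workflow
that measures this effect as a tested, reusable Python pipeline, for
groups running spheroid-in-gel invasion or angiogenesis assays:

* **fiber extraction** from reflection-confocal images: disk-mean background
  subtraction, a rolling-ball-style local threshold on the squared signal,
  binary cleanup, and connected components filtered to fibrillar shapes
  (>20 px, eccentricity ≥ 0.9);
* **the radial orientation statistic**: per fiber, cos²θ of the acute angle
  θ between the fiber axis and the radial vector from the tumor center
  (1 = radial, 0 = tangential, 0.5 = random expectation), binned by distance
  from the spheroid edge in 67 µm (100 px) bins;
* **the decay fit**: a two-parameter single exponential plateauing at the
  random baseline,

  ```
  y(x) = 0.5 + (Y0 − 0.5)·exp(−x/L0),    fitted for x > 100 µm
  ```

  with the *integrated orientation* `(Y0 − 0.5)·L0` (µm) as a single scalar
  for how strongly and how far the matrix is re-oriented, and the
  *orientation extent* — the largest distance at which the fitted curve's
  lower 95 % confidence bound still exceeds 0.5;
* **spheroid morphometry** from DIC images (median-filter illumination
  normalization, dark-core thresholding at mean − 2 SD, Canny-edge capture of
  the migration zone) and **nuclei counting** from Hoechst z-stacks
  (sum-projection, mean + 2 SD threshold, watershed splitting);
* **endothelial scoring**: direction `(90° − α)/90°` of an endothelial
  spheroid's long axis toward the tumor, elongation (major/minor axis
  ratio), and their product, the orientation score;
* **a synthetic scene generator** that produces ground-truthed fiber
  fields (radial bias decaying exponentially with distance), DIC-like
  spheroid phantoms, nuclei stacks, and elliptical endothelial masks, so
  every stage is verifiable without microscopy data.

## Worked example

Fit the orientation decay of a synthetic field whose ground truth is
Y0 = 0.9, L0 = 500 µm (radial bias w0 = 0.8, so Y0 = 0.5 + 0.5·w0):

```python
import fiberorient as fo

params = fo.FiberFieldParams(
    image_size_px=(4096, 4096), pixel_size_um=0.67,
    tumor_center_px=(0.0, 0.0), tumor_radius_um=116.0,
    n_fibers=20_000, radial_bias_w0=0.8, decay_length_um=500.0, seed=1,
)
fibers = fo.generate_fiber_field(params)
model = fo.RadialOrientationModel.from_fibers(
    [fo.Fiber(f.centroid_px, f.angle_deg, 25, 0.95) for f in fibers],
    tumor_center_px=(0, 0), tumor_radius_um=116.0, pixel_size_um=0.67,
)
print(model.fit().summary())
```

```
Radial collagen orientation fit
============================================
fibers used                 20000
populated bins                 56
Y0 (edge orientation)      0.9201 +/- 0.0621 (95% CI)
L0 (decay length, um)       475.8 +/- 86.3 (95% CI)
integrated orientation (um)       199.9
orientation extent (um)          2918.0
fit window x > 100 um on 55 bins
```

The edge orientation (0.92 vs 0.90) and decay length (476 µm vs 500 µm) are
recovered within sampling noise; the integrated orientation ≈ 200 µm is the
area between the fitted curve and the 0.5 baseline; the extent says the
alignment stays statistically distinguishable from random out to ~2.9 mm.

For real images, `extract_fibers` turns a reflection TIFF into the fiber
list, `segment_spheroid` supplies the tumor center and radius from the DIC
image, and `run_well` (or the `fiberorient analyze-well` CLI with a YAML
config) orchestrates the whole per-well analysis into CSV tables and a JSON
summary.  `compare_regions` reproduces the severed-versus-connected region
statistics (rank-sum on per-fiber orientation distributions).

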