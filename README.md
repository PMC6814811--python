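# contactq

Quantification of ER–mitochondria membrane contact sites in 2D
electron-microscopy cross-sections, with the accompanying fluorescence
line-profile analysis and cohort statistics.

## The problem

At membrane contact sites, ER membranes run within a few tens of nanometres
of the mitochondrial outer membrane (MOM). Given manually traced membranes
from EM sections (or integer label masks), `contactq` measures, per
mitochondrion:

- **Dilation-band ER lengths.** Conceptually the MOM is dilated outward in
  N = 30 increments of Δ = 1 nm; `L_i` is the total ER membrane length
  within distance `i·Δ` of the MOM, and `l_i = L_i − L_{i−1}` is the length
  inside band `i` (the annulus `((i−1)Δ, iΔ]`).
- **Contact length** `L = Σ_{i=1}^{30} l_i`.
- **Average contact distance** `D = Δ · (Σ i·l_i) / (Σ l_i)` (nm).
- **ER–mitochondria contact coefficient**
  `ERMICC = L / (P · D)` (nm⁻¹), with `P` the mitochondrial perimeter.

Cohorts of mitochondria from two experimental groups (e.g. wild-type vs
knock-out) are pooled per mitochondrion, summarized as mean ± s.e.m., and
compared with a two-tailed unpaired t-test. A separate module analyses
multi-channel fluorescence line profiles: min–max normalization, peak
localization, and the test whether a query channel's peak lies *between* two
flanking organelle markers.

Because the underlying EM segmentations of such studies are rarely
deposited, the package includes a first-class synthetic-scene generator
(perturbed-circle mitochondria with concentric ER arcs at prescribed
distances and coverages) whose ground-truth metrics are exact by
construction, plus a rasterizer producing label-mask fixtures, so the whole
pipeline is testable end to end.

## Worked example

```python
import contactq as cq

# one circular mitochondrion (r = 500 nm), one concentric ER arc at
# d = 12 nm covering 25% of the perimeter
spec = cq.SceneSpec(seed=1, n_mitochondria=1, shape_noise_amp_nm=0.0,
                    trace_jitter_nm=0.0, out_of_range_fraction=0.0,
                    mito_radius_nm_spec=500.0, er_arcs_per_mito_spec=1.0,
                    arc_distance_nm_spec=("uniform", 12.0, 12.0),
                    arc_coverage_frac_spec=("uniform", 0.25, 0.25))
scene, truth = cq.generate_scene(spec)
metrics, bands = cq.measure_scene(scene)
print(metrics[["mito_id", "P_nm", "L_nm", "D_nm", "ermicc_per_nm"]])
```

prints

```
  mito_id        P_nm        L_nm  D_nm  ermicc_per_nm
0  mito_0  3141.59056  802.711383  12.0       0.021293
```

The perimeter is `2π·500 ≈ 3141.6 nm`; the ER arc contributes
`0.25·2π·512 ≈ 804 nm` of contact length, all of it in band 12, so
`D = 12 nm` exactly and `ERMICC = L/(P·D) ≈ 0.0213 nm⁻¹` — within 0.2% of
the closed form `0.25·2π·512/(2π·500·12) = 0.021333 nm⁻¹`.

The same measurement from the command line:

```bash
contactq simulate --seed 7 --out scenes/
contactq measure --scene scenes/synthetic_traces.csv --pixel-size 1.0 \
                 --out metrics.csv --bands bands.csv
contactq compare --table metrics.csv --metric ermicc_per_nm --out stats.json
contactq profile --in profile.csv --query GFP --flanks Tom20,Sec61b \
                 --out report.json
```

`measure` also accepts paired integer label masks
(`--mom mom.tif --er er.tif`); filled MOM regions are contoured at sub-pixel
resolution and thin ER rasters are traced through their skeletons.

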