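# pdmap

**3D, cell-type- and interface-resolved quantification of plasmodesmata
pit fields in plant roots.**

Plant cells communicate directly through plasmodesmata (PD), cytoplasmic
channels crossing the cell wall, typically grouped into *pit fields*. How
many pit fields a given cell–cell wall carries — and how they are arranged
on it — sets the capacity of the symplastic transport route between those
two cells. `pdmap` maps punctate PD-marker fluorescence from dual-channel
confocal z-stacks onto the individual cell–cell interfaces of a segmented
root and quantifies, per interface and per cell-type pair:

- **Total Signal** — the summed binarised pit-field signal on the
  interface, `S = Σᵥ xᵥ·aᵥ` over interface vertices with binary signal `xᵥ`
  and barycentric vertex area `aᵥ` (μm² of signal-positive wall);
- **Signal Density** — `D = S / A`, Total Signal per unit interface area
  `A`; both are reported as percentages of the sample total, so that all
  retained interfaces sum to 100 %;
- **Moran's I** — the spatial autocorrelation of the binary signal across
  the interface mesh,

  `I = (N/W) · Σᵢⱼ wᵢⱼ (xᵢ−x̄)(xⱼ−x̄) / Σᵢ (xᵢ−x̄)²`,

  with binary edge-sharing adjacency `wᵢⱼ`: −1 for perfectly alternating
  signal (a checkerboard), ≈ −1/(N−1) for random placement, approaching +1
  for segregated/clustered placement.

The workflow mirrors quantitative 3D tissue imaging practice: cells are
segmented from the wall-stain channel by a 0.5 μm Gaussian blur and an
automatically seeded watershed; cell surfaces are meshed as a shared
cell-complex at a 0.5 μm sampling step (0.2 μm for spatial statistics)
with 10 smoothing passes; cells are assigned to concentric layers
(epidermis, cortex, endodermis, …) in a cylindrical coordinate system on
the estimated root axis; walls are classified as apical–basal, radial or
circumferential from their mean normal; the marker channel is
max-projected onto each wall within ±0.5 μm, background-trimmed with a
threshold that decreases into inner layers (photobleaching/depth
compensation), binarised, and quantified. Interfaces smaller than 3 μm²
are removed. Group comparisons use Welch's t-test with the star ladder
\* p<0.01, \*\* p<0.005, \*\*\* p<0.001.

Because real stacks are rarely shareable, the package ships a first-class
synthetic-root generator: a radially layered cylindrical root with
analytic wall geometry, a rendered wall-stain channel, and pit-field spots
placed by uniform-Poisson or Thomas-cluster point processes with known
per-class rates — ground truth for every pipeline stage.

## Worked example

```python
from pdmap import (PipelineParams, PitFieldParams, ProjectionParams,
                   RootGeometryParams, run_pipeline, simulate_root)

sample = simulate_root(RootGeometryParams(), PitFieldParams(seed=5))
params = PipelineParams(projection=ProjectionParams(base_trim=0.2, layer_decay=1.0))
result = run_pipeline(sample.pd_channel, labels=sample.labels, params=params)
print(result.table.groupby("orientation_class")
      [["pct_total_signal", "morans_I"]].mean().round(3))
```

prints (seed 5, default study conditions):

```
                   pct_total_signal  morans_I
orientation_class
apical_basal                  0.524     0.623
circumferential               0.303     0.630
radial                        0.329     0.613
```

The generator placed pit fields at a 4:1:1 rate ratio
(apical_basal : radial : circumferential), and the recovered mean
% Total Signal ranks apical–basal walls first; the positive Moran's I
values say that binarised pit-field signal forms contiguous patches rather
than scattered vertices. `examples/` contains one short script per
capability (simulation, segmentation, meshing, quantification, Moran's I
anchors, condition comparison), each printing what it computes.

## Command line

```bash
pdmap simulate --config sim.yaml --out sim/          # synthetic sample + truth
pdmap segment sim/wall.tif --blur 0.5 --out labels.tif
pdmap quantify --pd sim/pd.tif --labels labels.tif --out table.csv
pdmap report --group-a meristem*.csv --group-b transition*.csv \
             --metric pct_total_signal --out report/
```

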