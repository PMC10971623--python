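# aortoiliac

Morphometry of branched aortoiliac arterial centerlines: arterial-elongation
metrics (tortuosity index, average absolute curvature) and aortic-bifurcation
geometry (take-off / bifurcation / planarity angles, angle asymmetry,
near-bifurcation cross-sectional areas, and Murray's-law radius discrepancy),
plus a seeded synthetic-geometry generator used as the test bed.

All coordinates and radii are millimeters, all angles degrees. The patient
coordinate frame is declared per file (`LPS` default, `RAS` supported) and
determines left/right anatomical assignment; no unit or frame conversion is
ever inferred.

## Metric definitions

- **Tortuosity index (TI, %)** = `(L/D - 1) * 100`, with `L` the centerline
  arc length and `D` the straight endpoint distance.
- **Average absolute curvature (AAC, 1/mm x 1000)**: curvature is the
  reciprocal circumradius of each sample point and its two neighbours at
  5 mm arc-length intervals (endpoints excluded); AAC is the mean sample,
  scaled by 1000.
- **Bifurcation frame**: unit aorta flow vector `f` and daughter vectors
  `v_left`, `v_right` from least-squares line fits within 15 mm of the
  junction; plane normal `n = unit(f x (v_left - v_right))`, so the aorta
  lies in-plane. Take-off angles are measured between in-plane daughter
  projections and `f`; the bifurcation angle between the two projections;
  planarity is `|arcsin(v . n)|`.
- **Asymmetry** = `(theta_L - theta_R) / (theta_L + theta_R)`.
- **Murray's-law conformance**: mean cross-sectional areas (`pi r^2` from
  inscribed-sphere radii, sampled every 5 mm within 15 mm of the junction)
  give measured radii; `r_ideal = r_aorta * 2^(-1/3)` and
  `r_discrepancy = (|r_L - r_ideal| + |r_R - r_ideal|) / 2`.

## Pipeline

`analyze` runs smooth → resample → label → metrics:

1. Endpoint-pinned Laplacian smoothing of each branch polyline
   (factor 0.1, 100 iterations by default).
2. Arc-length resampling at 5 mm (plus the exact original endpoint).
3. Automatic anatomical labeling of root aorta, left/right common iliac
   arteries (by lateral centroid in the declared frame) and their external
   iliac continuations (by larger mean radius, or smallest deviation angle
   when radii are absent).
4. Elongation metrics per segment and bifurcation metrics at the junction,
   written to a fixed-schema report CSV with full provenance.

## CLI

```sh
# analyze one or more centerline files (csv | vtp | json dialects)
aortoiliac analyze --in subject.csv --format csv --out report.csv \
    [--config cfg.yaml] [--spacing-mm 5] [--window-mm 15] [--frame LPS]

# generate synthetic fixtures with ground-truth sidecars
aortoiliac simulate --preset murray_symmetric_52deg --out fixtures/
aortoiliac simulate --kind helix --param r=10 --param c=5 --param turns=1 \
    --seed 7 --out fixtures/
```

Config YAML schema (defaults shown):

```yaml
smoothing: {factor: 0.1, iterations: 100}
resample: {spacing_mm: 5.0}
curvature: {spacing_mm: 5.0}
bifurcation: {window_mm: 15.0, area_spacing_mm: 5.0}
frame: LPS
radius_array: MaximumInscribedSphereRadius
```

Command-line flags override config-file values; all effective parameters are
logged to stderr and embedded in each report row's provenance column.

### Input dialects

- **CSV**: header `branch_id,point_index,x,y,z[,radius][,parent_id][,label]`.
  Without `parent_id`, connectivity is inferred from shared endpoints
  (children attach within 1 mm of a parent point).
- **VTP**: ASCII VTK XML PolyData, one branch per polyline cell; per-point
  radius array name configurable (default `MaximumInscribedSphereRadius`).
- **JSON**: `{"coordinate_frame": "LPS", "branches": {id: {"points": [[x,y,z],...],
  "radius": [...], "parent": id|null, "label": str|null}}}`.

### Preset registry

| preset | contents |
| --- | --- |
| `murray_symmetric_52deg` | symmetric 26°/26° planar bifurcation, Murray-conforming radii |
| `tilted_left_10deg` | both daughters hinged 10° out of the construction plane (left planarity exactly 10°) |
| `asymmetric_30_20` | 30°/20° take-offs (asymmetry 0.2) |
| `elderly_tortuous` | high-amplitude sinusoidal single segment (bounds-only truth) |

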