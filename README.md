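# memthick

Membrane bilayer thickness from cryo-electron tomograms, measured on
triangulated surface meshes.

## The problem

In cryo-ET data collected at low-to-medium defocus, a lipid bilayer shows
up as two parallel rows of density — the opposing phospholipid head groups
(PHG). The distance between those two density peaks is the standard
readout of membrane thickness, and it varies with lipid and protein
composition between organelles (outer vs inner mitochondrial membrane,
ER, vesicles) and even between subcompartments of a single contiguous
membrane. Voxel-segmentation-based thickness estimates inherit the width
of the segmentation, which tends to overestimate; this package instead
samples the *original* tomogram density along the normals of a surface
mesh that models the bilayer mid-surface, so the measurement is
independent of how the segmentation was produced.

`memthick` is aimed at cryo-ET practitioners who already have (a) a
reconstructed tomogram (MRC) and (b) triangulated surface meshes of their
membranes (PLY), e.g. from a surface-morphometrics style pipeline, and
want per-triangle and per-surface thickness measurements, subcompartment
statistics, and particle-centered patch analysis.

## The measurement

For every mesh triangle, the tomogram density is trilinearly interpolated
along the triangle normal at 0.25 nm steps over ±10 nm — a *line scan*
with two head-group peaks. The scan is fitted with a two-Gaussian model

    f(x) = b + A₁ exp(−(x−μ₁)²/2σ₁²) + A₂ exp(−(x−μ₂)²/2σ₂²)

and the thickness is the peak separation **t = μ₂ − μ₁**. Fits are
accepted only for 1 nm ≤ t ≤ 8 nm (physically plausible bilayers).
Because individual tomographic scans are far too noisy to fit, two
averaging modes exist:

* **global** — all scans of a surface are averaged, then fitted once;
* **local** — each triangle's scan is averaged with all triangles within
  a 12 nm *geodesic* radius, weighted by w = 1/(1 + d) with d the
  geodesic distance (nm), then fitted per triangle.

Triangles within 8 nm (geodesic) of a mesh boundary are excluded —
missing-wedge artifacts corrupt densities near surface edges. Per-surface
summaries use the triangle-**area-weighted median**; between-group
comparisons treat surfaces as observations (mean ± 1.96·SE across
per-surface medians, two-sided Mann–Whitney U).

Also included:

* IMM subcompartment classification (inner boundary membrane / crista
  junction / crista body) from each face's distance to the OMM relative
  to the per-surface mode distance (< 4 nm excess → IBM, 4–14 nm → CJ,
  > 14 nm → CB);
* particle-centered patches (nearest face within 24 nm, 12 nm geodesic
  radius) with matched randomized controls (> 12 nm center separation)
  and extended −10 → +30 nm profiles along particle-curated normals;
* curvedness-quantile stratification (0–0.5, 0.5–0.9, 0.9–0.95,
  0.95–0.99, 0.99–1) of thickness;
* synthetic phantoms (plane / sphere / two-slab / strip / cristae, with
  optional blobs and noise) with exact analytic ground truth.

## Worked example

```python
import memthick as mt

# a synthetic "tomogram": an obliquely oriented bilayer with 3.6 nm
# head-group separation at 0.998 nm voxels, at realistic noise
spec = mt.PhantomSpec(geometry="plane", phg_separation=3.6, seed=0).noisy()
phantom = mt.rasterize_bilayer(spec)

mesh, vol = phantom.mesh, phantom.volume
graph = mt.build_face_graph(mesh)
edge = mt.edge_exclusion_mask(mesh, graph, margin=8.0)

t_global, fit = mt.measure_global_thickness(vol, mesh, graph, mask=edge)
tmap = mt.measure_local_thickness(vol, mesh, graph, radius=12.0, mask=edge)
summary = mt.summarize_surface(tmap.thickness, mesh.face_areas,
                               surface_id="phantom", label="plane")

print(f"faces: {mesh.n_faces} ({int(edge.sum())} edge-excluded)")
print(f"global thickness: {t_global:.3f} nm (truth 3.6)")
print(f"peak positions:   mu1 = {fit.mu1:.3f} nm, mu2 = {fit.mu2:.3f} nm")
print(f"local fits:       {100 * tmap.convergence_fraction:.1f}% converged")
print(f"area-weighted median thickness: {summary.median_thickness_nm:.3f} nm")
```

prints

```
faces: 1922 (954 edge-excluded)
global thickness: 3.597 nm (truth 3.6)
peak positions:   mu1 = -1.808 nm, mu2 = 1.789 nm
local fits:       100.0% converged
area-weighted median thickness: 3.597 nm
```

i.e. the two head-group peaks sit near ±1.8 nm and their separation
recovers the built-in 3.6 nm PHG spacing to a few hundredths of a nm,
despite the noise — that is what the 12 nm distance-weighted averaging
buys.

A command-line interface wraps the same pipeline:

```bash
memthick phantom --spec spec.yaml --out phantom_out/
memthick thickness --config run.yaml
memthick classify-imm --imm imm.ply --omm omm.ply --out labels.csv
memthick patches --config run.yaml
memthick report --summaries surfaces.csv --out compare.json
```

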