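# conemosaic

Topological-defect analysis and growth models for the zebrafish cone
photoreceptor mosaic.

The outer retina of zebrafish carries a crystalline arrangement of cone
photoreceptors.  Its UV-cone sublattice is an anisotropic triangular
lattice — about 10.25 µm between cones along a row, 12.25 µm within a
column, a column-to-row ratio of roughly 6/5 instead of the isotropic
√3 — whose rows radiate from the retinal center while new cones are added
at the rim.  Because the circumference grows, rows must be inserted to keep
the spacing constant.  Each insertion is a **Y-junction**: an edge
dislocation of the lattice, a five/seven-coordinated pair of UV cones with
Burgers vector equal to the oblique lattice vector

    |b| = sqrt((a_row/2)² + (a_col/2)²) ≈ 8 µm ,

the smallest deformation any insertion can carry (a double-row insertion
costs |b| = a_col ≈ 12 µm).  Y-junctions organize into radial **grain
boundaries** separating domains of different row orientation, and they do
so *as the mosaic forms*, not by later defect motion (glide, a single bond
flip in the triangulation per row of motion, is limited to about one row
per two days).

This package is for quantitative biologists and biophysicists studying
pattern formation in growing epithelia.  It provides, as a tested pipeline
working on point sets and row tracings rather than raw images:

- `conemosaic.synthetic` — a ground-truthed generator of UV-cone mosaics
  on a flattened cone frustum: planted Y-junctions (uniform, clustered into
  grain boundaries, or scheduled), row traces, full-mosaic decoration
  (1 UV : 1 Blue : 2 Green : 2 Red per unit cell), and two-timepoint
  "photoconversion" pairs with optional glide events;
- `conemosaic.defects` — triangulation (in isotropy-restoring
  coordinates), coordination census, dislocation cores, Burgers circuits,
  rigid registration of timepoints, glide (bond-flip) detection, plane
  fitting, glide/shuffle honeycomb core classification, vacancy search;
- `conemosaic.grain_boundary` — the five-box row-rotation detector
  (Δφ_rms against a 12° cutoff), the chain-linearity detector
  (a_gb = 7/8), row bonds for simulated peak lattices, margin domain
  rotation;
- `conemosaic.pfc` — an anisotropic phase-field-crystal model of
  repulsive, fate-committed cones: conserved dynamics
  ∂ψ/∂t = ∇²([R + (1+∇s²)²]ψ + ψ³) with the stretch
  b = sqrt(√3·a_row/a_col) on the radial direction, solved
  spectrally/finite-difference with a first-order implicit–explicit
  scheme (Δt = 0.075) on rectangles and cone frusta;
- `conemosaic.lateral_inhibition` — the contrasting model: static
  disordered packings with inhibitory signaling of range *l*, showing the
  excess defect load when *l* approaches the cell size;
- `conemosaic.growth_stats` — the Monte-Carlo null-model rank-sum test for
  whether new Y-junctions form preferentially near existing boundaries;
- a `conemosaic` command-line interface tying these together.

## Worked example

```python
import numpy as np
from conemosaic.lattice import make_lattice_spec
from conemosaic import synthetic as syn
from conemosaic.defects import triangulate, find_dislocations, burgers_circuit

spec = make_lattice_spec()            # a_row = 10.25 um, a_col = 12.25 um
alpha = 2 * spec.a_col / spec.a_row   # two row insertions per added column

sched = syn.CustomSchedule([(14, 0.3 * alpha, "Y"), (14, 0.7 * alpha, "Y")])
sample = syn.build_frustum_mosaic(spec, 120, 28, insertion_mode=sched, seed=0)
tri = triangulate(sample.xy, wrap=("angle", alpha), spec=spec, center=(0, 0))
cores, _ = find_dislocations(tri, spec, (0, 0))
for c in cores:
    b = burgers_circuit(tri, c, circuit_radius=2, spec=spec, center=(0, 0))
    print(c.kind, round(np.linalg.norm(b), 3))
```

prints

```
Y 7.986
Y 7.986
```

— the two planted insertions are recovered as Y-junctions whose Burgers
circuits fail to close by exactly one oblique lattice vector,
7.986 µm ≈ 8 µm.

The headline simulation, from the shell:

```
conemosaic pfc-scan --rows 60 --columns 30 --r-list=-0.15,-0.2,-0.25 \
    --seeds 0,1,2 --out scan.json
```

grows nine anisotropic crystals on the frustum along the
ψ₀ = −√(−R)/2 cut, extracts the density peaks, finds the Y-junction peaks
through their three row bonds, and reports the fraction sitting in grain
boundaries at the 12° cutoff; the mean fraction is well above one half —
repulsion-driven crystallization on the growing cone groups its defects
into grain boundaries without any defect motion.

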