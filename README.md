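# statphantom

How much does the dose absorbed by an organ depend on the size of that
organ?  Reference voxel phantoms represent a 50th-percentile individual,
but real lungs in a fixed height/weight percentile vary widely (adult-male
total lung mass is approximately Gaussian, 1246 ± 322 g).  `statphantom`
quantifies the resulting uncertainty in the **lung-absorbed dose per
fluence (LADF)** for external photon beams: it builds a population of
voxel thorax phantoms that differ *only* in lung mass, irradiates each one
with broad parallel beams in the six standard geometries (AP, PA, LLAT,
RLAT, ROT, ISO), and reports the mean, standard deviation and coefficient
of variation of the LADF as a function of photon energy.

The statistics are the population forms

```
SD = sqrt( Σᵢ (Dᵢ − D̄)² / N ),        CV = SD / D̄,
```

where `Dᵢ` is the LADF (pGy·cm²) of phantom `i` and `N` the series size.
The pipeline is:

1. **Template** — a procedural labeled voxel thorax (2.137 mm in-plane,
   8 mm slices) whose lung matches the reference inventory: lobar volumes
   1586.02 / 1325.17 cm³ with embedded blood-vessel trees (blood masses
   71.54 / 79.01 g at 1.06 g/cm³, lung tissue at 0.382 g/cm³, total lung
   mass 1208.37 g), lobar centroids fixed at (20.92, 14.79, 137.1) and
   (34.86, 15.8, 137.2) cm.
2. **Series** — N masses drawn from N(1246, 322²) g and converted to
   target volumes by the relative density ρ_re = 1208.37 g / 2911.190 cm³.
3. **Deformation** — each lobe rescaled about its fixed centroid to the
   target volume (level-set style resample + bisection volume matching),
   vessels matched proportionally, rib cage refit with the same linear
   factor, lung/heart/liver overlaps resolved by policy (`lung_wins` or
   `organ_wins`), deflation voids refilled with residual tissue.
4. **Transport** — an in-package photon Monte Carlo on the voxel grid
   (analog transport, track-length kerma scoring, Klein–Nishina Compton
   sampling, pair production, 2 keV cutoff) with fluence normalization
   per beam geometry.
5. **Statistics** — per-(energy, geometry) mean/SD/CV, normalized D/D̄
   histograms, MC noise floor, and reference-interval flags.

## Worked example

```python
from statphantom.pipeline import StudyConfig, run_study

config = StudyConfig.from_dict({
    "seed": 0,
    "output_dir": "out",
    "template": {"spacing": [0.4274, 0.4274, 0.8]},   # half-resolution demo
    "population": {"n": 20},
    "beam": {"energies": [0.015, 0.1, 1.0, 10.0],
             "geometries": ["AP"], "histories": 100_000},
})
result = run_study(config)
print(result.reports[["energy_MeV", "geometry", "mean", "cv"]])
```

On a 20-phantom series this package computes (AP geometry, high-statistics
run; CV in percent):

```
energy (MeV)   mean LADF (pGy·cm²)   CV (%)   MC noise floor (%)
0.015          0.0100                104.2    15.7
0.1            0.417                 1.91     0.27
1.0            4.32                  1.00     0.26
10.0           23.7                  0.65     0.27
```

Read: at 15 keV the lung dose is essentially unpredictable from a
reference phantom (CV ≈ 100% — a big lung sits closer to the skin and
absorbs far more of a weakly penetrating beam), while above ~1 MeV the
dose is nearly independent of lung size (CV ≈ 1%), so a single reference
value describes the whole population.  A CLI mirrors the library
(`statphantom study run --config study.yaml`).

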