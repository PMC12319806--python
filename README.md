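# tractgr — tract-specific aggregate g-ratio mapping

The g-ratio of a myelinated axon — the ratio of inner to outer diameter of
the myelin sheath — modulates conduction velocity along white-matter tracts.
It can be mapped in vivo by combining a myelin-sensitive MRI contrast
(magnetization transfer saturation, MTsat) with diffusion compartment
fractions. The conventional approach, *tractometry*, samples the voxel-wise
g-ratio map along tractography streamlines and averages — but most
white-matter voxels contain several crossing fiber populations, so
tractometry mixes the properties of unrelated tracts.

`tractgr` implements a *tract-specific* alternative: the diffusion and
myelin signals of each voxel are modeled as non-negative linear combinations
of contributions from the individual streamlines traversing it
(a convex microstructure-informed tractography formulation).  Solving these
global systems yields each streamline's intra-axonal and myelin
cross-sectional areas, hence per-tract intra-axonal volume (AV) and myelin
volume (MV), from which the aggregate g-ratio of a connectome edge follows
without partial-volume mixing.  The package is aimed at diffusion-MRI
methods researchers and ships a synthetic crossing-fiber phantom generator
so every stage is testable against exact ground truth without any scan data.

## Model

Voxel-wise, with myelin volume fraction MVF, isotropic (free-water) fraction
ISOVF and intra-neurite fraction ICVF:

```
AVF = (1 − MVF) (1 − ISOVF) ICVF          (intra-axonal volume fraction)
g   = sqrt( AVF / (AVF + MVF) )           (aggregate g-ratio)
MVF = α_calib · MTsat                     (linear myelin calibration)
```

α_calib is fixed by asserting a reference g-ratio of 0.7 in a high-FA
single-fiber calibration region.  Tract-wise, the diffusion signal is
decomposed with a stick–zeppelin–ball dictionary
(D∥ = 1.7·10⁻³ mm²/s, D⊥ = 0.51·10⁻³ mm²/s, D_iso = {1.7, 3.0}·10⁻³ mm²/s)
in three non-negative least-squares solves:

1. **filter** — fit the raw b0-normalized signal; streamlines with zero
   weight are implausible and removed; a volumetric tract-ICVF map results;
2. **myelin** — fit in-voxel streamline lengths to MVF·V_voxel, giving each
   streamline's myelin cross-sectional area (MV = area × length);
3. **true axonal** — refit the signal rescaled by (1 − MVF), the myelin
   correction, giving the true intra-axonal area (AV = area × length).

Edge g-ratio is `sqrt(AV_edge / (AV_edge + MV_edge))` over the summed
member-streamline volumes.  Cohort edge filters (bottom-80 % caliber
removal, 50 % consensus) and scan–rescan statistics (ICC(2,1),
Bland–Altman, coefficient of variation, a caliber/length mixed-effects
model) complete the pipeline.

## Worked example

Run the full two-branch pipeline on the default crossing phantom — two
50-streamline bundles with ground-truth g-ratios 0.60 and 0.80 whose paths
mix along a shared corridor, plus 10 implausible streamlines:

```python
from tractgr.phantom import two_bundle_spec
from tractgr.pipeline import run_phantom_pipeline

result = run_phantom_pipeline(two_bundle_spec(seed=0))
cols = ["bundle", "g_true", "g_tract_specific", "g_tractometry"]
print(result.comparison[cols].round(4).to_string(index=False))
kept = len(result.filter_result.kept_indices)
print(f"streamlines kept by filtering: {kept}/{len(result.streamlines)}")
```

prints

```
 bundle  g_true  g_tract_specific  g_tractometry
      0     0.6            0.6010         0.6776
      1     0.8            0.8007         0.7206
streamlines kept by filtering: 85/110
```

The tract-specific estimates recover each bundle's true g-ratio to ~0.001,
while tractometry pulls both bundles toward each other (0.68 / 0.72) because
its per-streamline medians average over voxels where the two populations
mix.  All 10 implausible streamlines are filtered out (85 kept of 100 true
streamlines: the remaining volume is reassigned among near-duplicate
bundle members, leaving bundle totals intact).

A command-line interface mirrors the library:
`tractgr phantom`, `tractgr fit`, `tractgr maps mtsat|calibrate|gratio`,
`tractgr connectome`, `tractgr tractometry`, `tractgr stats`.

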