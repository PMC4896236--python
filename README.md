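# ptmscope

Physicochemical interface descriptors from conformational ensembles, for
predicting how post-translational modification (PTM) patterns — in
particular serine phosphorylation at the interfaces of multimeric
proteins — shift a complex between compact and detaching states.

## The problem

Many regulatory proteins (small heat-shock proteins such as αB-Crystallin
are the canonical case) switch oligomeric state when a few interface
serines are phosphorylated. Simulating every modified form of a large
multimer to convergence is impractical, but *short* molecular-dynamics
ensembles of the smallest interface-bearing unit already carry a usable
signal. `ptmscope` extracts that signal as nine physicochemical
parameters per PTM variant and classifies the variants statistically.

## The method

For each variant's conformational ensemble (multi-model PDB, or XTC/DCD
with a PDB topology), restricted to its equilibrated window:

| parameter | meaning |
|---|---|
| Total SAS | solvent-accessible surface area of the complex, Å² (ensemble mean) |
| Hydrophobic SAS | SAS of carbon/sulfur atoms of apolar residues, Å² |
| Buried SAS | Σ single-chain SAS − complex SAS, Å² (interface burial) |
| HB | mean number of inter-chain hydrogen bonds per frame |
| Gap_Index | gap volume / interface ASA, Å (interface packing quality) |
| Volume | inter-chain gap volume by the gap-sphere method, Å³ |
| E_LJ | absolute inter-chain Lennard-Jones energy, kJ/mol |
| AbsMin | occupancy of the deepest free-energy-landscape minimum |
| #Min | number of minima reaching 70 % of the deepest one |

SAS is Shrake–Rupley sphere sampling (probe 1.4 Å). Gap_Index and Volume
are computed on the representative conformation — the central structure
of the largest GROMOS conformational cluster (Cα RMSD cutoff 0.3 nm) —
by filling the inter-chain cleft with maximal non-clashing spheres (0.8 Å
raster, 5 Å distance cutoff). AbsMin and #Min come from the free-energy
landscape: the ensemble is projected on its first two principal
components of Cα motion (essential dynamics), histogrammed on a 20×20
grid, and scored by sliding 3×3 occupancy boxes with non-maximum
suppression.

The statistical layer combines the nine parameters with one binary
indicator per modifiable site (1 = phosphorylated), optionally normalizes
wild-type/modified pairs by their per-variable means, and runs
correlation-matrix PCA, k-means on the leading component scores, and a
Pearson correlation map of site indicators against descriptors
(significance mask |r| > 0.30).

A synthetic module generates toy dimers, ensembles with planted
covariance modes or free-energy basins, and feature tables with planted
cluster structure, so every stage is testable against known ground
truth without running MD.

## Worked example

Descriptors for a synthetic two-chain complex whose ensemble hops between
two planted conformational basins:

```python
import ptmscope as pt

dimer = pt.make_toy_dimer(pt.ToySpec(n_res_per_chain=9, separation=2.0, seed=1))
ens = pt.make_basin_ensemble(dimer, pt.BasinSpec.well_separated(2, n_frames=60, seed=0))
cfg = pt.PipelineConfig()
cfg.descriptor.n_points = 240
cfg.descriptor.stride = 3
vec = pt.compute_descriptors(ens, cfg)
for name, value in vec.as_row().items():
    print(f"{name:16s} {value:10.3f}")
```

prints

```
Total SAS          1556.620
Hydrophobic SAS     950.479
Buried SAS          161.826
HB                    0.000
Gap_Index             4.861
Volume              408.064
E_LJ                 12.054
AbsMin                0.250
#Min                  2.000
```

The 2 Å interface separation buries ~162 Å² of surface and leaves a
408 Å³ cleft (Gap_Index 4.9 Å — a loose interface); the two planted
basins are recovered exactly (#Min = 2), each holding about a quarter of
the occupancy in its deepest 3×3 box (AbsMin 0.25).

The same operations are scriptable from the shell, e.g.

```sh
ptmscope simulate dimer --seed 7 --out dimer.pdb
ptmscope gap --pdb dimer.pdb --out gap.json
ptmscope simulate study --seed 3 --out feats.csv
ptmscope analyze --features feats.csv --indicators P --n-pcs 3 --k 2 --seed 42 --out-dir run/
```

Fixed seeds make every output byte-reproducible.

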