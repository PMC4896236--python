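# Methods

This note records the model behind each stage of the pipeline, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic generators do and do not emulate.

## Scope and model

The package quantifies how a pattern of interface phosphorylations moves
a multimeric complex along a compact ↔ detached axis. Its unit of
analysis is one *system*: a PTM variant of the smallest interface-bearing
subunit (typically a two-chain dimer), represented by a conformational
ensemble over a shared topology. Nine descriptors summarize the system;
binary site indicators encode its modification state; a statistical layer
classifies systems and attributes effects to sites. Generating the
ensembles (MD engines, force fields, solvation) and building modified
structures are outside the package's scope — it consumes coordinates.

## Structures, ensembles, equilibration

Coordinates are Å internally. PDB reading/writing goes through Biopython;
multi-MODEL files become ensembles; binary trajectories (XTC/DCD) are
read via MDAnalysis against a PDB topology. Van der Waals radii come from
a bundled Bondi-style element table; unknown elements fall back to 1.7 Å
with a warning. Phospho-serine is recognised by residue code (SEP) or an
explicit flag — the statistical layer needs the on/off state, not
phosphate atoms.

Equilibration is detected from the Cα RMSD series (nm, Kabsch
superposition, mass-unweighted): a sliding linear fit of length 10 % of
the trajectory (minimum 3 frames) is scanned, and the equilibrated window
starts at the first frame from which every subsequent slope magnitude
stays within 1e-4 nm/frame. This is a deterministic surrogate for the
visual plateau-reading usually applied to RMSD plots. A series that never
flattens falls back to the last half of the trajectory, with a warning,
so downstream averages always have data. The detection is idempotent.

## Surface and energetic descriptors

*SAS.* Shrake–Rupley sampling with a golden-spiral point set, 960
points/atom by default, probe 1.4 Å. Any converged estimator would do —
only averages and differences between systems enter the statistics — and
sphere sampling is directly testable against the analytic isolated-sphere
and two-sphere-union areas (tests also cross-check against mdtraj's
independent implementation to 1 %). Hydrophobic SAS sums the accessible
area of carbon/sulfur atoms in ALA, VAL, LEU, ILE, MET, PHE, TRP, PRO,
GLY (configurable; there is no universal definition of "hydrophobic
surface", so the set is explicit). Buried SAS is Σ isolated-chain SAS −
complex SAS, chains kept in their complex conformation; it is therefore
non-negative up to sampling noise and vanishes once the chains are
farther apart than two probe diameters.

*Hydrogen bonds.* Geometric criteria: donor–acceptor ≤ 3.5 Å and
hydrogen–donor–acceptor angle ≤ 30°, the common MD-analysis defaults;
donors are N/O atoms with a covalent hydrogen (≤ 1.25 Å). Structures
without hydrogens (crystal structures) use the heavy-atom fallback:
each inter-chain polar pair within 3.5 Å counts once. Only bonds whose
donor and acceptor lie on different chains are counted, and the reported
value is the mean count per equilibrated frame (real-valued).

*Lennard-Jones energy.* 12-6 energy summed over inter-chain pairs within
10 Å, per-element σ/ε table with Lorentz–Berthelot combination, absolute
value reported. The table is deliberately minimal: the classification
consumes relative differences between PTM variants, not force-field-
accurate absolute energies.

## Representative conformation and gap geometry

The static interface parameters are computed on the *representative
conformation*: the central structure of the largest cluster from
GROMOS-style neighbor counting on pairwise Cα RMSD (cutoff 0.3 nm) over
the equilibrated window — repeatedly take the frame with most neighbors
within the cutoff as a center, remove it and its neighbors, and renumber
clusters by decreasing size. Ties break toward the lowest frame index, so
the procedure is deterministic.

The *gap-sphere* construction fills the inter-chain cleft: for every
inter-chain atom pair with positive surface-to-surface separation ≤ 5 Å,
a trial sphere sits at the midpoint of the inter-surface segment with
radius half the separation, is shrunk against the nearest clashing atom,
and is kept if its final radius is ≥ 1 Å. The kept spheres are rasterized
at 0.8 Å; the union volume is the gap volume. Rasterization happens in a
canonical frame derived from the sphere set itself (centroid origin;
axes from the farthest center and the center farthest from that axis).
Because that frame is exactly equivariant under rigid motion, the voxel
count — hence the volume — is invariant under rotation/translation of the
input, rather than merely stable to within many voxels as a lab-frame
grid would be.

Gap_Index divides the gap volume by the interface accessible surface
area. The denominator defaults to buried SAS / 2 (the per-side ΔASA
convention of interface analysis); a `total` mode uses the full ΔASA.
Note the denominator vanishes once the chains separate beyond two probe
diameters (~2.8 Å), at which point the index is reported as 0 with the
volume still meaningful.

## Free-energy landscape markers

Essential dynamics: equilibrated frames are superposed on their mean
(one refinement pass), the 3n×3n covariance of Cα coordinates is
eigendecomposed, and eigenvectors get a deterministic sign
(largest-magnitude component positive). The ensemble is projected on the
first two components and histogrammed on a 20×20 grid. Both axes are Å
along principal modes, so one common bin width (the larger axis range) is
used for both axes, each centered on its own data midpoint; per-axis
ranging would stretch a noise-dominated second axis across the whole grid
and fragment basins. Occupancy probabilities (frame fractions), not free
energies, are the working quantity; −kT ln p is computed only for
plotting, which avoids log(0) for empty bins.

AbsMin is the summed probability of the best 3×3 box — the population of
the deepest free-energy minimum. Minima are counted with *sliding* 3×3
windows: a window counts if it reaches 70 % of the best window's sum and
is a strict local maximum among the windows overlapping it (ties break
toward the lower row/column index). Sliding windows with non-maximum
suppression were chosen over disjoint tiling because tiling makes the
count depend on grid phase; suppression guarantees one count per basin
and the count is always ≥ 1. Reflecting an eigenvector leaves both
markers unchanged, since the centered binning is mirror-symmetric.

## Statistical layer

Features are ordered: the nine descriptors, then one indicator per site.
Hexamer-scale systems are represented by the element-wise mean of the
descriptor vectors of their assembled dimeric members. Pairwise
normalization (for wild-type/modified validation pairs) divides each
variable's two values by their pair mean — each normalized pair sums to
2 and within-pair ratios are preserved; indicators are exempt, and the
wild-type/modified classification runs on the nine general descriptors
only (`descriptors_only()`), since indicator columns would leak the
answer. A zero pair mean maps both entries to 1 with a warning.

PCA defaults to correlation-matrix form (center + unit-variance scale):
the columns mix Å², kJ/mol, counts and probabilities, and without scaling
the ~10³–10⁴ Å² surface terms would own every component. Loadings are
unit-norm eigenvectors signed like the ED modes; scores × loadingsᵀ
reconstructs the standardized data exactly. All components are kept; the
conventional retention rule (standard deviation > 1) is exposed as a
helper, and explained variance is available per-component and
cumulatively. Constant columns are dropped with a warning under scaling.

k-means runs on the first *n* component scores via scikit-learn's Lloyd
algorithm with k-means++ initialization and 50 restarts, deterministic
given the seed; the run metadata records the variant, since the classic
R implementation of this analysis uses Hartigan–Wong (at these problem
sizes the two converge to equivalent partitions, and the seed contract is
what binds). Cluster-count choice is left to the user (inertia is
reported for elbow inspection); no automatic selection is forced.

Site–descriptor attribution is the Pearson correlation of each indicator
column with each descriptor column, with a significance mask at
|r| > 0.30. Zero-variance columns yield r = 0, unflagged, with a warning.

## Synthetic generators

All generators are pure functions of their seed.

*Toy dimer*: two mirror-image chains of backbone-like residues (N, H,
CA, CB, C, O) on a square grid, facing across a planar interface whose
minimum surface-to-surface distance is the requested separation; 0.01 Å
jitter breaks exact symmetry. It emulates nothing about real protein
geometry except what the descriptors consume: chains, radii, polar atoms,
a tunable interface.

*Slab pair*: two flat uniform-atom slabs across a known gap, for the
analytic gap-volume oracle. The reported reference area is the slab's van
der Waals footprint (atom-center extent plus one radius per side), which
is the area the gap region actually spans.

*Harmonic / basin ensembles*: displacement modes are random unit vectors
in Cα coordinate space, orthogonalized against rigid-body translations
and rotations so a superposition-based analysis sees exactly the planted
variance; frames displace only Cα atoms. Basin ensembles draw latent 2-D
samples from a Gaussian mixture (centers ≥ 6 latent σ apart for the
well-separated guarantee; widths default to 1 latent unit ≡ 1 Å) and
embed them along two such modes. These are statistical, not physical,
ensembles: no bonded structure is preserved and non-Cα atoms ride along
rigidly — passing tests demonstrate recovery of planted covariance and
occupancy structure, not realism of protein dynamics.

*Feature study*: two regimes per synthetic protein — detached (exposure
and gap descriptors shifted up, packing descriptors shifted down) and
compact (the reverse) — with unit normal noise per scaled variable and
per-descriptor baselines on realistic magnitudes. Defaults are 8 systems
per regime and a 5 σ effect, the conditions under which the
classification chain is expected to separate the regimes perfectly.

## Problem sizes and numerical choices

The test and acceptance workloads use 9-residue chains (108 atoms),
ensembles of 40–1000 frames, 240–960 SAS points/atom, and 20 seeds per
stochastic claim — sizes at which every planted signal is comfortably
recoverable while the full suite runs in well under a minute per stage.
Degenerate inputs are handled explicitly: empty atom subsets warn and
return 0; ensembles with identical frames give zero covariance, a
single occupied landscape bin and AbsMin = 1; chains beyond the gap
cutoff return zero volume with a warning; a never-equilibrating
trajectory falls back to its last half.

## Known limitations

- The LJ and radius tables are per-element, not per-atom-type; energies
  are comparative only.
- The gap-sphere shrink step reduces radii but does not relocate
  centers; very tortuous interfaces may be under-filled.
- Heavy-atom hydrogen-bond counting has no angular term and can
  overcount close polar contacts.
- The equilibration rule assumes a monotone-then-flat RMSD shape;
  slow-relaxing or oscillating series trigger the last-half fallback.
- Landscape markers depend on the 20×20/3×3/0.7 conventions; they are
  stability *markers*, not converged free energies.
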