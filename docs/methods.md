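# Methods

This note documents the models and procedures `emfitkit` implements, the
parameters that matter, the numerical conventions, and what the synthetic
test conditions do and do not establish about behaviour on real data.

## Coordinate and file conventions

All lengths are ångströms.  Voxel indices are 0-based; the world position
of voxel `(i, j, k)` is `origin + (i, j, k) · voxel_size`, referring to
the voxel *centre*.  In memory every grid is in `(x, y, z)` axis order.

MRC-2014 reading honours the machine stamp (little- and big-endian files),
accepts modes 0, 1, 2 and 6, applies the `MAPC/MAPR/MAPS` axis
permutation, and resolves the origin as: the `ORIGIN` record if any
component is nonzero, otherwise `NSTART · voxel_size` (permuted to world
axes).  Writing always emits little-endian mode 2 with the identity axis
mapping.  gzip is detected by the two magic bytes, never by file name, in
both map and model I/O.  Supported header fields are exactly those listed
above plus cell dimensions, statistics (dmin/dmax/dmean/rms) and one
label; extended (symmetry) headers are skipped on read and never written.

Model reading (via gemmi) keeps the first model only, includes hetero
atoms, excludes waters, and resolves alternate conformations by highest
occupancy with ties going to the first listed.  Unknown elements fall
back to carbon with a warning.  The PDB writer enforces the fixed-column
capacities (≤ 99 999 atoms, residue numbers −999…9999, one-character
chain ids) and raises advising mmCIF beyond them; mmCIF output stores
full-precision coordinates, so its roundtrip is exact while PDB's is
exact to the format's three decimals.

## Simulated density

An atom contributes a spherical Gaussian with peak height equal to its
atomic number and width `sigma = sigma_coeff · resolution`.  Parameters:

| parameter | default | meaning |
|---|---|---|
| `resolution` | — | stated map resolution, Å |
| `sigma_coeff` | 0.356 | proportionality between sigma and resolution |
| `use_b_factor` | off | adds `B/(8 pi²)` to `sigma²` per atom |
| `voxel_size` | resolution/3 | Nyquist-safe default sampling |
| `pad` | 3 · resolution | margin around the model bounding box |
| `truncation_sigmas` | 4 | per-atom evaluation cutoff |

The sigma–resolution proportionality constant is a modelling convention,
not a law; 0.356 makes the Gaussian's Fourier amplitude fall to half its
peak at the stated resolution's spatial frequency.  It is configurable
and all scores that compare a model to a map go through the same
simulation, so ranking-type conclusions are insensitive to it.  The
truncation radius is 4 sigma because a radial cutoff at 3 sigma would
discard 2.9% of a 3D Gaussian's mass (the familiar "0.2%" figure is the
one-dimensional tail); 4 sigma keeps the loss near 0.1%, within the 1%
accuracy the mass test asserts.  Hydrogens are excluded by default.

## Global scores

CCC is plain Pearson correlation over voxels (optionally masked).  MI
uses a joint histogram with 20 equal-width bins per axis spanning each
map's own [min, max], reported in bits; MI is invariant under affine
intensity rescaling because the bin edges rescale with the data.  LSF is
the raw sum of squared differences.  NV takes the surface voxels of the
first map's envelope at `threshold_a` (restricted to intensities ≤
`threshold_b` when given), computes outward normals `-grad/|grad|` from
3D Sobel gradients in both maps at the same voxels, and reports the mean
angle in radians; zero-gradient pairs are skipped.  CD is the mean
nearest-neighbour distance between envelope surfaces (one-sided by
default, symmetric on request).  ENV scores
`(N_overlap − 2 · N_probe_only)/N_target`.  Contour thresholds default to
mean + 1 SD of the relevant map — a parameter-free convention,
overridable wherever thresholds appear.  Binarization is strictly
"greater than", and a surface voxel is a true voxel with a six-connected
neighbour outside the mask (grid-boundary voxels count).

Scores with no defined value (zero variance, empty envelopes, vanishing
gradients everywhere) raise a dedicated error rather than returning a
sentinel; inside search loops such poses are ranked at −infinity instead,
so an optimizer can visit them without mistaking "no overlap" for "a
mediocre fit".

## Local scores

SCCC simulates the whole model on the experimental grid, masks voxels
where the *segment's* simulated density exceeds 10% of its own maximum,
and evaluates CCC there.  SMOC computes Mander's overlap coefficient
over per-residue masks built from heavy-atom footprints (voxel centres
within `radius` of an atom; default 3.0 Å).  SMOC_f unions the footprints
of a `window`-residue stretch centred on each residue (default 11,
truncated at chain ends); SMOC_d uses each residue's own footprint.  The
optional resolution-adjusted rules are explicit: window = nearest odd
integer to 1.5 · resolution, radius = max(3.0, 0.5 · resolution) Å.
Mander's coefficient presumes nonnegative signal, so negative
experimental intensities are clamped to zero inside masks; residues
without heavy atoms, or whose mask contains no signal, carry undefined
entries (written as `NA` in profiles).

## Rigid-body optimization

**Metropolis Monte Carlo** proposes a rotation about a uniformly random
axis with angle ~ N(0, `rot_step` = 2°) composed with a translation
~ N(0, `trans_step` = 1 Å per axis), pivoting at the probe's current
density centroid so orientation proposals do not drag the position.
Improvements are always accepted, deteriorations with probability
`exp(delta/temperature)`; the default temperature 0.01 (in CCC units)
tolerates ~1%-of-CCC setbacks, and temperature 0 is greedy ascent.  The
returned transform is the best ever visited; traces are bitwise
reproducible from the seed.

**Expectation–maximization** weights every reference voxel by the product
of reference density and moved-probe density (both clamped nonnegative).
The M-step re-estimates the pose from the weighted match between the
reference and the probe's own density centroid frame: translation moves
the probe centroid to the weighted reference centroid, rotation is the
proper orthogonal (Kabsch) factor of the weighted cross-covariance.
An update is kept only while the CCC objective improves, so the iteration
terminates at the first non-improving step and the reported objective is
nondecreasing by construction.  The translation update is the classic
fixed-point "most likely centre" scheme and converges geometrically on
blob-like densities; the rotation estimate is weaker and a
`translation_only` mode is provided.

**Quasi-Monte Carlo global search** draws poses from a scrambled Halton
sequence in 6D: three coordinates map into the translation box, three
parameterize rotations through the uniform-quaternion construction.  By
default orientations cover all of SO(3); when the misalignment is known
to be bounded, `max_rot_deg` restricts sampling to the rotation ball of
that angle (Haar density ∝ sin²(θ/2), inverted numerically), which is the
orientation analogue of choosing `trans_bounds`.  This matters in
practice: uniform SO(3) sampling at hundreds of samples has an expected
nearest-orientation error of tens of degrees, outside the capture range
of a small-step local search.

The default pipeline runs the global scan, then the Monte Carlo search
seeded from the best sample; its trace begins at that sample, so the
final best score never falls below the global stage's.  Model fitting
simulates the model on its own padded grid and fits that map.

## Difference maps

The probe map's Fourier transform is multiplied per spatial-frequency
shell by (reference shell mean amplitude)/(probe shell mean amplitude);
phases untouched; 30 shells by default, uniform from DC to the Nyquist
frequency of the finest axis (corner frequencies join the last shell).
Two guards keep the operation well-behaved on real transforms:
attenuation (factor ≤ 1) is always applied, but amplification is applied
only where the probe shell carries real signal (mean amplitude above
1e-4 of its strongest shell) — dividing by a near-zero shell mean would
amplify numerical junk into large real-space artefacts.  Both difference
directions are always produced on the first map's grid.  The dust filter
removes positive six-connected components above the positive RMS that
are smaller than `dust_min_voxels`.  For deciding *where* a difference
feature is, the package provides the significance convention standard
for difference densities: voxels above 3× the positive RMS
(`significant_positive`), the same idea as contouring an Fo−Fc map at
3 sigma.  Low-pass filtering to a common resolution is deliberately not
applied implicitly.

## Genetic-algorithm assembly fitting

A genome is one rigid placement per component.  Fitness = objective score
of the jointly simulated assembly against the target map (MI by default —
more robust at low resolution; CCC selectable) minus
`clash_weight · clash_fraction`, where the clash fraction counts Cα atoms
within 3.0 Å of a Cα of another component.  The population (default 20)
is seeded from a per-component quasi-Monte Carlo placement scan over the
map box; each generation applies size-2 tournament selection, uniform
per-component crossover (rate 0.7), pose mutation (rate 0.8; half fine
2°/0.5 Å steps, half coarse 10°/3 Å steps), and elitism (2 genomes).
Elites additionally receive `refine_steps` = 48 greedy improvement trials
per generation — mutation-style proposals kept only when fitness rises —
which is what turns the evolutionary scaffold into a reliable pose
refiner at small population sizes; the elite best fitness is exactly
nondecreasing.  Everything is deterministic given the seed.  A diagnostic
`rmsd_trace` recomputes the per-generation Cα RMSD of the best genome
against a known ground truth; it is never consulted during evolution.

## Synthetic test conditions

All tests and the acceptance script run on generated substrates: sums of
1–5 separated Gaussian blobs on small grids (24³–32³, 1 Å voxels), ideal
poly-alanine α-helices (rise 1.5 Å, twist 100°/residue, five heavy atoms
per residue), two-chain variants, transform pairs with known ground
truth, and apo/holo pairs with a compact added "ligand" blob (1/e
half-width convention, a few percent of the map's mass — the realistic
ligand regime).  Transform-pair second maps are constructed analytically
by moving the blob centres (exact for isotropic Gaussians), so fit
recovery is limited by the optimizer, not by resampling loss.

These fixtures are deliberately idealized: no noise, no missing density,
no local resolution variation, no solvent, no masking artefacts.
Passing tests therefore establish correctness of the mathematics and the
search machinery (identities, oracle agreement, monotonicity, recovery
of known transforms), not performance on experimental reconstructions —
scores on real maps are lower and noisier, and fitting capture ranges
shrink with noise.  Recovery tests declare search bounds that cover
their perturbation regime (±9 Å, ≤20°), the normal way these tools are
run when an approximate placement is known.

## Known limitations

- The EM refiner's rotation estimate is heuristic; large orientation
  errors should go through the Monte Carlo or QMC stages.
- MI uses fixed equal-width binning; no bias correction for small voxel
  counts.
- No FSC, no half-map handling, no symmetry expansion, no flexible
  fitting; PDB multi-model files contribute their first model only.
- The GA does not segment the map or exploit symmetry; components are
  treated as independent rigid bodies.
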