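# Methods

This note records the models, conventions and numerical choices behind
`baseflip`, and what the synthetic test structures do and do not represent.

## Idealized B-DNA construction

The duplex builder is a fiber-style model. Each base pair carries a
right-handed orthonormal frame; successive frames are generated by the
mid-frame (CEHS-style) composition of six rigid-body step parameters
(tilt, roll, twist; shift, slide, rise), defaulting to uniform
twist = 36°, rise = 3.38 Å and zeros elsewhere. Because the builder uses
the exact closed-form inverse of the analyzer's mid-frame decomposition,
builder → analyzer round trips recover step parameters to machine
precision; the 0.5°/0.05 Å tolerances quoted in the tests absorb only the
base-frame fitting step.

Bases are placed from the standard nucleic-acid reference frame (the
Olson/Tsukuba convention shared by 3DNA- and Curves-class tools): planar
heavy-atom templates with the frame origin at the pair centre, +x into the
major groove, +y toward the reference strand. The strand II base frame is
the pair frame rotated 180° about x (a proper rotation, so chirality is
preserved). The sugar–phosphate backbone is grown from internal coordinates
by natural-extension (NeRF) construction: C2'-endo pucker (pseudorotation
phase 162°, amplitude 36°), glycosidic χ = −110°, γ = 35°, β = 160°,
δ = 139°. These values were fixed once against textbook B-form benchmarks:
the resulting helix has C1'–C1' cross-pair separation 10.80 Å, phosphorus
9.22 Å from the axis, inter-residue O3'(i)→P(i+1) gap 1.60 Å and
N1(A)–N3(U) pair distance 2.95 Å. Base protons (ring, imino and amino) are
placed in-plane with N–H = 1.01 Å and C–H = 1.08 Å; backbone protons are
not modelled, which is sufficient for every measurement in the package.

Limitations: the geometry is idealized and sequence-independent — no
propeller/ inclination, no BI/BII substates, no thermal deformation. A
consequence worth flagging: the mass-weighted heavy-atom COM separation of
the two nucleotides of a Watson–Crick pair is 11.9 Å in this geometry
(9.9 Å without the phosphate groups, 5.8 Å for the bases alone). This
quantity is intra-pair-local — it does not depend on the helical
parameters at all, only on the nucleotide template — so differences from
trajectory-derived values reported elsewhere reflect the atom selection
used in the measurement, which published analyses rarely state. The
`pair_com_distance` operation therefore exposes `selection=`
`"nucleotide" | "nucleoside" | "base"` with whole-nucleotide as the
documented default.

## Flip coordinate and controlled flips

The flip angle is a centre-of-mass pseudo-dihedral: four atom groups
reduced to COMs, signed dihedral P1-P2-P3-P4 (IUPAC convention) with the
P2–P3 segment as the rotation axis and the target base as P4. Group
definitions:

| scheme | P1 | P2 | P3 | P4 |
|---|---|---|---|---|
| CPD  | base of 3'-neighbour + its partner | sugar of 3'-neighbour | sugar of target | target base |
| CPDa | four bases of the flanking pairs | 3'-flank sugar | 5'-flank sugar | target base |
| CPDb | as CPDa | 3'-flank phosphate | 5'-flank phosphate | target base |

Conventions fixed here (the literature leaves them open): the CPD
"next" nucleotide is the 3'-side neighbour (switchable); group COMs are
mass-weighted over all atoms present; angles live in (−180°, 180°] with
ties at ±180° mapped to +180°; the overall sign is calibrated so that
displacing the base toward the major groove gives positive angles in every
scheme (verified against the pair-frame +x direction, which points into
the major groove). On the intact ideal duplex the equilibrium values are
small (CPD ≈ −10°, CPDb ≈ +3°); different schemes are genuinely different
coordinates and agree only near the fully-flipped state.

`apply_base_flip` rotates the base rigidly about the scheme's anchor axis
until the measured pseudo-dihedral equals the request; because the P4 COM
orbits the axis, the mapping is exact and the sweep tests hold to well
under 1°. Only base atoms move — real flips sampled by dynamics also
distort the backbone, so synthetic flipped structures are tagged
`provenance="synthetic"` and should be read as geometric probes, not
conformational ensembles.

Watson–Crick partners are identified geometrically: a candidate on another
chain whose flipped base frame shares the target's origin (within 3 Å) and
z-axis. Stacked neighbours sit one rise (~3.4 Å) away along z and are
rejected; a fully flipped base has no in-register partner, and the metrics
layer then infers the partner from a flanking pair via antiparallel
numbering.

## Docking evaluation

The pose score is d_U1-U2: Cα Kabsch superposition of the pose receptor
onto the reference receptor over residues shared by number, then the
N3–N3 distance between the pose uracil and the reference uracil analog
(analog residue names are configurable; only a resolvable N3 is required).
Classification of the set's minimum distance uses half-open intervals
[0,3) High, [3,6) Medium, [6,9) Low, [9,∞) None — boundary values go to
the worse class, a deterministic reading of strict-inequality thresholds.
The 15 Å cutoff is a retention filter for reporting and plotting only;
classification always uses the unfiltered minimum. The summary layer
reports per-label counts, the flip-angle magnitude range among High
entries and the minimum groove distance among High entries (raw and
rounded to the nearest Å).

The mock receptor used in tests is a rigid Cα-only cloud with a pocket
marker placed at the uracil N3 plus a requested offset. It gives the
evaluation a receptor to superpose and a pocket with known location;
it has no chemistry, flexibility or score, and passing tests say nothing
about docking energetics.

Pose sets are rigid perturbations of the DNA partner in the receptor
frame: uniform random rotation axis with angle |N(0, σ_rot²)| about the
DNA COM and isotropic N(0, σ_disp²/3) translations, pose 0 always the
identity, fully seed-reproducible. These emulate the *output* of a
rigid-body docking sampler, not its scoring.

## Metadynamics toy

The flipping coordinate is modelled as one periodic degree of freedom
s ∈ [−180°, 180°) evolving by overdamped Langevin dynamics,
ds = μF dt + sqrt(2 μ k_BT dt) ξ, with mobility μ = 1/friction
(default 1 deg²·mol/kcal/fs), T = 310 K (k_BT = 0.616 kcal/mol) and a 1 fs
step. Every 50 steps a repulsive Gaussian hill is dropped at the walker's
position; the PMF estimate is the negative accumulated bias on 5° windows,
min-shifted to zero. Hill weight is 0.001 kcal/mol and hill width is two
bin-widths; whether that width is the Gaussian σ (default) or the FWHM is
a config switch, since the phrasing is ambiguous in common usage. Plain
(not well-tempered) deposition is used because the hill weight is fixed.

Surface and bias live on a 720-point interpolation grid and the integrator
is numba-compiled, so the default 8×10⁶-step run (1.6×10⁵ hills) takes a
few seconds. That length was chosen so the accumulated bias floods
barriers of ~10 kcal/mol with margin; with it, a double well with an
8.2 kcal/mol barrier is recovered to within a few percent per seed, and an
asymmetric two-branch surface (shallower major-groove branch) yields the
lower barrier on the correct side. A time-averaged estimator
(`pmf_estimate_averaged`, averaging −V over the last quarter of the
deposition) is provided for noise reduction; with the default run length
the plain final-bias estimate is already adequate. The toy demonstrates
the estimator machinery on a known landscape — it says nothing about
all-atom energetics, solvent or the true flipping kinetics.

## Trajectory descriptors

RMSD series superpose each frame onto a reference frame over the selection
(Kabsch) before measuring; Rg is mass-weighted by default with a
geometric option; the Rg histogram is normalized to unit sum. RMSF is
measured about the time-mean structure after two passes of iterative
fitting (fit to running mean, re-average), a common default since the
reference for fluctuations is otherwise arbitrary; per-residue values are
RMS over the residue's selected atoms.

## Degenerate inputs and tie-breaks

Planar atom sets are legitimate Kabsch inputs (the properness correction
resolves the reflection); only near-collinear sets warn. Terminal
residues without a flank or phosphate raise scheme errors rather than
silently substituting groups. Batch metrics record per-file failures as
table rows instead of aborting. Multi-model files with inconsistent atom
counts raise a trajectory error unless explicitly downgraded, in which
case the first model is kept with a warning.

## Known limitations

* The builder's idealized templates make round-trip tests exact but do not
  emulate sequence-dependent or thermally equilibrated geometry; absolute
  values of template-local observables (e.g. residue COM separations,
  equilibrium pseudo-dihedrals) carry the idealization.
* The recognition-complex checks require a user-supplied crystal structure
  (`data/1EMH.pdb`); it is not redistributed with the package.
* mmCIF input, bond topology, force fields, solvent and docking pose
  generation/scoring are out of scope.
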