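# baseflip

Quantitative machinery for deciding when a flipped-out uracil in
double-stranded DNA is *presentable* to a repair glycosylase.

Uracil in DNA is excised by uracil-DNA glycosylase (UDG), the first enzyme
of the base-excision repair pathway. Excision requires the uracil to leave
the base stack — to flip out through the major or minor groove — before it
can enter the enzyme's catalytic pocket, as seen in the crystallographic
recognition complex (PDB 1EMH). This package implements, as a tested
library plus CLI, the geometric and statistical tools used to analyse that
process:

* **Synthetic structures** — an idealized B-form duplex builder (uniform
  36° twist / 3.38 Å rise propagated through rigid-body step parameters,
  standard-reference-frame base templates, C2'-endo backbone), controlled
  base flips to a prescribed flip angle, mock recognition complexes and
  randomized rigid-body docking pose sets, so the whole pipeline runs
  without downloads.
* **Flip geometry** — centre-of-mass pseudo-dihedral flip coordinates
  (CPD/CPDa/CPDb group schemes; signed, positive toward the major groove),
  the uracil-to-opposite-strand groove distance d<sub>U-groove</sub>
  (N1 to nearest cross-strand phosphorus), Watson–Crick H-bond distances
  N1(A)···H3(U) and O4(U)···H6(A), residue COM separations, base-pair
  (buckle/propeller/opening) and step (tilt/roll/twist) parameters from
  fitted standard base frames, and a global duplex bend angle.
* **Docking evaluation** — the d<sub>U1-U2</sub> protocol: superpose the
  receptor of each docked pose onto the reference receptor (Cα Kabsch),
  measure the N3–N3 distance between the pose's uracil and the reference
  uracil analog, retain poses under 15 Å for reporting, and classify the
  best pose as High (< 3 Å), Medium (< 6 Å), Low (< 9 Å) or None (≥ 9 Å).
* **Metadynamics toy** — overdamped Langevin dynamics on a periodic 1D
  flipping coordinate with Gaussian hill deposition (5° windows over
  −180°…180°, hill weight 0.001 kcal/mol, width 2 bins) and PMF
  reconstruction F(s) ≈ −V<sub>bias</sub>(s).
* **Trajectory descriptors** — fitted RMSD series, radius of gyration with
  probability distribution, per-residue RMSF, for multi-model PDB input.

## Worked example

```python
from baseflip import *

st = build_duplex(DuplexSpec("CAGGATGTATATATCTG", (12,), with_hydrogens=True))
print(round(pseudo_dihedral(st, ("A", 12), CPD), 2))        # -10.47
print(round(wc_hbond_distances(st, ("A", 12), ("B", 23))[0], 2))  # 1.94
print(round(u_groove_distance(st, ("A", 12)), 2))           # 11.93

fl = apply_base_flip(st, ("A", 12), 175, "major")
print(round(pseudo_dihedral(fl, ("A", 12), CPD), 2))        # 175.0
print(round(wc_hbond_distances(fl, ("A", 12), ("B", 23))[0], 2))  # 13.25

cx = build_mock_complex(fl, seed=0)
ps = generate_pose_set(cx, 500, displacement=8, rotation=20, seed=0)
res = evaluate_pose_set(ps, cx)
print(int(res.table.retained.sum()), res.best_pose,
      round(res.best_distance, 2), res.label.value)  # 473 0 0.0 High
```

Reading: the intact duplex sits near the flipped-in state (small CPD
angle), with the Watson–Crick N1···H3 bond at 1.94 Å. Driving the uracil to
+175° (major groove) breaks the pair (N1···H3 grows to 13.2 Å). Docking
poses are then scored by how close each pose's uracil N3 lands to the
reference pocket after receptor superposition: 473 of 500 random poses fall
under the 15 Å retention cutoff, and the identity pose (distance 0) makes
the set "High" quality.

The same pipeline is scriptable from the shell:

```bash
baseflip build --sequence CAGGATGTATATATCTG --uracil 12 --out duplex.pdb
baseflip flip --in duplex.pdb --resid 12 --angle 175 --out flipped.pdb
baseflip metrics flipped.pdb --out metrics.csv
baseflip pipeline --n-poses 500 --seed 0 --out-dir run/
baseflip metatoy --surface doublewell --barrier 8.2 --seed 42 --out-prefix mtd
```

## Layout

```
src/baseflip/
  structure.py   PDB I/O, selection mini-language, COM, T->U mutation
  frames.py      base reference frames, nucleotide templates, step algebra
  synthetic.py   duplex builder, base flips, mock complexes, pose sets
  geometry.py    flip metrics (dihedral schemes, distances, pair/step params)
  superpose.py   Kabsch superposition and rigid-transform algebra
  dockeval.py    d_U1-U2 protocol, success classification, summaries
  metadyn.py     1D periodic metadynamics engine and PMF estimators
  trajectory.py  RMSD / Rg / RMSF descriptors
  cli.py         command-line pipeline (`baseflip ...`)
```
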