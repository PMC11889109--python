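"""Synthetic structure generation: idealized B-DNA duplexes, controlled base
flips, mock recognition complexes and randomized rigid-body pose sets.

Everything produced here is flagged ``provenance="synthetic"``.  The duplex
builder propagates base-pair frames through rigid-body step parameters
(uniform 36° twist / 3.38 Å rise by default) and decorates each frame with
idealized nucleotide templates, so the step-parameter analyzer recovers the
generating parameters exactly.  Base flips are pure rigid rotations of the
target base about the backbone anchor axis of the chosen pseudo-dihedral
scheme; real flips sampled from dynamics additionally distort the backbone,
which this generator deliberately does not model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemistry as chem
from .errors import BaseflipError, GeometryError
from .frames import FLIP, nucleotide_template, step_compose
from .structure import Atom, AtomSet, Structure, select_atoms
from .superpose import RigidTransform

__all__ = [
    "StepParameters",
    "DuplexSpec",
    "PoseSet",
    "build_duplex",
    "apply_base_flip",
    "build_mock_complex",
    "generate_pose_set",
]

_BACKBONE_ORDER = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
                   "C3'", "O3'", "C2'", "C1'")


@dataclass(frozen=True)
class StepParameters:
    """Rigid-body parameters of one base-pair step."""

    twist: float = 36.0   # degrees
    roll: float = 0.0     # degrees
    tilt: float = 0.0     # degrees
    shift: float = 0.0    # Å
    slide: float = 0.0    # Å
    rise: float = 3.38    # Å

    def __post_init__(self):
        if not np.isfinite([self.twist, self.roll, self.tilt,
                            self.shift, self.slide, self.rise]).all():
            raise ValueError("step parameters must be finite")
        if self.rise <= 0:
            raise ValueError("rise must be positive")


@dataclass
class DuplexSpec:
    """Recipe for an idealized duplex.

    ``sequence`` is strand I written 5'->3'; ``uracil_positions`` (1-based)
    are turned into uracil, paired with adenine.  Strand II is numbered
    ``N+1 .. 2N`` so that residue j pairs residue ``2N+1-j`` of strand I.
    """

    sequence: str
    uracil_positions: tuple[int, ...] = ()
    with_hydrogens: bool = False
    steps: StepParameters | list[StepParameters] | None = None

    def __post_init__(self):
        self.sequence = self.sequence.strip().upper()
        bad = set(self.sequence) - set("ACGTU")
        if not self.sequence or bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
        for p in self.uracil_positions:
            if not 1 <= p <= len(self.sequence):
                raise ValueError(f"uracil position {p} outside sequence")

    @property
    def n(self) -> int:
        return len(self.sequence)

    def strand_i_codes(self) -> list[str]:
        codes = list(self.sequence)
        for p in self.uracil_positions:
            codes[p - 1] = "U"
        return codes

    def step_list(self) -> list[StepParameters]:
        n_steps = self.n - 1
        if self.steps is None:
            return [StepParameters()] * n_steps
        if isinstance(self.steps, StepParameters):
            return [self.steps] * n_steps
        if len(self.steps) != n_steps:
            raise ValueError(f"need {n_steps} steps, got {len(self.steps)}")
        return list(self.steps)


def _place_residue(code: str, triad: np.ndarray, origin: np.ndarray,
                   with_h: bool, drop_phosphate: bool
                   ) -> tuple[list[str], np.ndarray]:
    tmpl = nucleotide_template(code, with_hydrogens=with_h)
    names = [n for n in _BACKBONE_ORDER if n in tmpl] \
        + [n for n in tmpl if n not in _BACKBONE_ORDER]
    if drop_phosphate:
        names = [n for n in names if n not in ("P", "OP1", "OP2")]
    xyz = np.array([triad @ tmpl[n] + origin for n in names])
    return names, xyz


def build_duplex(spec: DuplexSpec) -> Structure:
    """Build an idealized Watson-Crick duplex from a :class:`DuplexSpec`."""
    n = spec.n
    codes_i = spec.strand_i_codes()
    codes_ii = [chem.WC_PARTNER[c] for c in codes_i]

    triads = [np.eye(3)]
    origins = [np.zeros(3)]
    for sp in spec.step_list():
        T2, o2 = step_compose(triads[-1], origins[-1],
                              sp.tilt, sp.roll, sp.twist,
                              sp.shift, sp.slide, sp.rise)
        triads.append(T2)
        origins.append(o2)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 0

    def emit(chain_id: str, resnum: int, code: str, triad, origin,
             drop_p: bool) -> None:
        nonlocal serial
        names, xyz = _place_residue(code, triad, origin,
                                    spec.with_hydrogens, drop_p)
        for nm, pos in zip(names, xyz):
            serial += 1
            el = chem.element_from_name(nm)
            atoms.append(Atom(serial=serial, name=nm, element=el,
                              residue_name=chem.PDB_RESNAME[code],
                              chain_id=chain_id, residue_number=resnum,
                              mass=chem.atom_mass(el)))
            coords.append(pos)

    # strand I: pairs 1..N, residues 1..N
    for k in range(n):
        emit("A", k + 1, codes_i[k], triads[k], origins[k], drop_p=(k == 0))
    # strand II: residues N+1..2N; residue N+j sits at pair N+1-j
    for j in range(1, n + 1):
        k = n - j  # 0-based pair index
        emit("B", n + j, codes_ii[k], triads[k] @ FLIP, origins[k],
             drop_p=(j == 1))

    st = Structure(atoms, np.asarray(coords),
                   title=f"ideal duplex {''.join(codes_i)}",
                   provenance="synthetic")
    return st


# ---------------------------------------------------------------------------
# controlled base flip
# ---------------------------------------------------------------------------

def _rotate_about_axis(points: np.ndarray, origin: np.ndarray,
                       axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    return (points - origin) @ R.T + origin


def _wrap(angle: float) -> float:
    """Wrap to (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def apply_base_flip(structure: Structure, target, angle: float,
                    groove: str = "major", scheme=None) -> Structure:
    """Rotate the target base rigidly about the scheme's backbone anchor axis
    until the pseudo-dihedral equals the requested signed angle.

    ``angle`` is the magnitude (<= 180°); ``groove`` selects the sign
    convention (+ toward the major groove, - toward the minor groove).  A
    signed ``angle`` may also be passed directly, in which case its sign must
    agree with ``groove``.
    """
    from .geometry import CPD, pseudo_dihedral, scheme_groups

    if scheme is None:
        scheme = CPD
    if abs(angle) > 180.0:
        raise ValueError("|angle| must be <= 180 degrees")
    if groove not in ("major", "minor"):
        raise ValueError("groove must be 'major' or 'minor'")
    if angle < 0.0 and groove == "major":
        raise ValueError(f"signed angle {angle} contradicts groove={groove!r}")
    theta_target = abs(angle) if groove == "major" else -abs(angle)
    if angle == 0.0:
        theta_target = pseudo_dihedral(structure, target, scheme)

    out = structure.copy()
    groups = scheme_groups(out, target, scheme)
    p2 = groups[1].com()
    p3 = groups[2].com()
    axis = p2 - p3
    base_idx = groups[3].indices

    theta0 = pseudo_dihedral(out, target, scheme)
    delta = _wrap(theta_target - theta0)
    if abs(delta) < 1e-9:
        return out

    # the dihedral changes exactly +/- the rotation angle; probe the sign
    probe = out.copy()
    probe.coords[:, base_idx, :] = _rotate_about_axis(
        probe.coords[0, base_idx, :], p3, axis, 1.0)
    sign = 1.0 if _wrap(pseudo_dihedral(probe, target, scheme) - theta0) > 0 \
        else -1.0

    for m in range(out.n_models):
        out.coords[m, base_idx, :] = _rotate_about_axis(
            out.coords[m, base_idx, :], p3, axis, sign * delta)
    achieved = pseudo_dihedral(out, target, scheme)
    if abs(_wrap(achieved - theta_target)) > 0.5:
        raise GeometryError(
            f"base flip did not converge: requested {theta_target:.2f} deg",
            achieved=achieved)
    out.provenance = "synthetic"
    return out


# ---------------------------------------------------------------------------
# mock recognition complex
# ---------------------------------------------------------------------------

def build_mock_complex(flipped_dna: Structure, pocket_atoms: int = 60,
                       pocket_offset=(0.0, 0.0, 0.0), seed: int = 0
                       ) -> Structure:
    """Attach a rigid pseudo-receptor (Cα-only cloud + pocket marker) whose
    pocket sits at the uracil N3 plus ``pocket_offset``.

    The receptor stands in for a glycosylase only geometrically: it gives the
    docking evaluation a chain to superpose on and a known pocket location.
    """
    from .geometry import find_uracil

    chain, resid = find_uracil(flipped_dna)
    n3 = flipped_dna.coords[0, flipped_dna.atom_index(chain, resid, "N3")]
    pocket = n3 + np.asarray(pocket_offset, dtype=float)

    rng = np.random.default_rng(seed)
    atoms = list(flipped_dna.atoms)
    coords = [flipped_dna.coords[0]]
    serial = flipped_dna.n_atoms
    extra: list[np.ndarray] = []
    new_atoms: list[Atom] = []
    # Cα shell around the pocket (radius 5..14 Å), away from the DNA axis
    for i in range(pocket_atoms):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        r = rng.uniform(5.0, 14.0)
        serial += 1
        new_atoms.append(Atom(serial=serial, name="CA", element="C",
                              residue_name="GLY", chain_id="R",
                              residue_number=i + 1,
                              mass=chem.atom_mass("C")))
        extra.append(pocket + r * direction)
    serial += 1
    new_atoms.append(Atom(serial=serial, name="PM", element="C",
                          residue_name="STP", chain_id="R",
                          residue_number=pocket_atoms + 1,
                          mass=chem.atom_mass("C")))
    extra.append(pocket)

    all_atoms = atoms + new_atoms
    all_coords = np.vstack([coords[0], np.asarray(extra)])
    return Structure(all_atoms, all_coords,
                     title="mock recognition complex",
                     provenance="synthetic")


# ---------------------------------------------------------------------------
# randomized pose sets
# ---------------------------------------------------------------------------

@dataclass
class PoseSet:
    """Rigid perturbations of the DNA partner of a reference complex.

    Pose 0 is always the identity.  ``transforms`` act on the nucleic chains
    only, in the fixed receptor frame, mimicking rigid-body docking output.
    """

    reference: Structure
    transforms: list[RigidTransform]
    seed: int
    displacement_scale: float
    rotation_scale: float

    def __len__(self) -> int:
        return len(self.transforms)

    def dna_indices(self) -> np.ndarray:
        return select_atoms(self.reference, "nucleic").indices

    def pose_structure(self, i: int) -> Structure:
        t = self.transforms[i]
        out = self.reference.copy()
        idx = self.dna_indices()
        out.coords[:, idx, :] = out.coords[:, idx, :] @ t.rotation.T \
            + t.translation
        return out

    def to_csv(self, path) -> None:
        rows = [np.concatenate([[i], t.as_row(), [self.seed]])
                for i, t in enumerate(self.transforms)]
        cols = (["pose"] + [f"r{i}{j}" for i in range(3) for j in range(3)]
                + ["tx", "ty", "tz", "seed"])
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, reference: Structure) -> "PoseSet":
        df = pd.read_csv(path)
        transforms = [RigidTransform.from_row(row) for row in
                      df[[f"r{i}{j}" for i in range(3) for j in range(3)]
                         + ["tx", "ty", "tz"]].to_numpy()]
        seed = int(df["seed"].iloc[0]) if "seed" in df else -1
        return cls(reference, transforms, seed, float("nan"), float("nan"))


def generate_pose_set(reference: Structure, n: int, displacement: float = 8.0,
                      rotation: float = 20.0, seed: int = 0) -> PoseSet:
    """Draw ``n`` rigid perturbations of the DNA partner.

    Rotations use a uniform random axis with angle ``|N(0, rotation²)|``
    degrees about the DNA centre of mass; translations are isotropic
    ``N(0, displacement²/3)`` per component so the mean displacement scales
    with ``displacement``.  Pose 0 is the identity.
    """
    if n < 1:
        raise ValueError("need n >= 1 poses")
    rng = np.random.default_rng(seed)
    dna = select_atoms(reference, "nucleic")
    if len(dna) == 0:
        raise BaseflipError("reference complex has no nucleic chains")
    center = dna.com()
    transforms = [RigidTransform.identity()]
    for _ in range(n - 1):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = abs(rng.normal(0.0, max(rotation, 0.0))) if rotation > 0 else 0.0
        a = np.radians(ang)
        K = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
        shift = rng.normal(0.0, displacement / np.sqrt(3.0), size=3) \
            if displacement > 0 else np.zeros(3)
        # rotate about the DNA COM, then translate
        t = shift + center - R @ center
        transforms.append(RigidTransform(R, t))
    return PoseSet(reference, transforms, seed, displacement, rotation)
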