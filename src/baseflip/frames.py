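"""Base reference frames, nucleotide templates and rigid-body helical
parameters.

Two things live here.

* **Templates** — idealized nucleotide geometry expressed in the standard
  base reference frame: planar base heavy atoms (tables in
  :mod:`baseflip.chemistry`), in-plane base hydrogens, and a C2'-endo
  deoxyribose + 5'-phosphate backbone grown from internal coordinates by the
  natural-extension (NeRF) construction.  The backbone torsions are canonical
  fiber B-DNA values; with them a 36°/3.38 Å helix closes properly
  (O3'(i)→P(i+1) = 1.6 Å, P at 9.2 Å from the axis).

* **Frame algebra** — least-squares fitting of an observed base onto its
  template (giving the base triad + origin), and the mid-frame decomposition
  of the rotation between two triads into the six rigid-body parameters
  (tilt/roll/twist + shift/slide/rise for steps; buckle/propeller/opening +
  shear/stretch/stagger for intra-pair geometry).  ``step_compose`` is the
  exact closed-form inverse of ``step_params``, which the duplex builder
  uses so that builder→analyzer round trips are exact.
"""

from __future__ import annotations

import numpy as np

from . import chemistry as chem
from .superpose import kabsch_fit

__all__ = [
    "nucleotide_template",
    "base_template",
    "fit_base_frame",
    "step_params",
    "step_compose",
    "FLIP",
]

#: 180° rotation about x: relates the strand-II base frame to the pair frame
FLIP = np.diag([1.0, -1.0, -1.0])

# -- internal coordinates of the backbone (B-form, C2'-endo) ----------------
# torsions in degrees; bond lengths in Å.  chi is the glycosidic torsion
# (O4'-C1'-N reference), pucker is the pseudorotation phase/amplitude.
_CHI = -110.0
_PUCKER_P = 162.0
_PUCKER_AMP = 36.0
_GAMMA = 35.0     # O5'-C5'-C4'-C3'
_BETA = 160.0     # P-O5'-C5'-C4'
_DELTA = 139.0    # C5'-C4'-C3'-O3'
_ALPHA = -42.0    # O3'(prev)-P-O5'-C5' (used to orient the free P oxygens)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d bonded to c given the b-c-d angle and a-b-c-d torsion."""
    angle = np.radians(angle)
    torsion = np.radians(torsion)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * np.array([-np.cos(angle),
                         np.sin(angle) * np.cos(torsion),
                         np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _base_heavy(code: str) -> dict[str, np.ndarray]:
    return {k: np.array([x, y, 0.0])
            for k, (x, y) in chem.STANDARD_BASE_XY[code].items()}


def _ring_neighbors(code: str) -> dict[str, tuple[str, str]]:
    """Ring adjacency used to place in-plane substituent hydrogens."""
    if code in chem.PURINES:
        ring = ["N9", "C8", "N7", "C5", "C4", "N9"]  # 5-ring
        ring6 = ["C4", "C5", "C6", "N1", "C2", "N3", "C4"]
        seqs = [ring, ring6]
    else:
        seqs = [["N1", "C2", "N3", "C4", "C5", "C6", "N1"]]
    nb: dict[str, list[str]] = {}
    for seq in seqs:
        for i in range(len(seq) - 1):
            nb.setdefault(seq[i], []).append(seq[i + 1])
            nb.setdefault(seq[i + 1], []).append(seq[i])
    return {k: tuple(dict.fromkeys(v))[:2] for k, v in nb.items()}


# (hydrogen name, parent atom) per base; amino H handled separately
_RING_H = {
    "A": [("H2", "C2"), ("H8", "C8")],
    "G": [("H8", "C8"), ("H1", "N1")],
    "C": [("H5", "C5"), ("H6", "C6")],
    "T": [("H3", "N3"), ("H6", "C6")],
    "U": [("H3", "N3"), ("H5", "C5"), ("H6", "C6")],
}
_AMINO = {"A": ("N6", "C6", ("H61", "H62")),
          "G": ("N2", "C2", ("H21", "H22")),
          "C": ("N4", "C4", ("H41", "H42"))}

_NH_BOND = 1.01
_CH_BOND = 1.08


def base_template(code: str, with_hydrogens: bool = False) -> dict[str, np.ndarray]:
    """Base heavy atoms (standard frame), optionally with in-plane hydrogens."""
    at = _base_heavy(code)
    if not with_hydrogens:
        return at
    nb = _ring_neighbors(code)
    for hname, parent in _RING_H[code]:
        a, b = nb[parent]
        p = at[parent]
        v = (p - at[a]) / np.linalg.norm(p - at[a]) \
            + (p - at[b]) / np.linalg.norm(p - at[b])
        v = v / np.linalg.norm(v)
        bond = _NH_BOND if parent.startswith("N") else _CH_BOND
        at[hname] = p + bond * v
    if code in _AMINO:
        n, c, (h1, h2) = _AMINO[code]
        d0 = (at[n] - at[c]) / np.linalg.norm(at[n] - at[c])
        z = np.array([0.0, 0.0, 1.0])
        perp = np.cross(z, d0)
        for hname, s in ((h1, 1.0), (h2, -1.0)):
            direction = d0 * np.cos(np.radians(60.0)) \
                + s * perp * np.sin(np.radians(60.0))
            at[hname] = at[n] + _NH_BOND * direction
    if code == "T":
        # tetrahedral methyl on C7 with one proton anti to C4 in the plane
        c7, c5 = at["C7"], at["C5"]
        axis = (c7 - c5) / np.linalg.norm(c7 - c5)
        ref = at["C4"]
        for i, hname in enumerate(("H71", "H72", "H73")):
            at[hname] = _nerf(ref, c5, c7, 1.09, 109.5, 180.0 - 120.0 * i)
    return at


def nucleotide_template(code: str, with_hydrogens: bool = False
                        ) -> dict[str, np.ndarray]:
    """Full nucleotide (base + sugar + 5'-phosphate) in the standard frame.

    Backbone protons are not modelled; base protons are included when
    requested, which is what the Watson-Crick H-bond measurements need.
    """
    at = base_template(code, with_hydrogens)
    purine = code in chem.PURINES
    ng = at["N9"] if purine else at["N1"]
    ref = at["C4"] if purine else at["C2"]
    c1 = chem.C1_PRIME_STD.copy()
    at["C1'"] = c1
    nu = [_PUCKER_AMP * np.cos(np.radians(_PUCKER_P + 144.0 * (i - 2)))
          for i in range(5)]
    at["O4'"] = _nerf(ref, ng, c1, 1.420, 108.2, _CHI)
    at["C2'"] = _nerf(ref, ng, c1, 1.526, 113.5, _CHI - 118.0)
    at["C3'"] = _nerf(at["O4'"], c1, at["C2'"], 1.525, 101.5, nu[1])
    at["C4'"] = _nerf(c1, at["C2'"], at["C3'"], 1.524, 102.5, nu[2])
    at["C5'"] = _nerf(at["C2'"], at["C3'"], at["C4'"], 1.510, 114.7,
                      nu[3] - 119.0)
    at["O3'"] = _nerf(at["C5'"], at["C4'"], at["C3'"], 1.423, 110.3, _DELTA)
    at["O5'"] = _nerf(at["C3'"], at["C4'"], at["C5'"], 1.440, 110.2, _GAMMA)
    at["P"] = _nerf(at["C4'"], at["C5'"], at["O5'"], 1.593, 119.7, _BETA)
    at["OP1"] = _nerf(at["C5'"], at["O5'"], at["P"], 1.485, 108.0,
                      _ALPHA - 120.0)
    at["OP2"] = _nerf(at["C5'"], at["O5'"], at["P"], 1.485, 108.0,
                      _ALPHA + 120.0)
    return at


# ---------------------------------------------------------------------------
# base-frame fitting
# ---------------------------------------------------------------------------

def fit_base_frame(code: str, names: list[str], coords: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit the standard base onto observed base atoms.

    Returns ``(R, origin, rmsd)`` where columns of R are the base x/y/z axes
    in the lab frame and ``origin`` is the image of the standard-frame
    origin, i.e. ``lab = R @ std + origin``.
    """
    tmpl = _base_heavy(code)
    fit_names = [n for n in chem.FRAME_FIT_ATOMS[code] if n in names]
    if len(fit_names) < 3:
        raise ValueError(f"not enough ring atoms to fit a {code} base frame")
    obs = np.array([coords[names.index(n)] for n in fit_names])
    std = np.array([tmpl[n] for n in fit_names])
    tr, rmsd = kabsch_fit(obs, std)
    return tr.rotation, tr.translation, rmsd


# ---------------------------------------------------------------------------
# mid-frame rigid-body parameters
# ---------------------------------------------------------------------------

def _rotmat(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def _signed_angle(v1: np.ndarray, v2: np.ndarray, about: np.ndarray) -> float:
    x = float(np.dot(v1, v2))
    y = float(np.dot(np.cross(v1, v2), about))
    return float(np.degrees(np.arctan2(y, x)))


def step_params(T1: np.ndarray, o1: np.ndarray,
                T2: np.ndarray, o2: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Six rigid-body parameters taking frame 1 to frame 2 via the mid-frame.

    Returns ``(angles, displacement, mid_triad)`` with
    ``angles = (tilt, roll, twist)`` in degrees and
    ``displacement = (shift, slide, rise)`` in Å, both expressed in the
    mid-frame, following the standard mid-frame (CEHS-style) decomposition.
    """
    z1, z2 = T1[:, 2], T2[:, 2]
    cosg = float(np.clip(np.dot(z1, z2), -1.0, 1.0))
    gamma = float(np.degrees(np.arccos(cosg)))
    hinge = np.cross(z1, z2)
    if np.linalg.norm(hinge) < 1e-12:
        hinge = T1[:, 1]  # z axes parallel: hinge undefined, gamma ~ 0
    T1p = _rotmat(hinge, gamma / 2.0) @ T1
    T2p = _rotmat(hinge, -gamma / 2.0) @ T2
    zm = T1p[:, 2]
    twist = _signed_angle(T1p[:, 0], T2p[:, 0], zm)
    xm = T1p[:, 0] + T2p[:, 0]
    xm = xm / np.linalg.norm(xm)
    ym = np.cross(zm, xm)
    Tm = np.column_stack([xm, ym, zm])
    # decompose the hinge rotation into roll (about ym) and tilt (about xm)
    h = hinge / np.linalg.norm(hinge)
    roll = gamma * float(np.dot(h, ym))
    tilt = gamma * float(np.dot(h, xm))
    disp = Tm.T @ (o2 - o1)
    return np.array([tilt, roll, twist]), disp, Tm


def step_compose(T1: np.ndarray, o1: np.ndarray,
                 tilt: float, roll: float, twist: float,
                 shift: float, slide: float, rise: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form inverse of :func:`step_params`.

    In mid-frame coordinates the two triads read
    ``T1 = R(h, -Γ/2) Rz(-ω/2)`` and ``T2 = R(h, +Γ/2) Rz(+ω/2)`` with the
    hinge direction ``h = (tilt·x_m + roll·y_m)/Γ``; the mid-frame is
    recovered from T1 and the parameters, then T2 and the origin follow.
    """
    gamma = float(np.hypot(tilt, roll))
    ez = np.array([0.0, 0.0, 1.0])
    if gamma < 1e-12:
        A1 = _rotmat(ez, -twist / 2.0)
        A2 = _rotmat(ez, twist / 2.0)
    else:
        h_mid = np.array([tilt, roll, 0.0]) / gamma
        A1 = _rotmat(h_mid, -gamma / 2.0) @ _rotmat(ez, -twist / 2.0)
        A2 = _rotmat(h_mid, gamma / 2.0) @ _rotmat(ez, twist / 2.0)
    Tm = T1 @ A1.T  # A1 orthogonal
    T2 = Tm @ A2
    o2 = o1 + Tm @ np.array([shift, slide, rise])
    return T2, o2


def pair_params(T_ref: np.ndarray, o_ref: np.ndarray,
                T_cmp_flipped: np.ndarray, o_cmp: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Intra-base-pair parameters between a reference-strand base triad and
    the flipped triad of its partner.

    Returns ``(angles, displacement, pair_triad, pair_origin)`` with
    ``angles = (buckle, propeller, opening)`` in degrees and
    ``displacement = (shear, stretch, stagger)`` in Å.  The decomposition is
    the same mid-frame construction as for steps, applied from the partner's
    flipped frame to the reference frame; the mid-frame is the base-pair
    frame used for step parameters.
    """
    angles, disp, Tm = step_params(T_cmp_flipped, o_cmp, T_ref, o_ref)
    om = 0.5 * (o_ref + o_cmp)
    return angles, disp, Tm, om
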