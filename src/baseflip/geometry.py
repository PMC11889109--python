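"""Per-structure geometric descriptors of the base-flipping process.

The central quantity is the centre-of-mass pseudo-dihedral (CPD) flip angle:
four atom groups P1..P4 are reduced to their COMs and the signed dihedral
P1-P2-P3-P4 is evaluated with the P2-P3 segment as the rotation axis and the
target base as P4.  Three group definitions are supported:

``CPD``
    P1 = base of the 3'-neighbour plus the base opposing that neighbour,
    P2 = sugar of the 3'-neighbour, P3 = sugar of the flipping nucleotide,
    P4 = the flipping base.
``CPDa``
    P1 = the four bases of the two flanking pairs, P2/P3 = the flanking
    sugars (3'/5'), P4 = the flipping base.
``CPDb``
    as CPDa but with the flanking phosphate groups as P2/P3.

The sign convention is: positive dihedral = base displaced toward the major
groove, negative = minor groove, values in (-180, 180].

Also here: the uracil-to-opposite-strand-groove distance (N1 to the nearest
phosphorus of the complementary strand), Watson-Crick hydrogen-bond
distances, residue-COM separation of a pair, base-pair (buckle/propeller/
opening, shear/stretch/stagger) and step (tilt/roll/twist, shift/slide/rise)
parameters from fitted standard base frames, and a whole-duplex bend angle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemistry as chem
from .errors import AtomLookupError, EmptySetError, SchemeError
from .frames import FLIP, fit_base_frame, pair_params, step_params
from .structure import AtomSet, Structure, center_of_mass, read_pdb

__all__ = [
    "FlipScheme", "CPD", "CPDa", "CPDb", "SCHEMES",
    "FlipMetrics", "BasePairGeom", "StepGeom",
    "scheme_groups", "pseudo_dihedral", "u_groove_distance",
    "wc_hbond_distances", "pair_com_distance", "base_pair_parameters",
    "step_parameters", "bend_angle", "find_uracil", "find_pair_partner",
    "flip_metrics", "metrics_table",
]


@dataclass(frozen=True)
class FlipScheme:
    """Named COM pseudo-dihedral group definition."""

    name: str
    #: which flank supplies P2 / P3 ("3prime" or "5prime" or "self")
    moiety: str = "sugar"   # moiety of the P2/P3 anchors

    def __str__(self) -> str:
        return self.name


CPD = FlipScheme("CPD", moiety="sugar")
CPDa = FlipScheme("CPDa", moiety="sugar")
CPDb = FlipScheme("CPDb", moiety="phosphate")
SCHEMES = {"CPD": CPD, "CPDa": CPDa, "CPDb": CPDb}


@dataclass
class FlipMetrics:
    """Per-structure record of the flip descriptors."""

    structure_id: str
    scheme: str
    dihedral: float            # signed degrees, (-180, 180]
    d_u_groove: float          # Å
    hbond_n1_h3: float | None  # Å, needs hydrogens
    hbond_o4_h6: float | None  # Å, needs hydrogens
    com_pair_distance: float | None  # Å

    @property
    def groove_side(self) -> int:
        return 1 if self.dihedral >= 0 else -1


@dataclass(frozen=True)
class BasePairGeom:
    buckle: float
    propeller: float
    opening: float
    shear: float
    stretch: float
    stagger: float


@dataclass(frozen=True)
class StepGeom:
    tilt: float
    roll: float
    twist: float
    shift: float
    slide: float
    rise: float


# ---------------------------------------------------------------------------
# residue helpers
# ---------------------------------------------------------------------------

def _resolve_target(structure: Structure, target) -> tuple[str, int]:
    if isinstance(target, tuple):
        chain, resid = target
        return chain, int(resid)
    idx = structure.residue_indices(None, int(target))
    return structure.atoms[idx[0]].chain_id, int(target)


def _moiety_set(structure: Structure, chain: str, resid: int,
                moiety: str, model: int = 0) -> AtomSet:
    table = {"base": chem.BASE_ATOMS, "sugar": chem.SUGAR_ATOMS,
             "phosphate": chem.PHOSPHATE_ATOMS}[moiety]
    idx = [int(i) for i in structure.residue_indices(chain, resid)
           if structure.atoms[i].name in table]
    return AtomSet(structure, np.asarray(idx, dtype=int), model=model)


def find_pair_partner(structure: Structure, chain: str, resid: int,
                      max_distance: float = 3.0) -> tuple[str, int] | None:
    """Geometric Watson-Crick partner of a nucleotide.

    Paired bases share (nearly) one standard-frame origin and, after
    flipping the partner's frame, one z-axis; stacked neighbours sit a rise
    (~3.4 Å) away along z.  The partner is the other-chain residue whose
    flipped base frame coincides with the target's within ``max_distance``
    Å and with aligned z-axes; None when the base has no in-register
    partner (e.g. it is flipped out).
    """
    try:
        R1, o1 = _base_frame_of(structure, (chain, resid))
    except (EmptySetError, AtomLookupError, ValueError):
        return None
    best, best_d = None, max_distance
    for (ch, num, icode), idx in structure.residues():
        if ch == chain or icode:
            continue
        a0 = structure.atoms[idx[0]]
        if not chem.is_nucleotide(a0.residue_name):
            continue
        try:
            R2, o2 = _base_frame_of(structure, (ch, num))
        except (EmptySetError, AtomLookupError, ValueError):
            continue
        d = float(np.linalg.norm(o2 - o1))
        z_dot = float(np.dot(R1[:, 2], (R2 @ FLIP)[:, 2]))
        if d < best_d and z_dot > 0.5:
            best, best_d = (ch, num), d
    return best


def find_uracil(structure: Structure,
                analog_names: tuple[str, ...] = chem.URACIL_ANALOG_NAMES
                ) -> tuple[str, int]:
    """Locate a uracil (or uracil-analog) residue with a resolvable N3."""
    analogs = {n.upper() for n in analog_names}
    fallback = None
    for (ch, num, icode), idx in structure.residues():
        if icode:
            continue
        resname = structure.atoms[idx[0]].residue_name.upper()
        names = {structure.atoms[i].name for i in idx}
        if "N3" not in names:
            continue
        if chem.canonical_na(resname) == "U":
            return ch, num
        if resname in analogs and fallback is None:
            fallback = (ch, num)
    if fallback:
        return fallback
    raise AtomLookupError("no uracil or uracil-analog residue with an N3 atom")


# ---------------------------------------------------------------------------
# pseudo-dihedral schemes
# ---------------------------------------------------------------------------

def _neighbor(structure: Structure, chain: str, resid: int, offset: int
              ) -> tuple[str, int]:
    nb = resid + offset
    try:
        structure.residue_indices(chain, nb)
    except AtomLookupError as exc:
        raise SchemeError(
            f"target {chain}/{resid} lacks a {'3' if offset > 0 else '5'}'"
            f"-side neighbour") from exc
    return chain, nb


def scheme_groups(structure: Structure, target, scheme: FlipScheme,
                  neighbor_side: str = "3prime", model: int = 0
                  ) -> list[AtomSet]:
    """Resolve the four COM groups P1..P4 for a scheme and target residue."""
    chain, resid = _resolve_target(structure, target)
    p4 = _moiety_set(structure, chain, resid, "base", model)
    if len(p4) == 0:
        raise SchemeError(f"target {chain}/{resid} has no base atoms")

    def base_of(res: tuple[str, int]) -> np.ndarray:
        s = _moiety_set(structure, res[0], res[1], "base", model)
        if len(s) == 0:
            raise SchemeError(f"residue {res} has no base atoms")
        return s.indices

    if scheme.name == "CPD":
        off = 1 if neighbor_side == "3prime" else -1
        nxt = _neighbor(structure, chain, resid, off)
        opp = find_pair_partner(structure, *nxt)
        if opp is None:
            raise SchemeError(f"no opposing residue for neighbour {nxt}")
        p1_idx = np.concatenate([base_of(nxt), base_of(opp)])
        p2 = _moiety_set(structure, nxt[0], nxt[1], "sugar", model)
        p3 = _moiety_set(structure, chain, resid, "sugar", model)
        p1 = AtomSet(structure, p1_idx, model)
    else:
        fl3 = _neighbor(structure, chain, resid, 1)
        fl5 = _neighbor(structure, chain, resid, -1)
        opp3 = find_pair_partner(structure, *fl3)
        opp5 = find_pair_partner(structure, *fl5)
        if opp3 is None or opp5 is None:
            raise SchemeError("flanking base pairs are not both resolvable")
        p1_idx = np.concatenate([base_of(fl3), base_of(opp3),
                                 base_of(fl5), base_of(opp5)])
        p1 = AtomSet(structure, p1_idx, model)
        p2 = _moiety_set(structure, fl3[0], fl3[1], scheme.moiety, model)
        p3 = _moiety_set(structure, fl5[0], fl5[1], scheme.moiety, model)
    if len(p2) == 0 or len(p3) == 0:
        raise SchemeError(
            f"empty {scheme.moiety} anchor group for scheme {scheme.name} "
            f"(terminal residue without phosphate?)")
    return [p1, p2, p3, p4]


def _dihedral_points(p1, p2, p3, p4) -> float:
    """Signed dihedral of four points, IUPAC convention, degrees."""
    b0 = p1 - p2
    b1 = p3 - p2
    b2 = p4 - p3
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1n, v), w))
    ang = float(np.degrees(np.arctan2(-y, x)))
    return 180.0 if ang == -180.0 else ang


#: overall sign fixed so that displacement of the flipping base toward the
#: major groove gives positive angles in every scheme (checked by the
#: builder/analyzer consistency tests)
_SIGN = {"CPD": 1.0, "CPDa": 1.0, "CPDb": 1.0}


def pseudo_dihedral(structure: Structure, target, scheme: FlipScheme,
                    neighbor_side: str = "3prime", model: int = 0) -> float:
    """Signed COM pseudo-dihedral flip angle of the target base, degrees."""
    groups = scheme_groups(structure, target, scheme, neighbor_side, model)
    coms = [g.com() for g in groups]
    raw = _dihedral_points(*coms)
    val = _SIGN[scheme.name] * raw
    return 180.0 if val == -180.0 else val


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def u_groove_distance(structure: Structure, uracil, model: int = 0) -> float:
    """Distance from the flipping base's N1 to the nearest phosphorus of the
    opposite strand (steric accessibility of the groove)."""
    chain, resid = _resolve_target(structure, uracil)
    try:
        n1 = structure.coords[model, structure.atom_index(chain, resid, "N1")]
    except AtomLookupError as exc:
        raise AtomLookupError(f"uracil {chain}/{resid} lacks N1") from exc
    ps = [structure.coords[model, i] for i, a in enumerate(structure.atoms)
          if a.name == "P" and a.chain_id != chain
          and chem.is_nucleotide(a.residue_name)]
    if not ps:
        raise AtomLookupError("no phosphorus atoms on the opposite strand")
    return float(np.min(np.linalg.norm(np.asarray(ps) - n1, axis=1)))


def wc_hbond_distances(structure: Structure, uracil, adenine,
                       model: int = 0) -> tuple[float, float]:
    """Watson-Crick H-bond distances (N1(A)···H3(U), O4(U)···H6(A amino)).

    Requires hydrogens; the adenine amino proton nearer O4 plays H6'.
    """
    uch, ures = _resolve_target(structure, uracil)
    ach, ares = _resolve_target(structure, adenine)
    try:
        h3 = structure.coords[model, structure.atom_index(uch, ures, "H3")]
    except AtomLookupError as exc:
        raise AtomLookupError(
            "H3 missing on the uracil: build with hydrogens") from exc
    n1 = structure.coords[model, structure.atom_index(ach, ares, "N1")]
    o4 = structure.coords[model, structure.atom_index(uch, ures, "O4")]
    hs = []
    for i in structure.residue_indices(ach, ares):
        if structure.atoms[i].name in ("H61", "H62", "1H6", "2H6"):
            hs.append(structure.coords[model, i])
    if not hs:
        raise AtomLookupError(
            "amino hydrogens missing on the adenine: build with hydrogens")
    d_o4 = min(float(np.linalg.norm(o4 - h)) for h in hs)
    return float(np.linalg.norm(n1 - h3)), d_o4


_COM_SELECTIONS = {
    "nucleotide": None,  # all residue atoms
    "nucleoside": chem.BASE_ATOMS | chem.SUGAR_ATOMS,
    "base": chem.BASE_ATOMS,
}


def pair_com_distance(structure: Structure, res_i, res_j,
                      selection: str = "nucleotide", heavy_only: bool = True,
                      weighting: str = "mass", model: int = 0) -> float:
    """Distance between the COMs of two residues.

    ``selection`` picks the atom subset: the whole nucleotide (default), the
    nucleoside (no phosphate) or the base moiety only; ``heavy_only`` drops
    hydrogens.
    """
    allowed = _COM_SELECTIONS[selection]

    def com_of(res) -> np.ndarray:
        ch, num = _resolve_target(structure, res)
        idx = [int(i) for i in structure.residue_indices(ch, num)
               if (allowed is None or structure.atoms[i].name in allowed)
               and not (heavy_only and structure.atoms[i].element.upper() == "H")]
        if not idx:
            raise EmptySetError(f"residue {res} has no atoms in selection")
        return center_of_mass(AtomSet(structure, np.asarray(idx), model),
                              weighting)

    return float(np.linalg.norm(com_of(res_i) - com_of(res_j)))


# ---------------------------------------------------------------------------
# base-pair and step parameters
# ---------------------------------------------------------------------------

def _base_frame_of(structure: Structure, res, model: int = 0):
    ch, num = _resolve_target(structure, res)
    code = chem.canonical_na(structure.residue_name_of(ch, num))
    if code is None:
        raise AtomLookupError(f"residue {ch}/{num} is not a nucleotide")
    idx = structure.residue_indices(ch, num)
    names = [structure.atoms[i].name for i in idx]
    coords = structure.coords[model][idx]
    R, o, rmsd = fit_base_frame(code, names, coords)
    if rmsd > 0.5:
        import warnings
        warnings.warn(f"degenerate base {ch}/{num}: frame fit RMSD "
                      f"{rmsd:.2f} Å", stacklevel=2)
    return R, o


def base_pair_parameters(structure: Structure, pair, model: int = 0
                         ) -> BasePairGeom:
    """Intra-pair parameters of (reference residue, partner residue)."""
    res_i, res_j = pair
    Ti, oi = _base_frame_of(structure, res_i, model)
    Tj, oj = _base_frame_of(structure, res_j, model)
    angles, disp, _, _ = pair_params(Ti, oi, Tj @ FLIP, oj)
    buckle, propeller, opening = angles
    shear, stretch, stagger = disp
    return BasePairGeom(buckle, propeller, opening, shear, stretch, stagger)


def _pair_frame(structure: Structure, pair, model: int = 0):
    res_i, res_j = pair
    Ti, oi = _base_frame_of(structure, res_i, model)
    Tj, oj = _base_frame_of(structure, res_j, model)
    _, _, Tm, om = pair_params(Ti, oi, Tj @ FLIP, oj)
    return Tm, om


def step_parameters(structure: Structure, step, model: int = 0) -> StepGeom:
    """Step parameters between two consecutive base pairs
    ``((i1, j1), (i2, j2))``."""
    pair1, pair2 = step
    T1, o1 = _pair_frame(structure, pair1, model)
    T2, o2 = _pair_frame(structure, pair2, model)
    angles, disp, _ = step_params(T1, o1, T2, o2)
    tilt, roll, twist = angles
    shift, slide, rise = disp
    return StepGeom(tilt, roll, twist, shift, slide, rise)


def _infer_pairs(structure: Structure) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    chains = [c for c in structure.chain_ids()
              if any(chem.is_nucleotide(a.residue_name)
                     for a in structure.atoms if a.chain_id == c)]
    if not chains:
        raise AtomLookupError("no nucleic chains")
    first = chains[0]
    pairs = []
    for (ch, num, icode), idx in structure.residues():
        if ch != first or icode:
            continue
        if not chem.is_nucleotide(structure.atoms[idx[0]].residue_name):
            continue
        partner = find_pair_partner(structure, ch, num)
        if partner is not None:
            pairs.append(((ch, num), partner))
    return pairs


def bend_angle(structure: Structure, pairs=None, span: int = 4,
               model: int = 0) -> float:
    """Global duplex bend: angle between the helix-axis directions fitted to
    the base-pair centres of the first ``span`` steps and the last ``span``
    steps (principal axis of each window)."""
    if pairs is None:
        pairs = _infer_pairs(structure)
    if len(pairs) < 2 * span:
        raise ValueError(f"need at least {2 * span} base pairs, "
                         f"got {len(pairs)}")
    centers = np.array([_pair_frame(structure, p, model)[1] for p in pairs])

    def axis_of(window: np.ndarray) -> np.ndarray:
        c = window - window.mean(axis=0)
        _, _, vt = np.linalg.svd(c)
        d = vt[0]
        if np.dot(d, window[-1] - window[0]) < 0:
            d = -d
        return d

    d1 = axis_of(centers[: span + 1])
    d2 = axis_of(centers[-(span + 1):])
    cosang = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# batch metrics
# ---------------------------------------------------------------------------

def flip_metrics(structure: Structure, target=None, scheme: FlipScheme = CPD,
                 structure_id: str = "", model: int = 0) -> FlipMetrics:
    """All flip descriptors of one structure in a single record.

    H-bond and COM descriptors are filled when resolvable (hydrogens present,
    partner identifiable) and left as None otherwise.
    """
    if target is None:
        target = find_uracil(structure)
    chain, resid = _resolve_target(structure, target)
    dih = pseudo_dihedral(structure, (chain, resid), scheme, model=model)
    dug = u_groove_distance(structure, (chain, resid), model=model)
    partner = find_pair_partner(structure, chain, resid)
    if partner is None:
        # a flipped-out base has left its partner behind; infer the partner
        # from a flanking pair (antiparallel numbering runs the other way)
        for off in (1, -1):
            try:
                nb = find_pair_partner(structure, chain, resid + off)
            except AtomLookupError:
                continue
            if nb is None:
                continue
            cand = (nb[0], nb[1] + off)
            try:
                structure.residue_indices(*cand)
            except AtomLookupError:
                continue
            partner = cand
            break
    hb1 = hb2 = comd = None
    if partner is not None:
        comd = pair_com_distance(structure, (chain, resid), partner,
                                 model=model)
        try:
            hb1, hb2 = wc_hbond_distances(structure, (chain, resid), partner,
                                          model=model)
        except AtomLookupError:
            pass
    return FlipMetrics(structure_id or structure.title or "structure",
                       scheme.name, dih, dug, hb1, hb2, comd)


def metrics_table(paths, scheme: FlipScheme = CPD) -> pd.DataFrame:
    """Batch mode: one metrics row per PDB file (Table-1-style layout).

    Per-file failures are recorded as rows with an ``error`` note instead of
    aborting the batch.
    """
    rows = []
    for p in paths:
        p = Path(p)
        try:
            st = read_pdb(p)
            m = flip_metrics(st, scheme=scheme, structure_id=p.stem)
            rows.append({"structure": p.stem, "scheme": m.scheme,
                         "dihedral_deg": m.dihedral,
                         "d_u_groove_A": m.d_u_groove,
                         "hbond_n1_h3_A": m.hbond_n1_h3,
                         "hbond_o4_h6_A": m.hbond_o4_h6,
                         "com_pair_A": m.com_pair_distance, "error": ""})
        except Exception as exc:  # noqa: BLE001 - batch robustness
            rows.append({"structure": p.stem, "scheme": scheme.name,
                         "dihedral_deg": np.nan, "d_u_groove_A": np.nan,
                         "hbond_n1_h3_A": np.nan, "hbond_o4_h6_A": np.nan,
                         "com_pair_A": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)
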