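"""Docking-pose evaluation against a reference recognition complex.

A docked pose is scored by one number, d_U1-U2: after superposing the pose's
receptor onto the reference receptor (Cα Kabsch over residues common by
number), the distance between the N3 atom of the pose's uracil and the N3
atom of the reference's uracil (or uracil analog).  The best (minimum) pose
distance of a set maps onto a four-level success label:

=========  =================
label      best distance d
=========  =================
High       d < 3 Å
Medium     3 Å <= d < 6 Å
Low        6 Å <= d < 9 Å
None       d >= 9 Å
=========  =================

Boundaries are assigned to the worse class (half-open intervals).  The 15 Å
retention cutoff is a display/reporting filter on the per-pose table; the
classification always uses the unfiltered minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from . import chemistry as chem
from .errors import AlignmentError, AtomLookupError
from .geometry import find_uracil
from .structure import Structure
from .superpose import kabsch_fit

__all__ = [
    "SuccessLabel", "PoseEvaluation", "PoseSetEvaluation",
    "classify_success", "uracil_similarity_distance", "evaluate_pose_set",
    "summarize_success_table", "DEFAULT_THRESHOLDS", "DEFAULT_CUTOFF",
]

DEFAULT_THRESHOLDS = (3.0, 6.0, 9.0)   # Å, High/Medium/Low upper edges
DEFAULT_CUTOFF = 15.0                  # Å, retention filter


class SuccessLabel(str, Enum):
    HIGH = "High"
    MEDIUM = "Medium"
    LOW = "Low"
    NONE = "None"

    @property
    def rank(self) -> int:
        return {"High": 3, "Medium": 2, "Low": 1, "None": 0}[self.value]


def classify_success(best_distance: float,
                     thresholds=DEFAULT_THRESHOLDS) -> SuccessLabel:
    """Map a best-pose distance onto the success label (monotone step map)."""
    d = float(best_distance)
    if d < 0 or not np.isfinite(d):
        raise ValueError(f"distance must be finite and >= 0, got {d}")
    hi, med, low = thresholds
    if not (0 < hi < med < low):
        raise ValueError("thresholds must be strictly increasing")
    if d < hi:
        return SuccessLabel.HIGH
    if d < med:
        return SuccessLabel.MEDIUM
    if d < low:
        return SuccessLabel.LOW
    return SuccessLabel.NONE


@dataclass(frozen=True)
class PoseEvaluation:
    pose: int
    d_u1_u2: float
    retained: bool


@dataclass
class PoseSetEvaluation:
    """Per-pose table plus the set-level verdict."""

    table: pd.DataFrame
    best_pose: int
    best_distance: float
    label: SuccessLabel

    def summary_row(self, structure_id: str = "") -> dict:
        return {"structure": structure_id, "best_pose": self.best_pose,
                "d_u1_u2_A": self.best_distance, "success": self.label.value}


# ---------------------------------------------------------------------------
# receptor handling
# ---------------------------------------------------------------------------

def receptor_chain(structure: Structure, override: str | None = None) -> str:
    """The chain holding the receptor protein: the one with most Cα atoms."""
    if override is not None:
        return override
    counts: dict[str, int] = {}
    for a in structure.atoms:
        if a.name == "CA" and chem.is_amino_acid(a.residue_name):
            counts[a.chain_id] = counts.get(a.chain_id, 0) + 1
    if not counts:
        raise AlignmentError("no chain with amino-acid Cα atoms found")
    return max(counts, key=counts.get)


def _ca_map(structure: Structure, chain: str) -> dict[int, int]:
    out = {}
    for i, a in enumerate(structure.atoms):
        if a.chain_id == chain and a.name == "CA" \
                and chem.is_amino_acid(a.residue_name):
            out[a.residue_number] = i
    return out


def _uracil_n3(structure: Structure, analog_names) -> np.ndarray:
    ch, res = find_uracil(structure, analog_names)
    return structure.coords[0, structure.atom_index(ch, res, "N3")]


def uracil_similarity_distance(pose: Structure, reference: Structure,
                               pose_receptor: str | None = None,
                               ref_receptor: str | None = None,
                               analog_names=chem.URACIL_ANALOG_NAMES) -> float:
    """d_U1-U2 of one pose: receptor-aligned N3(pose uracil) to N3(reference
    uracil/analog) distance, in Å."""
    rc_pose = receptor_chain(pose, pose_receptor)
    rc_ref = receptor_chain(reference, ref_receptor)
    map_pose = _ca_map(pose, rc_pose)
    map_ref = _ca_map(reference, rc_ref)
    common = sorted(set(map_pose) & set(map_ref))
    if len(common) < 3:
        raise AlignmentError(
            f"only {len(common)} shared receptor residues; cannot align")
    ref_xyz = reference.coords[0][[map_ref[r] for r in common]]
    pose_xyz = pose.coords[0][[map_pose[r] for r in common]]
    tr, _ = kabsch_fit(ref_xyz, pose_xyz)
    n3_pose = tr.apply(_uracil_n3(pose, analog_names))
    n3_ref = _uracil_n3(reference, analog_names)
    return float(np.linalg.norm(n3_pose - n3_ref))


def evaluate_pose_set(poses, reference: Structure,
                      cutoff: float = DEFAULT_CUTOFF,
                      thresholds=DEFAULT_THRESHOLDS,
                      analog_names=chem.URACIL_ANALOG_NAMES
                      ) -> PoseSetEvaluation:
    """Score every pose of a set and classify the set by its best pose.

    ``poses`` may be a :class:`~baseflip.synthetic.PoseSet` or an iterable of
    pose structures.  Poses with d below ``cutoff`` are flagged retained;
    classification uses the global minimum regardless of the filter.
    """
    if hasattr(poses, "pose_structure"):
        structures = (poses.pose_structure(i) for i in range(len(poses)))
        n = len(poses)
    else:
        structures = iter(poses)
        n = None
    rows = []
    for i, pose in enumerate(structures):
        d = uracil_similarity_distance(pose, reference,
                                       analog_names=analog_names)
        rows.append(PoseEvaluation(i, d, d < cutoff))
    if not rows:
        raise ValueError("empty pose set")
    if n is not None and len(rows) != n:  # pragma: no cover - defensive
        raise ValueError("pose count mismatch")
    table = pd.DataFrame([r.__dict__ for r in rows])
    best_idx = int(table["d_u1_u2"].idxmin())
    best = float(table.loc[best_idx, "d_u1_u2"])
    return PoseSetEvaluation(table, int(table.loc[best_idx, "pose"]), best,
                             classify_success(best, thresholds))


# ---------------------------------------------------------------------------
# Table-1-style summary
# ---------------------------------------------------------------------------

def summarize_success_table(table: pd.DataFrame) -> dict:
    """Aggregate a per-structure metrics/success table.

    ``table`` needs columns ``structure``, ``dihedral_deg``,
    ``d_u_groove_A`` and ``success``.  Reports per-label counts, the min/max
    flip-angle magnitude among High entries, and the minimum groove distance
    among High entries (raw and rounded to the nearest Å).
    """
    required = {"structure", "dihedral_deg", "d_u_groove_A", "success"}
    missing = required - set(table.columns)
    if missing:
        raise KeyError(f"summary table lacks columns {sorted(missing)}")
    counts = {label.value: int((table["success"] == label.value).sum())
              for label in SuccessLabel}
    high = table[table["success"] == SuccessLabel.HIGH.value]
    out = {"counts": counts, "n": int(len(table))}
    if len(high):
        mags = high["dihedral_deg"].abs()
        dmin = float(high["d_u_groove_A"].min())
        out.update({
            "high_min_abs_dihedral_deg": float(mags.min()),
            "high_max_abs_dihedral_deg": float(mags.max()),
            "high_min_d_u_groove_A": round(dmin, 1),
            "high_min_d_u_groove_rounded_A": int(round(dmin)),
        })
    else:
        out.update({"high_min_abs_dihedral_deg": None,
                    "high_max_abs_dihedral_deg": None,
                    "high_min_d_u_groove_A": None,
                    "high_min_d_u_groove_rounded_A": None})
    return out
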