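"""Trajectory descriptors for multi-model structures: RMSD time series,
radius of gyration (with probability distribution) and per-residue RMSF."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptySetError, TrajectoryError
from .structure import AtomSet, Structure, select_atoms
from .superpose import kabsch_fit

__all__ = ["TimeSeries", "rmsd_series", "rg_series", "histogram",
           "rmsf_profile"]


@dataclass
class TimeSeries:
    frames: np.ndarray
    values: np.ndarray
    selection: str
    units: str = "A"

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.frames) != len(self.values):
            raise ValueError("frame/value length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": self.frames,
                             f"value_{self.units}": self.values})


def _selected(trajectory: Structure, selection: str) -> AtomSet:
    sel = select_atoms(trajectory, selection)
    if len(sel) == 0:
        raise EmptySetError(f"selection {selection!r} matches no atoms")
    return sel


def rmsd_series(trajectory: Structure, selection: str = "heavy",
                reference: int = 0) -> TimeSeries:
    """Fitted RMSD of every frame against a reference frame.

    Each frame is Kabsch-superposed onto the reference over the selection
    before the deviation is measured, so rigid-body motion does not count.
    """
    if trajectory.n_models < 2:
        raise TrajectoryError("need at least 2 frames for an RMSD series")
    sel = _selected(trajectory, selection)
    ref = trajectory.coords[reference][sel.indices]
    vals = []
    for m in range(trajectory.n_models):
        mob = trajectory.coords[m][sel.indices]
        _, rmsd = kabsch_fit(ref, mob)
        vals.append(rmsd)
    return TimeSeries(np.arange(trajectory.n_models), np.array(vals),
                      selection)


def rg_series(trajectory: Structure, selection: str = "heavy",
              mass_weighted: bool = True) -> TimeSeries:
    """Radius of gyration per frame (mass-weighted by default)."""
    sel = _selected(trajectory, selection)
    w = sel.masses if mass_weighted else np.ones(len(sel))
    w = w / w.sum()
    vals = []
    for m in range(trajectory.n_models):
        xyz = trajectory.coords[m][sel.indices]
        com = (w[:, None] * xyz).sum(axis=0)
        vals.append(np.sqrt((w * ((xyz - com) ** 2).sum(axis=1)).sum()))
    return TimeSeries(np.arange(trajectory.n_models), np.array(vals),
                      selection)


def histogram(values, bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Probability distribution of a series: (bin centers, probabilities
    summing to one)."""
    values = np.asarray(values, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    n = max(int(round((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(values, bins=n, range=(lo, lo + n * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum()


def rmsf_profile(trajectory: Structure, selection: str = "heavy",
                 fit_passes: int = 2) -> pd.DataFrame:
    """Per-residue RMSF about the time-mean structure.

    Frames are superposed onto the running mean structure (iterated
    ``fit_passes`` times), then each residue's fluctuation is the RMS over
    its selected atoms and all frames.  Columns: chain, resid, rmsf_A.
    """
    if trajectory.n_models < 2:
        raise TrajectoryError("need at least 2 frames for an RMSF profile")
    sel = _selected(trajectory, selection)
    frames = trajectory.coords[:, sel.indices, :].copy()
    mean = frames[0]
    for _ in range(fit_passes):
        fitted = []
        for m in range(frames.shape[0]):
            tr, _ = kabsch_fit(mean, frames[m])
            fitted.append(tr.apply(frames[m]))
        frames = np.asarray(fitted)
        mean = frames.mean(axis=0)
    msf = ((frames - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom

    rows = []
    keys = [trajectory.atoms[i].residue_key for i in sel.indices]
    order: list[tuple] = []
    groups: dict[tuple, list[int]] = {}
    for pos, k in enumerate(keys):
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(pos)
    for k in order:
        rows.append({"chain": k[0], "resid": k[1],
                     "rmsf_A": float(np.sqrt(msf[groups[k]].mean()))})
    return pd.DataFrame(rows)
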