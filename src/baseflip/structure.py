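"""Hierarchical coordinate model, PDB input/output and atom selection.

The in-memory layout follows the flat-atoms-plus-coordinate-array style of
trajectory libraries: a single ordered atom table shared by all models, and a
``(n_models, n_atoms, 3)`` coordinate array.  Chains and residues are views
obtained by grouping the atom table, which keeps whole-structure operations
(superposition, rigid transforms, COMs) plain numpy.

Parsing and serialization of the PDB format are delegated to gemmi; this
module only converts between gemmi's hierarchy and the flat model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from . import chemistry as chem
from .errors import (
    AtomLookupError,
    EmptySetError,
    FormatError,
    MutationError,
    SelectionError,
    TrajectoryError,
)

__all__ = [
    "Atom",
    "Structure",
    "AtomSet",
    "read_pdb",
    "write_pdb",
    "select_atoms",
    "center_of_mass",
    "mutate_thymine_to_uracil",
]


@dataclass(frozen=True)
class Atom:
    """One atom of the shared atom table (coordinates live on the Structure)."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0
    mass: float = 12.011

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


class Structure:
    """Ordered atoms plus per-model coordinates.

    Parameters
    ----------
    atoms:
        Ordered atom records, shared by every model.
    coords:
        Array of shape ``(n_models, n_atoms, 3)`` in Å.
    title, source:
        Free-text metadata.
    """

    def __init__(self, atoms: list[Atom], coords: np.ndarray,
                 title: str = "", source: str = "", provenance: str = ""):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None, :, :]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if coords.shape[1] != len(atoms):
            raise ValueError("coordinate count does not match atom count")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.atoms = list(atoms)
        self.coords = coords
        self.title = title
        self.source = source
        self.provenance = provenance  # e.g. "synthetic" for built structures

    # -- basic introspection -------------------------------------------------
    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def model_coords(self, model: int = 0) -> np.ndarray:
        return self.coords[model]

    def copy(self) -> "Structure":
        return Structure(list(self.atoms), self.coords.copy(),
                         self.title, self.source, self.provenance)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<Structure {self.title or self.source or 'unnamed'}: "
                f"{self.n_atoms} atoms, {self.n_models} model(s)>")

    # -- hierarchy views -----------------------------------------------------
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id)
        return list(seen)

    def residues(self) -> list[tuple[tuple[str, int, str], np.ndarray]]:
        """Ordered residues as (key, atom index array) pairs."""
        order: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            k = a.residue_key
            if k not in groups:
                groups[k] = []
                order.append(k)
            groups[k].append(i)
        return [(k, np.asarray(groups[k], dtype=int)) for k in order]

    def residue_indices(self, chain_id: str | None, residue_number: int,
                        insertion_code: str = "") -> np.ndarray:
        idx = [i for i, a in enumerate(self.atoms)
               if a.residue_number == residue_number
               and a.insertion_code == insertion_code
               and (chain_id is None or a.chain_id == chain_id)]
        if not idx:
            where = f"chain {chain_id} " if chain_id else ""
            raise AtomLookupError(f"residue {where}{residue_number} not found")
        chains = {self.atoms[i].chain_id for i in idx}
        if chain_id is None and len(chains) > 1:
            raise AtomLookupError(
                f"residue number {residue_number} is ambiguous across chains "
                f"{sorted(chains)}; pass a chain id")
        return np.asarray(idx, dtype=int)

    def atom_index(self, chain_id: str | None, residue_number: int,
                   atom_name: str) -> int:
        for i in self.residue_indices(chain_id, residue_number):
            if self.atoms[i].name == atom_name:
                return int(i)
        raise AtomLookupError(
            f"atom {atom_name} not found in residue {chain_id}/{residue_number}")

    def residue_name_of(self, chain_id: str | None, residue_number: int) -> str:
        return self.atoms[self.residue_indices(chain_id, residue_number)[0]].residue_name

    def validate_trajectory(self) -> None:
        """Raise unless every model shares the single atom table (by design
        all models do; kept for interface symmetry)."""
        if self.n_models < 1:
            raise TrajectoryError("structure has no models")


@dataclass
class AtomSet:
    """An ordered subset of atoms of one model of a Structure."""

    structure: Structure
    indices: np.ndarray
    model: int = 0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size and (self.indices.min() < 0
                                  or self.indices.max() >= self.structure.n_atoms):
            raise IndexError("atom indices out of range")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("duplicate atom indices in AtomSet")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def positions(self) -> np.ndarray:
        return self.structure.coords[self.model][self.indices]

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.structure.atoms[i].mass for i in self.indices])

    @property
    def atom_names(self) -> list[str]:
        return [self.structure.atoms[i].name for i in self.indices]

    def com(self, weighting: str = "mass") -> np.ndarray:
        return center_of_mass(self, weighting)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _atom_from_gemmi(serial: int, chain_id: str, res: gemmi.Residue,
                     at: gemmi.Atom) -> Atom:
    el = at.element.name if at.element and at.element.name != "X" else ""
    if not el or el == "D":
        el = chem.element_from_name(at.name, res.name)
    return Atom(
        serial=serial,
        name=at.name,
        element=el,
        residue_name=res.name.strip(),
        chain_id=chain_id,
        residue_number=res.seqid.num,
        insertion_code=(res.seqid.icode or "").strip(),
        occupancy=float(at.occ),
        b_factor=float(at.b_iso),
        mass=chem.atom_mass(el),
    )


def read_pdb(path, strict_models: bool = True) -> Structure:
    """Read a (possibly multi-model) PDB file into a :class:`Structure`.

    MODEL/ENDMDL blocks become trajectory frames.  When models disagree in
    atom count the call raises :class:`TrajectoryError` under
    ``strict_models``, otherwise it keeps the first model and warns.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")

    per_model: list[list[Atom]] = []
    per_coords: list[np.ndarray] = []
    for model in st:
        atoms: list[Atom] = []
        xyz: list[tuple[float, float, float]] = []
        serial = 0
        for ch in model:
            for res in ch:
                for at in res:
                    serial += 1
                    atoms.append(_atom_from_gemmi(serial, ch.name, res, at))
                    xyz.append((at.pos.x, at.pos.y, at.pos.z))
        per_model.append(atoms)
        per_coords.append(np.asarray(xyz, dtype=float))

    if not per_model[0]:
        raise FormatError(f"{path}: zero atoms")
    counts = {len(a) for a in per_model}
    if len(counts) > 1:
        if strict_models:
            raise TrajectoryError(
                f"{path}: models have differing atom counts {sorted(counts)}")
        import warnings
        warnings.warn(f"{path}: inconsistent models, keeping the first",
                      stacklevel=2)
        per_model, per_coords = per_model[:1], per_coords[:1]

    coords = np.stack(per_coords)
    return Structure(per_model[0], coords,
                     title=st.name or "", source=str(path))


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure to PDB, preserving names, numbering and coordinates
    (3-decimal columns); multi-model structures emit MODEL/ENDMDL blocks."""
    st = gemmi.Structure()
    st.name = structure.title or "baseflip"
    for m in range(structure.n_models):
        model = gemmi.Model(m + 1)
        cur_chain: gemmi.Chain | None = None
        cur_res: gemmi.Residue | None = None
        cur_key: tuple | None = None
        for i, a in enumerate(structure.atoms):
            if cur_chain is None or cur_chain.name != a.chain_id:
                cur_chain = gemmi.Chain(a.chain_id)
                model.add_chain(cur_chain)
                cur_chain = model[len(model) - 1]
                cur_key = None
            rkey = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
            if rkey != cur_key:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
                cur_chain.add_residue(res)
                cur_res = cur_chain[len(cur_chain) - 1]
                cur_key = rkey
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.occ = a.occupancy
            at.b_iso = a.b_factor
            x, y, z = structure.coords[m, i]
            at.pos = gemmi.Position(float(x), float(y), float(z))
            cur_res.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write PDB file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# selection mini-language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

_CLASS_KEYWORDS = {"base", "sugar", "phosphate", "heavy", "hydrogen",
                   "calpha", "ca", "nucleic", "protein", "backbone"}
_FIELD_KEYWORDS = {"chain", "resid", "residue", "resname", "name", "element"}


def _class_mask(structure: Structure, kw: str) -> np.ndarray:
    atoms = structure.atoms
    n = len(atoms)
    mask = np.zeros(n, dtype=bool)
    if kw in ("calpha", "ca"):
        for i, a in enumerate(atoms):
            mask[i] = a.name == "CA" and chem.is_amino_acid(a.residue_name)
    elif kw == "hydrogen":
        for i, a in enumerate(atoms):
            mask[i] = a.element.upper() == "H"
    elif kw == "heavy":
        for i, a in enumerate(atoms):
            mask[i] = a.element.upper() != "H"
    elif kw == "nucleic":
        for i, a in enumerate(atoms):
            mask[i] = chem.is_nucleotide(a.residue_name)
    elif kw == "protein":
        for i, a in enumerate(atoms):
            mask[i] = chem.is_amino_acid(a.residue_name)
    elif kw == "base":
        for i, a in enumerate(atoms):
            mask[i] = (chem.is_nucleotide(a.residue_name)
                       and a.name in chem.BASE_ATOMS)
    elif kw == "sugar":
        for i, a in enumerate(atoms):
            mask[i] = (chem.is_nucleotide(a.residue_name)
                       and a.name in chem.SUGAR_ATOMS)
    elif kw == "phosphate":
        for i, a in enumerate(atoms):
            mask[i] = (chem.is_nucleotide(a.residue_name)
                       and a.name in chem.PHOSPHATE_ATOMS)
    elif kw == "backbone":
        for i, a in enumerate(atoms):
            mask[i] = (chem.is_nucleotide(a.residue_name)
                       and (a.name in chem.PHOSPHATE_ATOMS
                            or a.name in chem.SUGAR_ATOMS))
    return mask


def _field_mask(structure: Structure, field_name: str, value: str) -> np.ndarray:
    atoms = structure.atoms
    vals = value.split(",")
    mask = np.zeros(len(atoms), dtype=bool)
    if field_name == "chain":
        want = set(vals)
        for i, a in enumerate(atoms):
            mask[i] = a.chain_id in want
    elif field_name in ("resid", "residue"):
        want: set[int] = set()
        for v in vals:
            if ":" in v:
                lo, hi = v.split(":")
                want.update(range(int(lo), int(hi) + 1))
            else:
                want.add(int(v))
        for i, a in enumerate(atoms):
            mask[i] = a.residue_number in want
    elif field_name == "resname":
        want = {v.upper() for v in vals}
        for i, a in enumerate(atoms):
            mask[i] = a.residue_name.upper() in want
    elif field_name == "name":
        want = {v.upper() for v in vals}
        for i, a in enumerate(atoms):
            mask[i] = a.name.upper() in want
    elif field_name == "element":
        want = {v.upper() for v in vals}
        for i, a in enumerate(atoms):
            mask[i] = a.element.upper() in want
    else:  # pragma: no cover - guarded by caller
        raise SelectionError(f"unknown field {field_name!r}")
    return mask


class _Parser:
    """Recursive-descent parser for the tiny selection grammar:

    expr   := term ('or' term)*
    term   := factor ('and' factor)*
    factor := 'not' factor | '(' expr ')' | class-kw | field value
    """

    def __init__(self, tokens: list[str], structure: Structure):
        self.toks = tokens
        self.pos = 0
        self.st = structure

    def peek(self) -> str | None:
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        m = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens near {self.peek()!r}")
        return m

    def expr(self) -> np.ndarray:
        m = self.term()
        while self.peek() == "or":
            self.next()
            m = m | self.term()
        return m

    def term(self) -> np.ndarray:
        m = self.factor()
        while self.peek() == "and":
            self.next()
            m = m & self.factor()
        return m

    def factor(self) -> np.ndarray:
        tok = self.next()
        low = tok.lower()
        if low == "not":
            return ~self.factor()
        if tok == "(":
            m = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parenthesis")
            return m
        if low in _CLASS_KEYWORDS:
            return _class_mask(self.st, low)
        if low in _FIELD_KEYWORDS:
            return _field_mask(self.st, low, self.next())
        raise SelectionError(f"unknown selection token {tok!r}")


def select_atoms(structure: Structure, criteria: str, model: int = 0) -> AtomSet:
    """Evaluate a selection expression and return an order-preserving AtomSet.

    An empty result is returned as an empty set, not an error.
    """
    tokens = _TOKEN_RE.findall(criteria)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, structure).parse()
    return AtomSet(structure, np.nonzero(mask)[0], model=model)


# ---------------------------------------------------------------------------
# centre of mass
# ---------------------------------------------------------------------------

def center_of_mass(atoms: AtomSet, weighting: str = "mass") -> np.ndarray:
    """Mass-weighted (default) or geometric centre of an atom set, in Å."""
    if len(atoms) == 0:
        raise EmptySetError("centre of mass of an empty atom set")
    pos = atoms.positions
    if weighting == "mass":
        w = atoms.masses
    elif weighting == "geometric":
        w = np.ones(len(atoms))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return (w[:, None] * pos).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# thymine -> uracil mutation
# ---------------------------------------------------------------------------

def mutate_thymine_to_uracil(structure: Structure, chain: str | None,
                             resnum: int) -> Structure:
    """Demethylate a thymine in place of the C5 methyl and rename it DU.

    Only the methyl carbon (C7/C5M) and its hydrogens are removed; every
    other atom keeps its exact coordinates.
    """
    idx = structure.residue_indices(chain, resnum)
    resname = structure.atoms[idx[0]].residue_name
    if chem.canonical_na(resname) != "T":
        raise MutationError(
            f"residue {chain}/{resnum} is {resname}, not thymine")
    drop = {int(i) for i in idx
            if structure.atoms[i].name in chem.THYMINE_METHYL}
    keep = [i for i in range(structure.n_atoms) if i not in drop]
    new_atoms = []
    for serial, i in enumerate(keep, start=1):
        a = structure.atoms[i]
        if i in idx:
            a = replace(a, residue_name=chem.PDB_RESNAME["U"], serial=serial)
        else:
            a = replace(a, serial=serial)
        new_atoms.append(a)
    coords = structure.coords[:, keep, :].copy()
    out = Structure(new_atoms, coords, structure.title, structure.source,
                    structure.provenance)
    return out
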