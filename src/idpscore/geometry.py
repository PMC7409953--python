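"""Coordinate-derived observables: phi dihedrals, distances, FRET, R_g.

This module computes the per-conformer observables the scorer can derive
itself from a multi-model PDB pool - backbone phi angles (for Karplus
J-coupling terms), proton-proton and tag-amide distances (NOE/PRE), scaled
Calpha-Calpha FRET efficiencies, and the radius of gyration.  Observables
whose predictors are external programs (chemical shifts, RDCs, R_h, SAXS
curves) are consumed as pre-computed tables instead; see
:mod:`idpscore.restraints`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from .restraints import BackCalcTable, DataType, FretParams

__all__ = [
    "ConformerPool",
    "dihedral",
    "compute_phi",
    "karplus_terms",
    "pair_distance",
    "fret_distance_scaled",
    "fret_efficiency",
    "radius_of_gyration",
    "phi_table",
    "distance_table",
    "fret_table",
]


@dataclass
class ConformerPool:
    """A pool of conformers sharing one sequence/atom topology.

    ``coords`` is (n_conformers, n_atoms, 3) in Angstrom; ``atoms`` carries
    per-atom metadata (residue_index, residue_name, atom_name, element,
    mass).  ``labels`` optionally tags each conformer with the parent
    sub-population it came from (used for composition analysis after
    optimization).
    """

    conformer_ids: list
    coords: np.ndarray
    atoms: pd.DataFrame
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must be (n_conformers, n_atoms, 3)")
        if self.coords.shape[0] != len(self.conformer_ids):
            raise ValueError("conformer_ids must match coords first axis")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atoms table must match coords second axis")
        if self.labels is not None and len(self.labels) != len(self.conformer_ids):
            raise ValueError("population labels must cover every conformer")

    @property
    def n_conformers(self) -> int:
        return len(self.conformer_ids)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        mask = (self.atoms["residue_index"] == residue_index) & (self.atoms["atom_name"] == atom_name)
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise KeyError(f"atom {atom_name} of residue {residue_index} not in pool topology")
        return int(idx[0])

    @classmethod
    def from_pdb(cls, path: str | Path, labels: list[str] | None = None) -> "ConformerPool":
        """Read a multi-model PDB; model number = conformer index.

        The first matching altloc of each atom is taken.  All models must
        share the atom topology of the first model.
        """
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("pool", str(path))
        models = list(structure)
        if not models:
            raise ValueError(f"{path}: no models found")

        def model_atoms(model):
            rows, xyz = [], []
            for chain in model:
                for residue in chain:
                    seen = set()
                    for atom in residue:
                        name = atom.get_name()
                        if name in seen:  # keep first altloc only
                            continue
                        seen.add(name)
                        rows.append((residue.id[1], residue.get_resname(), name,
                                     atom.element, float(atom.mass)))
                        xyz.append(atom.get_coord())
            return rows, np.asarray(xyz, dtype=float)

        ref_rows, ref_xyz = model_atoms(models[0])
        atoms = pd.DataFrame(ref_rows, columns=["residue_index", "residue_name",
                                                "atom_name", "element", "mass"])
        coords = np.empty((len(models), len(ref_rows), 3))
        coords[0] = ref_xyz
        key = [(r[0], r[2]) for r in ref_rows]
        for m, model in enumerate(models[1:], start=1):
            rows, xyz = model_atoms(model)
            if [(r[0], r[2]) for r in rows] != key:
                raise ValueError(f"{path}: model {model.id} atom topology differs from model 1")
            coords[m] = xyz
        ids = [m.id + 1 for m in models]
        return cls(ids, coords, atoms, labels)


# ---------------------------------------------------------------------------
# Elementary geometry
# ---------------------------------------------------------------------------


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle (degrees) in (-180, 180], IUPAC convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1)
    if b1n == 0 or np.linalg.norm(n1) == 0 or np.linalg.norm(n2) == 0:
        raise ValueError("degenerate (collinear) atom placement: dihedral undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1) / b1n
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def compute_phi(pool: ConformerPool, conformer: int, residue_index: int) -> float:
    """Backbone phi dihedral C(i-1)-N(i)-CA(i)-C(i) in degrees."""
    try:
        idx = [pool.atom_index(residue_index - 1, "C"),
               pool.atom_index(residue_index, "N"),
               pool.atom_index(residue_index, "CA"),
               pool.atom_index(residue_index, "C")]
    except KeyError as exc:
        raise ValueError(f"phi undefined for residue {residue_index}: {exc}") from exc
    xyz = pool.coords[conformer]
    return dihedral(*(xyz[i] for i in idx))


def karplus_terms(phi: float | np.ndarray, phi0: float) -> tuple[np.ndarray, np.ndarray]:
    """cos(phi - phi0) and its square, the two Karplus ensemble-average inputs."""
    c = np.cos(np.deg2rad(np.asarray(phi, dtype=float) - phi0))
    return c, c ** 2


def pair_distance(pool: ConformerPool, conformer: int,
                  atom_a: tuple[int, str], atom_b: tuple[int, str]) -> float:
    """Euclidean distance (A) between two named atoms of one conformer."""
    ia = pool.atom_index(*atom_a)
    ib = pool.atom_index(*atom_b)
    if ia == ib:
        raise ValueError(f"atom pair {atom_a}/{atom_b} selects the same atom twice")
    d = pool.coords[conformer, ia] - pool.coords[conformer, ib]
    return float(np.linalg.norm(d))


def fret_distance_scaled(r_ca_ca: float, n_residues: int, n_linker: int, upsilon: float) -> float:
    """Scale a Calpha-Calpha distance up to the inter-dye distance.

    ``r_da = r_ca_ca * ((N + N_linker) / N) ** upsilon`` - a polymer-model
    correction for the dye linkers, with N the sequence separation of the
    labelled residues and upsilon the Flory exponent.
    """
    if n_residues <= 0:
        raise ValueError("number of residues between labels must be positive")
    if n_linker < 0:
        raise ValueError("linker residue count must be non-negative")
    return float(r_ca_ca) * ((n_residues + n_linker) / n_residues) ** upsilon


def fret_efficiency(r_da: float | np.ndarray, r0: float) -> float | np.ndarray:
    """Forster transfer efficiency E = 1 / (1 + (r_da / r0)^6)."""
    if r0 <= 0:
        raise ValueError("Forster radius must be positive")
    r = np.asarray(r_da, dtype=float)
    if np.any(r <= 0):
        raise ValueError("inter-dye distance must be positive")
    e = 1.0 / (1.0 + (r / r0) ** 6)
    return float(e) if np.isscalar(r_da) or r.ndim == 0 else e


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Root-mean-square distance of atoms from their (mass-weighted) centroid."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ValueError("need at least two atoms")
    if masses is None:
        w = np.full(coords.shape[0], 1.0 / coords.shape[0])
    else:
        masses = np.asarray(masses, dtype=float)
        w = masses / masses.sum()
    center = w @ coords
    dev = coords - center
    return float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", dev, dev))))


# ---------------------------------------------------------------------------
# Table builders (pool -> BackCalcTable)
# ---------------------------------------------------------------------------


def phi_table(pool: ConformerPool, residues: Sequence[int],
              phi0: float = 60.0, ids: Sequence[str] | None = None) -> BackCalcTable:
    """Per-conformer phi angles for the given residues as a JC table."""
    residues = list(residues)
    ids = list(ids) if ids is not None else [f"{r}.3JHNHA" for r in residues]
    phi = np.empty((pool.n_conformers, len(residues)))
    for j, res in enumerate(residues):
        for i in range(pool.n_conformers):
            phi[i, j] = compute_phi(pool, i, res)
    return BackCalcTable.from_phi(DataType.JC, pool.conformer_ids, ids, phi, phi0=phi0)


def distance_table(pool: ConformerPool, pairs: Sequence[tuple[tuple[int, str], tuple[int, str]]],
                   datatype: DataType, ids: Sequence[str] | None = None) -> BackCalcTable:
    """Per-conformer atom-pair distances as a NOE or PRE table.

    For PRE pools without an explicit spin-label atom, pass the tag-site CB
    (or another configured proxy atom) as the first member of each pair.
    """
    datatype = DataType(datatype)
    pairs = list(pairs)
    if ids is None:
        ids = [f"{a[0]}.{a[1]}-{b[0]}.{b[1]}" for a, b in pairs]
    values = np.empty((pool.n_conformers, len(pairs)))
    for j, (a, b) in enumerate(pairs):
        ia, ib = pool.atom_index(*a), pool.atom_index(*b)
        if ia == ib:
            raise ValueError(f"pair {a}/{b} selects the same atom twice")
        diff = pool.coords[:, ia, :] - pool.coords[:, ib, :]
        values[:, j] = np.linalg.norm(diff, axis=1)
    return BackCalcTable(datatype, pool.conformer_ids, list(ids), values)


def fret_table(pool: ConformerPool, label_pairs: Sequence[tuple[int, int]],
               params: FretParams, ids: Sequence[str] | None = None) -> BackCalcTable:
    """Per-conformer FRET efficiencies for Calpha label pairs.

    Chain per conformer: Calpha-Calpha distance -> linker-scaled inter-dye
    distance -> efficiency.  Ensemble averaging then happens on the
    efficiency scale (fast-exchange <E> regime).
    """
    label_pairs = list(label_pairs)
    if ids is None:
        ids = [f"E.{a}-{b}" for a, b in label_pairs]
    values = np.empty((pool.n_conformers, len(label_pairs)))
    for j, (res_a, res_b) in enumerate(label_pairs):
        n_sep = abs(res_b - res_a)
        ia, ib = pool.atom_index(res_a, "CA"), pool.atom_index(res_b, "CA")
        diff = pool.coords[:, ia, :] - pool.coords[:, ib, :]
        r = np.linalg.norm(diff, axis=1)
        r_da = np.array([fret_distance_scaled(v, n_sep, params.n_linker, params.upsilon)
                         for v in r])
        values[:, j] = fret_efficiency(r_da, params.r0)
    return BackCalcTable(DataType.FRET, pool.conformer_ids, list(ids), values)
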