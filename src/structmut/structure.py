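"""Protein structures: PDB IO, Gaussian-network modes, hinges, SASA, interfaces.

The elastic-network model is the scalar Gaussian network model (GNM): unit
springs connect C-alpha atoms within a cutoff (default 10 A, i.e. 1 nm), the
Kirchhoff (graph Laplacian) matrix is diagonalized, and slow nontrivial modes
describe collective motions.  Hinge residues are where a slow mode's
eigenvector component is near zero or changes sign — the boundary between
regions moving in opposite directions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg
from scipy.spatial import cKDTree

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

# Heavy-atom van der Waals radii (A); hydrogens are excluded from SASA.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}


@dataclass
class ProteinStructure:
    """Flat atom table grouped into ordered residues.

    Residue-level arrays (``chain_ids``, ``res_numbers``, ``res_names``) have
    one entry per residue; atom-level arrays map each atom to its residue via
    ``atom_res_index``.  ``calpha_index`` holds the atom index of each
    residue's C-alpha, or -1 when absent.
    """

    chain_ids: np.ndarray
    res_numbers: np.ndarray
    res_names: np.ndarray
    atom_res_index: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray  # (n_atoms, 3) in Angstrom
    calpha_index: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.calpha_index is None:
            ca = np.full(self.n_residues, -1, dtype=np.int64)
            for i, (ri, name) in enumerate(zip(self.atom_res_index, self.atom_names)):
                if name == "CA" and ca[ri] == -1:
                    ca[ri] = i
            self.calpha_index = ca
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.res_numbers)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residue_ids(self) -> list[tuple[str, int]]:
        return list(zip(self.chain_ids.tolist(), self.res_numbers.tolist()))

    def calpha_coords(self) -> np.ndarray:
        if (self.calpha_index < 0).any():
            missing = [
                rid for rid, ci in zip(self.residue_ids(), self.calpha_index) if ci < 0
            ]
            raise ValueError(f"residues missing a C-alpha: {missing[:10]}")
        return self.coords[self.calpha_index]

    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    @classmethod
    def from_calpha(
        cls,
        coords: np.ndarray,
        chain_id: str = "A",
        res_name: str = "ALA",
        start_number: int = 1,
    ) -> "ProteinStructure":
        """Build a C-alpha-only structure from an (n, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        return cls(
            chain_ids=np.full(n, chain_id, dtype="<U4"),
            res_numbers=np.arange(start_number, start_number + n, dtype=np.int64),
            res_names=np.full(n, res_name, dtype="<U3"),
            atom_res_index=np.arange(n, dtype=np.int64),
            atom_names=np.full(n, "CA", dtype="<U4"),
            elements=np.full(n, "C", dtype="<U2"),
            coords=coords.copy(),
        )


def _structure_from_atom_array(arr: bst.AtomArray) -> ProteinStructure:
    starts = bst.get_residue_starts(arr)
    bounds = np.append(starts, len(arr))
    atom_res_index = np.empty(len(arr), dtype=np.int64)
    for ri, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
        atom_res_index[s:e] = ri
    struct = ProteinStructure(
        chain_ids=arr.chain_id[starts].astype("<U4"),
        res_numbers=arr.res_id[starts].astype(np.int64),
        res_names=arr.res_name[starts].astype("<U3"),
        atom_res_index=atom_res_index,
        atom_names=arr.atom_name.astype("<U4"),
        elements=arr.element.astype("<U2"),
        coords=np.asarray(arr.coord, dtype=float),
    )
    n_missing = int((struct.calpha_index < 0).sum())
    if n_missing:
        warnings.warn(f"{n_missing} residues lack a C-alpha atom", stacklevel=3)
    return struct


def read_pdb(path: str | Path, model: str = "first"):
    """Read a PDB file; ``model='all'`` returns one structure per MODEL block.

    Residues are ordered by chain then residue number as stored; altlocs are
    resolved to the highest-occupancy conformer.
    """
    if model not in ("first", "all"):
        raise ValueError("model must be 'first' or 'all'")
    try:
        pdb = PDBFile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise ValueError(f"unreadable PDB file {path}: {exc}") from exc
    if model == "first":
        arr = pdb.get_structure(model=1, altloc="occupancy")
        return _structure_from_atom_array(arr)
    stack = pdb.get_structure(altloc="occupancy")
    return [_structure_from_atom_array(stack[i]) for i in range(stack.stack_depth())]


def write_pdb(structures, path: str | Path) -> None:
    """Write one structure, or a list as a multi-model PDB."""
    if isinstance(structures, ProteinStructure):
        structures = [structures]
    first = structures[0]
    arrays = []
    for s in structures:
        arr = bst.AtomArray(s.n_atoms)
        arr.chain_id = first.chain_ids[s.atom_res_index]
        arr.res_id = first.res_numbers[s.atom_res_index]
        arr.res_name = first.res_names[s.atom_res_index]
        arr.atom_name = s.atom_names
        arr.element = s.elements
        arr.coord = np.asarray(s.coords, dtype=np.float32)
        arr.hetero = np.zeros(s.n_atoms, dtype=bool)
        arrays.append(arr)
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Gaussian network model
# ---------------------------------------------------------------------------


@dataclass
class ElasticNetworkModel:
    kirchhoff: np.ndarray
    cutoff: float
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns matched to eigenvalues
    n_zero_modes: int

    @property
    def n_nodes(self) -> int:
        return self.kirchhoff.shape[0]


def build_gnm(structure: ProteinStructure, cutoff: float = 10.0) -> ElasticNetworkModel:
    """Kirchhoff matrix and full eigendecomposition of the C-alpha network.

    kirchhoff[i, j] = -1 when C-alpha i and j are within ``cutoff`` A (i != j);
    the diagonal makes every row sum to zero.  A disconnected contact network
    yields one zero mode per connected component (reported via n_zero_modes).
    """
    coords = structure.calpha_coords()
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 C-alpha atoms")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    contact = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    kirchhoff = -contact.astype(float)
    np.fill_diagonal(kirchhoff, contact.sum(axis=1).astype(float))
    eigvals, eigvecs = linalg.eigh(kirchhoff)
    tol = 1e-8 * max(1.0, float(eigvals[-1]))
    n_zero = int((np.abs(eigvals) < tol).sum())
    return ElasticNetworkModel(
        kirchhoff=kirchhoff,
        cutoff=cutoff,
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        n_zero_modes=n_zero,
    )


def mode(enm: ElasticNetworkModel, k: int) -> np.ndarray:
    """Eigenvector of the k-th (1-based) nontrivial mode, sign-fixed.

    Sign convention: the first component of magnitude > 1e-12 is positive.
    """
    if k < 1 or k > enm.n_nodes - enm.n_zero_modes:
        raise IndexError(
            f"mode {k} out of range (model has {enm.n_nodes - enm.n_zero_modes} "
            "nontrivial modes)"
        )
    v = enm.eigenvectors[:, enm.n_zero_modes + k - 1].copy()
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        v = -v
    return v


@dataclass
class HingeSet:
    residues: list[tuple[str, int]]
    mode_index: int
    tolerance: float


def find_hinges(
    mode_vector: np.ndarray,
    structure: ProteinStructure,
    tolerance: float | None = None,
    mode_index: int = 0,
) -> HingeSet:
    """Residues at (near-)zero crossings of a mode vector.

    A residue is a hinge when its component magnitude is <= tolerance
    (default 0.05 x max|component|) or its sign differs from the previous
    residue's.  Consecutive hinge residues are reported individually.
    """
    v = np.asarray(mode_vector, dtype=float)
    if v.size != structure.n_residues:
        raise ValueError("mode vector length must equal residue count")
    if tolerance is None:
        tolerance = 0.05 * float(np.abs(v).max())
    small = np.abs(v) <= tolerance
    flip = np.zeros(v.size, dtype=bool)
    flip[1:] = v[:-1] * v[1:] < 0
    mask = small | flip
    ids = structure.residue_ids()
    return HingeSet(
        residues=[ids[i] for i in np.flatnonzero(mask)],
        mode_index=mode_index,
        tolerance=float(tolerance),
    )


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform points on the unit sphere (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into their principal-axes frame.

    The frame is fixed by the structure itself (PCA axes, third-moment sign
    convention, right-handedness), so the sphere-point lattice sees an
    identical geometry for any rigidly transformed copy — making SASA exactly
    invariant to global rotation and translation.
    """
    center = coords.mean(axis=0)
    x = coords - center
    if len(x) < 3:
        return x
    cov = x.T @ x
    _, axes = np.linalg.eigh(cov)
    axes = axes[:, ::-1]  # descending variance
    proj = x @ axes
    for k in range(3):
        s = (proj[:, k] ** 3).sum()
        if s < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return x @ axes


@dataclass
class SasaProfile:
    area: np.ndarray  # per residue, A^2
    atom_area: np.ndarray
    probe_radius: float
    n_sphere_points: int

    def buried(self, threshold: float = 20.0) -> np.ndarray:
        """Boolean mask of buried residues (area <= threshold A^2)."""
        return self.area <= threshold


def sasa(
    structure: ProteinStructure,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> SasaProfile:
    """Per-residue solvent-accessible surface area by Shrake-Rupley counting.

    Heavy atoms only; radii C 1.7, N 1.55, O 1.52, S 1.8 A.  Exact duplicate
    atoms (same position and radius) are collapsed to one before occlusion.
    """
    heavy = np.flatnonzero(structure.heavy_mask())
    radii = np.empty(heavy.size)
    for out_i, ai in enumerate(heavy):
        el = structure.elements[ai]
        if el not in VDW_RADII:
            raise ValueError(
                f"unknown element {el!r} for atom {structure.atom_names[ai]} "
                f"in residue {structure.residue_ids()[structure.atom_res_index[ai]]}"
            )
        radii[out_i] = VDW_RADII[el]

    coords = _canonical_frame(structure.coords[heavy])

    # collapse coincident duplicates: keep the first, zero the rest
    order = np.lexsort((radii, coords[:, 2], coords[:, 1], coords[:, 0]))
    keep = np.ones(heavy.size, dtype=bool)
    for a, b in zip(order[:-1], order[1:]):
        if keep[a] and np.allclose(coords[a], coords[b], atol=1e-6) and radii[a] == radii[b]:
            keep[b] = False

    sphere = _fibonacci_sphere(n_sphere_points)
    atom_area = np.zeros(structure.n_atoms)
    active = np.flatnonzero(keep)
    if active.size:
        tree = cKDTree(coords[active])
        max_r = radii.max() + probe
        for ii in active:
            r_ext = radii[ii] + probe
            pts = coords[ii] + r_ext * sphere
            neigh = [
                j
                for j in tree.query_ball_point(coords[ii], r_ext + max_r)
                if active[j] != ii
            ]
            exposed = np.ones(n_sphere_points, dtype=bool)
            for j in neigh:
                aj = active[j]
                d2 = ((pts - coords[aj]) ** 2).sum(axis=1)
                exposed &= d2 >= (radii[aj] + probe) ** 2
            atom_area[heavy[ii]] = (
                exposed.sum() / n_sphere_points * 4.0 * np.pi * r_ext**2
            )
    res_area = np.zeros(structure.n_residues)
    np.add.at(res_area, structure.atom_res_index, atom_area)
    return SasaProfile(
        area=res_area,
        atom_area=atom_area,
        probe_radius=probe,
        n_sphere_points=n_sphere_points,
    )


# ---------------------------------------------------------------------------
# Interfaces and distances
# ---------------------------------------------------------------------------


def interface_residues(
    structure_a: ProteinStructure,
    structure_b: ProteinStructure,
    cutoff: float = 10.0,
) -> list[tuple[str, int]]:
    """Residues of A with any heavy atom within ``cutoff`` A of B's heavy atoms."""
    if structure_a.n_atoms == 0 or structure_b.n_atoms == 0:
        raise ValueError("empty structure")
    a_idx = np.flatnonzero(structure_a.heavy_mask())
    b_idx = np.flatnonzero(structure_b.heavy_mask())
    tree = cKDTree(structure_b.coords[b_idx])
    hits = tree.query_ball_point(structure_a.coords[a_idx], cutoff)
    res_hit = np.zeros(structure_a.n_residues, dtype=bool)
    for ai, h in zip(a_idx, hits):
        if h:
            res_hit[structure_a.atom_res_index[ai]] = True
    ids = structure_a.residue_ids()
    return [ids[i] for i in np.flatnonzero(res_hit)]


def distance_to_residue_set(
    structure: ProteinStructure, target_residues: Sequence
) -> np.ndarray:
    """Per-residue minimum C-alpha distance (A) to a target residue set.

    Targets may be residue numbers or (chain, residue number) pairs; every
    target must exist in the structure.
    """
    if not len(target_residues):
        raise ValueError("target set is empty")
    ids = structure.residue_ids()
    index = {rid: i for i, rid in enumerate(ids)}
    index_by_num: dict[int, int] = {}
    for i, (_, num) in enumerate(ids):
        index_by_num.setdefault(num, i)
    targets = []
    for t in target_residues:
        if isinstance(t, tuple):
            if t not in index:
                raise KeyError(f"target residue {t} not in structure")
            targets.append(index[t])
        else:
            if int(t) not in index_by_num:
                raise KeyError(f"target residue {t} not in structure")
            targets.append(index_by_num[int(t)])
    ca = structure.calpha_coords()
    tc = ca[targets]
    diff = ca[:, None, :] - tc[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)).min(axis=1)
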