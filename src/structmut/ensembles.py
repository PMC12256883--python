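"""Conformational-ensemble analysis: superposition, RMSD/RMSF, block t tests, PCA.

Ensembles stand in for MD trajectories and are ingested as multi-model PDB
plus per-frame times (sidecar TSV or uniform spacing).  The flexibility
comparison follows a block protocol: each ensemble's analysis window is cut
into contiguous equal-frame blocks, a per-residue RMSF is computed per block,
and a Welch two-sample t test compares the block RMSFs of the two ensembles
residue by residue.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure import ProteinStructure, read_pdb, write_pdb

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class ConformationEnsemble:
    """Frames x atoms x 3 coordinate stack sharing one atom table."""

    structure: ProteinStructure  # topology (frame-0 coordinates)
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    times: np.ndarray  # ns, strictly increasing

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise ValueError("frame atom count differs from topology")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def window_indices(self, window: tuple[float, float] | None) -> np.ndarray:
        if window is None:
            return np.arange(self.n_frames)
        t0, t1 = window
        idx = np.flatnonzero((self.times >= t0) & (self.times <= t1))
        if idx.size == 0:
            raise ValueError(f"window {window} selects no frames")
        return idx

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        times_path: str | Path | None = None,
        dt: float | None = None,
    ) -> "ConformationEnsemble":
        """Load a multi-model PDB; times from a sidecar TSV or uniform ``dt`` ns."""
        structures = read_pdb(path, model="all")
        frames = np.stack([s.coords for s in structures])
        if times_path is not None:
            times = pd.read_csv(times_path, sep="\t")["time_ns"].to_numpy(dtype=float)
        elif dt is not None:
            times = np.arange(len(structures)) * dt
        else:
            raise ValueError("provide times_path or dt")
        return cls(structure=structures[0], frames=frames, times=times)

    def to_pdb(self, path: str | Path, times_path: str | Path | None = None) -> None:
        frames = []
        for f in self.frames:
            s = ProteinStructure(
                chain_ids=self.structure.chain_ids,
                res_numbers=self.structure.res_numbers,
                res_names=self.structure.res_names,
                atom_res_index=self.structure.atom_res_index,
                atom_names=self.structure.atom_names,
                elements=self.structure.elements,
                coords=f,
            )
            frames.append(s)
        write_pdb(frames, path)
        if times_path is not None:
            pd.DataFrame({"frame": np.arange(self.n_frames), "time_ns": self.times}).to_csv(
                times_path, sep="\t", index=False
            )

    def calpha_atom_indices(self) -> np.ndarray:
        idx = self.structure.calpha_index
        if (idx < 0).any():
            raise ValueError("some residues lack a C-alpha")
        return idx


def _subset_indices(ens_or_struct, atom_subset) -> np.ndarray:
    if atom_subset is None:
        n = (
            ens_or_struct.n_atoms
            if hasattr(ens_or_struct, "n_atoms")
            else len(ens_or_struct)
        )
        return np.arange(n)
    if isinstance(atom_subset, str):
        if atom_subset != "calpha":
            raise ValueError("atom_subset must be 'calpha', None or index array")
        return ens_or_struct.calpha_atom_indices()
    return np.asarray(atom_subset, dtype=np.int64)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    atom_subset: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    The rotation/translation minimizing the subset RMSD is found by SVD of
    the covariance matrix with a proper-rotation (det +1) correction, then
    applied to all mobile atoms.  Returns (transformed mobile, subset RMSD).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sub = np.arange(len(mobile)) if atom_subset is None else np.asarray(atom_subset)
    if sub.size < 3:
        raise ValueError("need at least 3 atoms to superpose")
    m = mobile[sub]
    r = reference[sub]
    mc, rc = m.mean(axis=0), r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    if np.linalg.matrix_rank(r - rc, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) atom subset")
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mobile - mc) @ rot.T + rc
    rmsd = float(np.sqrt(((moved[sub] - r) ** 2).sum(axis=1).mean()))
    return moved, rmsd


def rmsd_series(
    ens: ConformationEnsemble,
    reference_frame: int | np.ndarray = 0,
    atom_subset=None,
) -> np.ndarray:
    """Per-frame RMSD after optimal superposition onto a reference frame."""
    sub = _subset_indices(ens, atom_subset)
    ref = (
        ens.frames[reference_frame]
        if isinstance(reference_frame, (int, np.integer))
        else np.asarray(reference_frame, dtype=float)
    )
    out = np.empty(ens.n_frames)
    for i in range(ens.n_frames):
        _, out[i] = kabsch_superpose(ens.frames[i], ref, sub)
    return out


def _superpose_to_mean(
    frames: np.ndarray, sub: np.ndarray, n_iter: int = 2
) -> np.ndarray:
    """Superpose frames onto their iterated mean structure (default 2 passes)."""
    ref = frames[0]
    aligned = frames
    for _ in range(n_iter):
        aligned = np.stack([kabsch_superpose(f, ref, sub)[0] for f in aligned])
        ref = aligned.mean(axis=0)
    return aligned


def rmsf(
    ens: ConformationEnsemble,
    window: tuple[float, float] | None = None,
    atom_subset="calpha",
) -> np.ndarray:
    """Per-residue RMSF (A) over the window, after mean-structure superposition."""
    idx = ens.window_indices(window)
    if idx.size < 2:
        raise ValueError("window must select at least 2 frames")
    sub = _subset_indices(ens, atom_subset)
    aligned = _superpose_to_mean(ens.frames[idx], sub)
    x = aligned[:, sub, :]
    mean = x.mean(axis=0)
    return np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0))


@dataclass
class FlexibilityComparison:
    rmsf_a: np.ndarray
    rmsf_b: np.ndarray
    t_statistic: np.ndarray
    p_value: np.ndarray
    n_blocks: int
    window: tuple[float, float] | None


def _block_rmsfs(
    ens: ConformationEnsemble,
    idx: np.ndarray,
    sub: np.ndarray,
    n_blocks: int,
) -> np.ndarray:
    """(n_blocks, n_residues) per-block RMSF over contiguous equal-frame blocks."""
    per = idx.size // n_blocks
    out = []
    for b in range(n_blocks):
        block_idx = idx[b * per : (b + 1) * per]
        aligned = _superpose_to_mean(ens.frames[block_idx], sub)
        x = aligned[:, sub, :]
        mean = x.mean(axis=0)
        out.append(np.sqrt(((x - mean) ** 2).sum(axis=2).mean(axis=0)))
    return np.stack(out)


def rmsf_difference_test(
    ens_a: ConformationEnsemble,
    ens_b: ConformationEnsemble,
    window: tuple[float, float] | None = None,
    n_blocks: int = 5,
) -> FlexibilityComparison:
    """Per-residue Welch t test between block RMSFs of two ensembles.

    Zero-variance convention: identical block values give t = 0, p = 1;
    a zero pooled SE with a nonzero mean difference gives the smallest
    positive p (the difference is unambiguous at block resolution).
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    idx_a = ens_a.window_indices(window)
    idx_b = ens_b.window_indices(window)
    if idx_a.size < 2 * n_blocks or idx_b.size < 2 * n_blocks:
        raise ValueError("each window must contain at least 2 frames per block")
    sub_a = _subset_indices(ens_a, "calpha")
    sub_b = _subset_indices(ens_b, "calpha")
    blocks_a = _block_rmsfs(ens_a, idx_a, sub_a, n_blocks)
    blocks_b = _block_rmsfs(ens_b, idx_b, sub_b, n_blocks)
    if blocks_a.shape[1] != blocks_b.shape[1]:
        raise ValueError("ensembles have different residue counts")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(blocks_a, blocks_b, axis=0, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    diff = blocks_a.mean(axis=0) - blocks_b.mean(axis=0)
    bad = ~np.isfinite(t)
    t[bad & (np.abs(diff) <= 1e-12)] = 0.0
    p[bad & (np.abs(diff) <= 1e-12)] = 1.0
    t[bad & (np.abs(diff) > 1e-12)] = np.inf
    p[bad & (np.abs(diff) > 1e-12)] = _TINY_P
    return FlexibilityComparison(
        rmsf_a=rmsf(ens_a, window=window),
        rmsf_b=rmsf(ens_b, window=window),
        t_statistic=t,
        p_value=p,
        n_blocks=n_blocks,
        window=window,
    )


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, 3m) orthonormal rows
    explained_variance: np.ndarray  # non-increasing
    projections: np.ndarray  # (n_frames, n_components)
    mean: np.ndarray  # (3m,) mean flattened coordinates


def coordinate_pca(
    ens: ConformationEnsemble,
    window: tuple[float, float] | None = None,
    atom_subset="calpha",
) -> PCAResult:
    """PCA of superposed, flattened subset coordinates."""
    idx = ens.window_indices(window)
    if idx.size < 3:
        raise ValueError("need at least 3 frames for PCA")
    sub = _subset_indices(ens, atom_subset)
    aligned = _superpose_to_mean(ens.frames[idx], sub)
    x = aligned[:, sub, :].reshape(idx.size, -1)
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (idx.size - 1)
    return PCAResult(
        components=vt,
        explained_variance=var,
        projections=u * s,
        mean=mean,
    )


def contact_residence(
    ens: ConformationEnsemble,
    residue_pairs: Sequence[tuple[int, int]],
    cutoff: float = 4.0,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Percentage of frames in which each residue pair is in contact.

    Contact = minimum heavy-atom distance <= cutoff (default 4 A).  Pairs are
    given as residue numbers of the shared topology.
    """
    idx = ens.window_indices(window)
    struct = ens.structure
    heavy = struct.heavy_mask()
    num_to_atoms: dict[int, np.ndarray] = {}
    for num in np.unique(struct.res_numbers):
        res_idx = np.flatnonzero(struct.res_numbers == num)
        atoms = np.flatnonzero(
            np.isin(struct.atom_res_index, res_idx) & heavy
        )
        num_to_atoms[int(num)] = atoms
    out = np.empty(len(residue_pairs))
    for k, (ri, rj) in enumerate(residue_pairs):
        ai = num_to_atoms.get(int(ri))
        aj = num_to_atoms.get(int(rj))
        if ai is None or aj is None or ai.size == 0 or aj.size == 0:
            raise KeyError(f"residue pair ({ri}, {rj}) not found")
        in_contact = 0
        for f in idx:
            d = ens.frames[f][ai][:, None, :] - ens.frames[f][aj][None, :, :]
            if np.sqrt((d**2).sum(axis=2)).min() <= cutoff:
                in_contact += 1
        out[k] = 100.0 * in_contact / idx.size
    return out
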