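"""Synthetic-data generators with machine-readable ground truth.

Every generator is deterministic under a fixed seed and emits data in exactly
the formats the corresponding readers consume, so the whole pipeline can be
exercised end to end with known answers: two-domain structures with a planted
hinge linker, mutation cohorts drawn from a stated 96-channel signature with
tunable enrichment near target residues, neutral or positively selected genes
for dN/dS, conformational ensembles with specified per-residue variance, and
two-arm survival cohorts with a specified hazard ratio.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .catalog import (
    BASES,
    CodingGene,
    MutationRecord,
    MutationalSignature,
    classify_consequence,
    enumerate_snvs,
)
from .selection import build_universe
from .structure import ProteinStructure
from .survival import SurvivalCohort

CA_SPACING = 3.8  # consecutive C-alpha distance along a chain, Angstrom


@dataclass
class GroundTruth:
    """What was planted, serialized alongside every generated dataset."""

    kind: str
    params: dict

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"kind": self.kind, "params": self.params}, fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(kind=d["kind"], params=d["params"])


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


def _compact_coil(n: int, rng: np.random.Generator) -> np.ndarray:
    """A compact self-avoiding-ish chain with ~3.8 A steps inside a ball."""
    radius = 1.25 * (3.0 * n * 125.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    coords = np.zeros((n, 3))
    for i in range(1, n):
        min_sep = 3.4
        for attempt in range(400):
            step = rng.normal(size=3)
            step *= CA_SPACING / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if np.linalg.norm(cand) > radius:
                continue
            if i > 1:
                d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                if d.min() < min_sep:
                    continue
            coords[i] = cand
            break
        else:  # relax self-avoidance rather than fail
            step = rng.normal(size=3)
            step *= CA_SPACING / np.linalg.norm(step)
            cand = coords[i - 1] + step
            if np.linalg.norm(cand) > radius:
                cand = coords[i - 1] - step
            coords[i] = cand
    return coords - coords.mean(axis=0)


def _orient_toward_x(coords: np.ndarray, index: int, direction: int) -> np.ndarray:
    """Rotate centered coords so residue ``index`` points along +x (or -x)."""
    c = coords - coords.mean(axis=0)
    v = c[index]
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        return c
    target = np.array([float(direction), 0.0, 0.0])
    axis = np.cross(v / norm, target)
    s = np.linalg.norm(axis)
    dot = float(np.dot(v / norm, target))
    if s < 1e-12:
        rot = np.eye(3) if dot > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        rot = Rotation.from_rotvec(axis / s * np.arctan2(s, dot)).as_matrix()
    return c @ rot.T


def make_two_domain_structure(
    n_per_domain: int = 30,
    linker_length: int = 4,
    seed: int = 0,
) -> tuple[ProteinStructure, GroundTruth]:
    """Two compact globules joined by an extended linker (the planted hinge).

    The chain runs domain A -> linker -> domain B along +x.  The inter-domain
    span is stretched (keeping consecutive C-alpha steps below the 10 A GNM
    cutoff) until no A atom comes within ~12 A of any B atom, so intradomain
    springs dominate and the slowest nontrivial mode flips sign inside the
    linker.  Ground truth records the 1-based linker residue range.  With
    linker_length 0 the clearance guarantee is dropped (single-domain-like
    control, no guaranteed hinge).
    """
    if n_per_domain < 10:
        raise ValueError("n_per_domain must be >= 10")
    rng = np.random.default_rng(seed)
    dom_a = _orient_toward_x(_compact_coil(n_per_domain, rng), n_per_domain - 1, +1)
    dom_b = _orient_toward_x(_compact_coil(n_per_domain, rng), 0, -1)
    # overshoot of each domain past its linker-anchor residue along x
    shift_a = float(dom_a[:, 0].max() - dom_a[-1, 0])
    shift_b = float(dom_b[0, 0] - dom_b[:, 0].min())
    span = CA_SPACING * (linker_length + 1)
    if linker_length >= 1:
        # stretch for clearance but keep each step comfortably inside the cutoff
        span = min(max(span, shift_a + shift_b + 12.0), 9.0 * (linker_length + 1))
    step = span / (linker_length + 1)
    a_end = dom_a[-1]
    linker = np.empty((linker_length, 3))
    for i in range(linker_length):
        linker[i] = a_end + np.array([step * (i + 1), 0.0, 0.0])
        linker[i, 1:] += rng.normal(scale=0.25, size=2)
    dom_b = dom_b + (a_end + np.array([span, 0.0, 0.0]) - dom_b[0])
    coords = np.vstack([dom_a, linker, dom_b])
    structure = ProteinStructure.from_calpha(coords)
    truth = GroundTruth(
        kind="two_domain_structure",
        params={
            "n_per_domain": n_per_domain,
            "linker_length": linker_length,
            "seed": seed,
            "linker_start": n_per_domain + 1,
            "linker_end": n_per_domain + linker_length,
        },
    )
    return structure, truth


# ---------------------------------------------------------------------------
# Mutation cohorts
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if (a + b + c) not in ("TAA", "TAG", "TGA")
]


def random_coding_gene(
    n_codons: int, seed_or_rng, gene: str = "SYNGENE"
) -> CodingGene:
    """A random CDS (ATG start, no internal stops) with random flanks."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    codons = ["ATG"] + [
        _NONSTOP_CODONS[rng.integers(len(_NONSTOP_CODONS))]
        for _ in range(n_codons - 1)
    ]
    return CodingGene(
        gene=gene,
        cds="".join(codons),
        flank5=BASES[rng.integers(4)],
        flank3=BASES[rng.integers(4)],
    )


def make_mutation_cohort(
    gene: CodingGene,
    signature: MutationalSignature,
    n_mutations: int,
    selection: tuple[Sequence[int], float] | None = None,
    seed: int = 0,
    proximity_k: int = 5,
    structure: ProteinStructure | None = None,
    proximity_cutoff: float = 10.0,
) -> tuple[list[MutationRecord], GroundTruth]:
    """Draw missense mutations from the signature-weighted universe.

    ``selection = (target_residues, enrichment_fold)`` multiplies the weight
    of universe entries near the targets before renormalization: within
    ``proximity_k`` residues along the sequence by default, or within
    ``proximity_cutoff`` A of the targets' C-alphas when a structure is
    supplied.  enrichment_fold = 1 reproduces the pure signature null.
    """
    rng = np.random.default_rng(seed)
    universe = build_universe(gene, signature)
    entries = universe.entries.copy()
    weights = entries["weight"].to_numpy().copy()
    targets: list[int] = []
    enrichment = 1.0
    if selection is not None:
        targets, enrichment = list(selection[0]), float(selection[1])
        if enrichment < 1:
            raise ValueError("enrichment_fold must be >= 1")
        pos = entries["protein_position"].to_numpy()
        if structure is not None:
            from .structure import distance_to_residue_set

            dist = distance_to_residue_set(structure, targets)
            near = dist[pos - 1] <= proximity_cutoff
        else:
            near = np.zeros(pos.size, dtype=bool)
            for t in targets:
                near |= np.abs(pos - t) <= proximity_k
        weights[near] *= enrichment
        weights /= weights.sum()
    records: list[MutationRecord] = []
    if n_mutations > 0:
        picks = rng.choice(len(entries), size=n_mutations, replace=True, p=weights)
        for i, k in enumerate(picks):
            row = entries.iloc[int(k)]
            consequence, prot = classify_consequence(
                gene, int(row["cds_position"]), row["ref_base"], row["alt_base"]
            )
            records.append(
                MutationRecord(
                    gene=gene.gene,
                    sample_id=f"S{i + 1:05d}",
                    tissue="synthetic",
                    cds_position=int(row["cds_position"]),
                    ref_base=row["ref_base"],
                    alt_base=row["alt_base"],
                    protein_change=prot,
                    consequence=consequence,
                )
            )
    truth = GroundTruth(
        kind="mutation_cohort",
        params={
            "gene": gene.gene,
            "n_mutations": n_mutations,
            "target_residues": targets,
            "enrichment_fold": enrichment,
            "proximity_k": proximity_k,
            "seed": seed,
        },
    )
    return records, truth


def make_dnds_cohort(
    n_genes: int,
    gene_length: int,
    signature: MutationalSignature,
    omega: float,
    mutations_per_gene: int,
    seed: int = 0,
) -> tuple[dict[str, CodingGene], dict[str, list[MutationRecord]], GroundTruth]:
    """Per-gene mutation draws with synonymous : nonsynonymous rates rS : omega*rN.

    ``gene_length`` is in codons.  omega = 1 is neutral; omega > 1 plants
    positive selection at the stated strength.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    rng = np.random.default_rng(seed)
    genes: dict[str, CodingGene] = {}
    cohorts: dict[str, list[MutationRecord]] = {}
    for g in range(n_genes):
        name = f"G{g + 1:04d}"
        gene = random_coding_gene(gene_length, rng, gene=name)
        genes[name] = gene
        snvs = enumerate_snvs(gene)
        usable = snvs[snvs["consequence"].isin(["synonymous", "missense", "nonsense"])]
        w = signature.channel_probs[usable["channel"].to_numpy()].copy()
        nonsyn = usable["consequence"].isin(["missense", "nonsense"]).to_numpy()
        w[nonsyn] *= omega
        if w.sum() <= 0:
            raise ValueError("signature assigns no mass to this gene's changes")
        w /= w.sum()
        recs: list[MutationRecord] = []
        if mutations_per_gene > 0:
            picks = rng.choice(len(usable), size=mutations_per_gene, replace=True, p=w)
            for i, k in enumerate(picks):
                row = usable.iloc[int(k)]
                consequence, prot = classify_consequence(
                    gene, int(row["cds_position"]), row["ref_base"], row["alt_base"]
                )
                recs.append(
                    MutationRecord(
                        gene=name,
                        sample_id=f"{name}_S{i + 1:04d}",
                        tissue="synthetic",
                        cds_position=int(row["cds_position"]),
                        ref_base=row["ref_base"],
                        alt_base=row["alt_base"],
                        protein_change=prot,
                        consequence=consequence,
                    )
                )
        cohorts[name] = recs
    truth = GroundTruth(
        kind="dnds_cohort",
        params={
            "n_genes": n_genes,
            "gene_length": gene_length,
            "omega": omega,
            "mutations_per_gene": mutations_per_gene,
            "seed": seed,
        },
    )
    return genes, cohorts, truth


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


def make_ensemble(
    structure: ProteinStructure,
    per_residue_sigma: np.ndarray,
    n_frames: int,
    frame_dt: float = 0.1,
    seed: int = 0,
):
    """Frames = base coordinates + isotropic Gaussian jitter per residue.

    Each residue's atoms are displaced by N(0, sigma_i) independently per
    frame and axis, then a random global rigid transform is applied per frame
    so downstream superposition is genuinely exercised.  Noise is
    frame-independent (no autocorrelation).
    """
    from .ensembles import ConformationEnsemble

    sigma = np.asarray(per_residue_sigma, dtype=float)
    if sigma.shape != (structure.n_residues,):
        raise ValueError("need one sigma per residue")
    if (sigma < 0).any():
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    atom_sigma = sigma[structure.atom_res_index]
    frames = np.empty((n_frames, structure.n_atoms, 3))
    for f in range(n_frames):
        jitter = rng.normal(size=(structure.n_atoms, 3)) * atom_sigma[:, None]
        coords = structure.coords + jitter
        rot = Rotation.random(rng=rng).as_matrix()
        trans = rng.uniform(-20.0, 20.0, size=3)
        frames[f] = coords @ rot.T + trans
    times = np.arange(n_frames) * frame_dt
    ens = ConformationEnsemble(structure=structure, frames=frames, times=times)
    truth = GroundTruth(
        kind="ensemble",
        params={
            "per_residue_sigma": sigma.tolist(),
            "n_frames": n_frames,
            "frame_dt": frame_dt,
            "seed": seed,
        },
    )
    return ens, truth


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


def make_survival_cohort(
    n_per_arm: int = 100,
    hazard_ratio: float = 1.0,
    censor_rate: float = 0.0,
    seed: int = 0,
    baseline_hazard: float = 1.0 / 40.0,
) -> tuple[SurvivalCohort, GroundTruth]:
    """Two-arm exponential survival cohort.

    Arm A event hazard = ``baseline_hazard`` per month (default median ~28
    months); arm B hazard = hazard_ratio x arm A.  Censoring times are
    exponential with hazard censor_rate x baseline_hazard (0 = none).
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for arm, hazard in (("A", baseline_hazard), ("B", hazard_ratio * baseline_hazard)):
        event_t = rng.exponential(1.0 / hazard, size=n_per_arm)
        if censor_rate > 0:
            censor_t = rng.exponential(
                1.0 / (censor_rate * baseline_hazard), size=n_per_arm
            )
        else:
            censor_t = np.full(n_per_arm, np.inf)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        for i in range(n_per_arm):
            rows.append(
                {
                    "patient_id": f"{arm}{i + 1:04d}",
                    "time": float(time[i]),
                    "event": int(event[i]),
                    "group": arm,
                }
            )
    cohort = SurvivalCohort(pd.DataFrame(rows))
    truth = GroundTruth(
        kind="survival_cohort",
        params={
            "n_per_arm": n_per_arm,
            "hazard_ratio": hazard_ratio,
            "censor_rate": censor_rate,
            "baseline_hazard": baseline_hazard,
            "seed": seed,
        },
    )
    return cohort, truth
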