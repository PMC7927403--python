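"""Receptor structure I/O and the Val84-Leu249 activation descriptor.

GPCR activation opens the intracellular face of the helical bundle; for the
adenosine A2A receptor the outward shift of Val84 (TM3), referenced to the
comparatively static Leu249 (TM6), separates active- from inactive-state
crystal structures by roughly 1.6 A. This module reads C-alpha coordinates
from PDB files, superposes structure ensembles (Kabsch), quantifies
per-residue positional stability across the aligned ensemble, measures the
inter-residue descriptor, and selects the docking template with the extreme
descriptor value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

STATES = ("active", "inactive", "unknown")

#: Default author-numbering window for the A2A receptor; coordinates of fused
#: crystallisation partners (BRIL, lysozyme) carry residue numbers outside it.
DEFAULT_RESIDUE_RANGE = (1, 320)


@dataclass(frozen=True)
class ResiduePairDescriptor:
    """A C-alpha inter-residue distance descriptor (default Val84-Leu249)."""

    residue_a: int = 84
    residue_b: int = 249
    atom: str = "CA"

    def __post_init__(self):
        if self.residue_a == self.residue_b:
            raise ValueError("descriptor residues must differ")


@dataclass
class StructureModel:
    """C-alpha trace of one receptor chain with an activity-state label."""

    structure_id: str
    chain_id: str
    ca_coords: dict[int, np.ndarray]
    state: str = "unknown"

    def __post_init__(self):
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}, got {self.state!r}")
        clean: dict[int, np.ndarray] = {}
        for res, xyz in self.ca_coords.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ValueError(f"residue {res}: coordinate must be a finite 3-vector")
            if res <= 0:
                raise ValueError(f"residue numbers must be positive, got {res}")
            clean[int(res)] = arr
        self.ca_coords = clean

    @property
    def residues(self) -> list[int]:
        return sorted(self.ca_coords)

    def coords(self, residues: Sequence[int]) -> np.ndarray:
        return np.array([self.ca_coords[r] for r in residues], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with coordinates mapped to R @ x + t."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        moved = {r: rotation @ xyz + translation for r, xyz in self.ca_coords.items()}
        return replace(self, ca_coords=moved)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # A
    rmsd: float  # post-fit C-alpha RMSD, A
    n_atoms_used: int


@dataclass
class EnsembleAlignment:
    members: list[StructureModel]
    shared_residues: list[int]
    mean_positions: dict[int, np.ndarray]


@dataclass
class ResidueStability:
    residue: int
    rmsd_from_mean: float  # A


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_models(path, chain_id, residue_range):
    """Parse ATOM records; returns (models, chains_seen).

    models is a list of dicts residue -> (occupancy, xyz) after altloc
    resolution (highest occupancy wins, ties to first encountered).
    """
    lo, hi = residue_range if residue_range is not None else (None, None)
    models: list[dict[int, tuple[float, np.ndarray]]] = []
    current: dict[int, tuple[float, np.ndarray]] = {}
    chains_seen: set[str] = set()
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec.startswith("MODEL"):
                if in_model and current:
                    models.append(current)
                current = {}
                in_model = True
                continue
            if rec.startswith("ENDMDL"):
                models.append(current)
                current = {}
                in_model = False
                continue
            if not rec.startswith("ATOM"):
                continue  # HETATM, waters, everything else ignored
            atom_name = line[12:16].strip()
            if atom_name != "CA":
                continue
            chain = line[21]
            chains_seen.add(chain)
            if chain != chain_id:
                continue
            icode = line[26].strip()
            if icode:
                raise ValueError(
                    f"{path}, line {lineno}: insertion codes are not supported "
                    f"(residue {line[22:26].strip()}{icode})"
                )
            try:
                resnum = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: malformed coordinate/residue field") from exc
            occ_field = line[54:60].strip()
            occ = float(occ_field) if occ_field else 1.0
            if lo is not None and not (lo <= resnum <= hi):
                continue
            prev = current.get(resnum)
            if prev is None or occ > prev[0]:  # ties keep first encountered
                current[resnum] = (occ, np.array([x, y, z]))
    if current:
        models.append(current)
    return models, chains_seen


def read_structure(
    path,
    chain_id: str = "A",
    residue_range: tuple[int, int] | None = DEFAULT_RESIDUE_RANGE,
    state: str = "unknown",
    structure_id: str | None = None,
) -> StructureModel:
    """Read the C-alpha trace of one chain from a PDB file (first model)."""
    frames = read_frames(path, chain_id, residue_range, state, structure_id)
    return frames[0]


def read_frames(
    path,
    chain_id: str = "A",
    residue_range: tuple[int, int] | None = DEFAULT_RESIDUE_RANGE,
    state: str = "unknown",
    structure_id: str | None = None,
) -> list[StructureModel]:
    """Read every MODEL of a (possibly multi-model) PDB file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sid = structure_id if structure_id is not None else path.stem
    models, chains_seen = _parse_models(path, chain_id, residue_range)
    models = [m for m in models if m]
    if not models:
        if chains_seen and chain_id not in chains_seen:
            raise ValueError(
                f"{path}: chain {chain_id!r} not found; available chains: "
                + ", ".join(sorted(chains_seen))
            )
        raise ValueError(f"{path}: no C-alpha ATOM records parsed")
    out = []
    for i, m in enumerate(models):
        coords = {r: xyz for r, (occ, xyz) in m.items()}
        out.append(StructureModel(sid if len(models) == 1 else f"{sid}#{i}", chain_id, coords, state))
    return out


def write_pdb(models: StructureModel | Sequence[StructureModel], path) -> None:
    """Write C-alpha-only models as standard PDB text (MODEL/ENDMDL if > 1)."""
    if isinstance(models, StructureModel):
        models = [models]
    lines = []
    multi = len(models) > 1
    for i, model in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        serial = 1
        for res in model.residues:
            x, y, z = model.ca_coords[res]
            lines.append(
                f"ATOM  {serial:5d}  CA  ALA {model.chain_id}{res:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
                f" C  "
            )
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Descriptor and superposition
# ---------------------------------------------------------------------------

def pair_distance(model: StructureModel, pair: ResiduePairDescriptor = ResiduePairDescriptor()) -> float:
    """Euclidean C-alpha distance (A) between the descriptor residues."""
    for res in (pair.residue_a, pair.residue_b):
        if res not in model.ca_coords:
            raise ValueError(f"{model.structure_id}: residue {res} absent from model")
    return float(np.linalg.norm(model.ca_coords[pair.residue_a] - model.ca_coords[pair.residue_b]))


def _shared_residues(models: Iterable[StructureModel]) -> list[int]:
    sets = [set(m.ca_coords) for m in models]
    shared = set.intersection(*sets) if sets else set()
    return sorted(shared)


def superpose(mobile: StructureModel, reference: StructureModel) -> SuperpositionResult:
    """Least-squares rigid-body (Kabsch) fit of mobile onto reference.

    The fit is over the shared C-alpha atoms; apply the result with
    ``mobile.transformed(res.rotation, res.translation)``.
    """
    shared = _shared_residues([mobile, reference])
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared residues for superposition, got {len(shared)}")
    mob = mobile.coords(shared)
    ref = reference.coords(shared)
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    a = ref - ref_c
    b = mob - mob_c
    if np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) atom set; rotation is underdetermined")
    rot, _ = Rotation.align_vectors(a, b)
    rmat = rot.as_matrix()
    translation = ref_c - rmat @ mob_c
    # recompute the residual from the transformed coordinates; scipy's rssd
    # loses ~1e-7 A to cancellation near a perfect fit
    moved = mob @ rmat.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rmat, translation=translation, rmsd=rmsd, n_atoms_used=len(shared))


def apply_superposition(mobile: StructureModel, result: SuperpositionResult) -> StructureModel:
    return mobile.transformed(result.rotation, result.translation)


def align_ensemble(models: Sequence[StructureModel], n_iterations: int = 2) -> EnsembleAlignment:
    """Superpose all models into a common frame.

    Pass 1 fits everything onto member 0; each refinement pass re-fits onto
    the running mean structure, which removes the arbitrary choice of
    reference up to a global rigid motion.
    """
    if len(models) < 2:
        raise ValueError("ensemble alignment needs >= 2 models")
    shared = _shared_residues(models)
    if len(shared) < 3:
        raise ValueError("ensemble members share fewer than 3 residues")

    def _mean_model(members):
        stack = np.stack([m.coords(shared) for m in members])
        mean = stack.mean(axis=0)
        return StructureModel("__mean__", members[0].chain_id, dict(zip(shared, mean)))

    aligned = [models[0]] + [
        apply_superposition(m, superpose(m, models[0])) for m in models[1:]
    ]
    for _ in range(max(0, n_iterations - 1)):
        target = _mean_model(aligned)
        aligned = [apply_superposition(m, superpose(m, target)) for m in aligned]
    mean = _mean_model(aligned)
    return EnsembleAlignment(
        members=aligned,
        shared_residues=shared,
        mean_positions={r: mean.ca_coords[r] for r in shared},
    )


def residue_stability(alignment: EnsembleAlignment, residue: int) -> ResidueStability:
    """RMSD of one residue's aligned positions about their ensemble centroid."""
    if residue not in alignment.shared_residues:
        raise ValueError(f"residue {residue} is not shared by all ensemble members")
    pos = np.stack([m.ca_coords[residue] for m in alignment.members])
    mean = alignment.mean_positions[residue]
    rmsd = float(np.sqrt(np.mean(np.sum((pos - mean) ** 2, axis=1))))
    return ResidueStability(residue=residue, rmsd_from_mean=rmsd)


def distance_table(models: Sequence[StructureModel], pair: ResiduePairDescriptor = ResiduePairDescriptor()) -> pd.DataFrame:
    """Per-structure descriptor table (structures lacking a residue are skipped)."""
    rows = []
    for m in models:
        try:
            d = pair_distance(m, pair)
        except ValueError:
            continue
        rows.append(
            {
                "structure_id": m.structure_id,
                "state": m.state,
                "residue_a": pair.residue_a,
                "residue_b": pair.residue_b,
                "distance_A": d,
            }
        )
    return pd.DataFrame(rows, columns=["structure_id", "state", "residue_a", "residue_b", "distance_A"])


def select_template(
    models: Sequence[StructureModel],
    pair: ResiduePairDescriptor = ResiduePairDescriptor(),
    mode: str = "max",
) -> tuple[str, pd.DataFrame]:
    """Pick the structure with the extreme descriptor value.

    mode="max" is the agonist-template rule: the widest Val84-Leu249 opening
    leaves room for the agonist-induced TM3 shift. Ties break to the
    lexicographically smallest structure_id.
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    table = distance_table(models, pair)
    if table.empty:
        raise ValueError("no model contains both descriptor residues")
    best = table.sort_values(
        ["distance_A", "structure_id"], ascending=[mode == "min", True], kind="mergesort"
    ).iloc[0]
    return str(best["structure_id"]), table
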