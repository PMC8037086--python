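"""Multi-model structural-ensemble statistics.

Reads an NMR-style multi-model PDB into a shared atom roster plus a
(models × atoms × 3) coordinate array, superposes models by least-squares
rigid-body fitting (Kabsch), and reports the ensemble precision as the
RMSD of each model from the iteratively converged mean structure over a
residue range and atom selection — the statistic structure tables quote
as "RMSD from mean structure".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C")
BACKBONE_ATOMS_WITH_O = ("N", "CA", "C", "O")


@dataclass
class Ensemble:
    """Multi-model coordinates on an identical, identically ordered atom roster.

    ``atoms`` columns: chain, residue, res_name, atom_name, element.
    ``coords`` has shape (n_models, n_atoms, 3), Å.
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_models, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords and atom roster disagree on atom count")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class AtomSelection:
    """Atom subset for superposition/RMSD: backbone (N, CA, C) or all heavy atoms,
    over an inclusive residue range."""

    mode: str = "backbone"
    residue_range: tuple[int, int] | None = None
    include_carbonyl_O: bool = False

    def mask(self, atoms: pd.DataFrame) -> np.ndarray:
        if self.mode == "backbone":
            names = BACKBONE_ATOMS_WITH_O if self.include_carbonyl_O else BACKBONE_ATOMS
            m = atoms["atom_name"].isin(names).to_numpy()
        elif self.mode == "heavy":
            m = (atoms["element"] != "H").to_numpy()
        else:
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.residue_range is not None:
            lo, hi = self.residue_range
            m &= (atoms["residue"] >= lo).to_numpy() & (atoms["residue"] <= hi).to_numpy()
        return m


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model PDB (MODEL/ENDMDL records) into an Ensemble.

    Alternate locations are resolved to the highest-occupancy conformer;
    atoms absent from any model are dropped from all models (logged).
    Fewer than two models is a validation error.
    """
    st = gemmi.read_structure(str(path))
    if len(st) < 2:
        raise ValueError(f"{path}: ensemble statistics require at least 2 models, got {len(st)}")
    models = []
    for model in st:
        atoms: dict[tuple, tuple] = {}
        for chain in model:
            for residue in chain:
                for atom in residue:
                    key = (chain.name, residue.seqid.num, atom.name)
                    entry = (
                        atom.occ,
                        (atom.pos.x, atom.pos.y, atom.pos.z),
                        residue.name,
                        atom.element.name,
                    )
                    if key not in atoms or atom.occ > atoms[key][0]:
                        atoms[key] = entry
        models.append(atoms)
    common = set(models[0])
    for m in models[1:]:
        common &= set(m)
    dropped = set().union(*(set(m) for m in models)) - common
    if dropped:
        logger.info("dropping %d atoms absent from some models: %s", len(dropped),
                    sorted(dropped)[:5])
    roster_keys = [k for k in models[0] if k in common]  # model-1 order
    first = models[0]
    atoms_df = pd.DataFrame(
        {
            "chain": [k[0] for k in roster_keys],
            "residue": [k[1] for k in roster_keys],
            "res_name": [first[k][2] for k in roster_keys],
            "atom_name": [k[2] for k in roster_keys],
            "element": [first[k][3] for k in roster_keys],
        }
    )
    coords = np.array([[m[k][1] for k in roster_keys] for m in models])
    return Ensemble(atoms_df, coords)


def write_ensemble(ens: Ensemble, path: str | Path) -> None:
    """Write an Ensemble as a multi-model PDB file."""
    st = gemmi.Structure()
    st.name = "ensemble"
    for i in range(ens.n_models):
        model = gemmi.Model(i + 1)
        for chain_name in ens.atoms["chain"].unique():
            chain = gemmi.Chain(str(chain_name))
            sel = ens.atoms[ens.atoms["chain"] == chain_name]
            for res_id in sel["residue"].unique():
                rsel = sel[sel["residue"] == res_id]
                residue = gemmi.Residue()
                residue.name = str(rsel["res_name"].iloc[0])
                residue.seqid = gemmi.SeqId(int(res_id), " ")
                for idx, row in rsel.iterrows():
                    atom = gemmi.Atom()
                    atom.name = str(row["atom_name"])
                    atom.element = gemmi.Element(str(row["element"]))
                    x, y, z = ens.coords[i, idx]
                    atom.pos = gemmi.Position(float(x), float(y), float(z))
                    residue.add_atom(atom)
                chain.add_residue(residue)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass(frozen=True)
class Transform:
    """Proper rigid-body transform x ↦ R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[Transform, float]:
    """Least-squares rigid-body superposition (Kabsch) of paired coordinates.

    Returns the proper rotation (det +1) and translation minimising the
    RMSD of ``mobile`` onto ``reference``, and that minimum RMSD.  Needs at
    least 3 non-collinear atoms.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    P, Q = mobile - cm, reference - cr
    if np.linalg.matrix_rank(Q, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mobile) - reference) ** 2, axis=1))))
    return transform, rmsd


@dataclass(frozen=True)
class RmsdReport:
    selection: AtomSelection
    per_model_rmsd: np.ndarray
    mean: float
    sd: float
    n_atoms: int
    n_iterations: int


def rmsd_from_mean(
    ens: Ensemble,
    selection: AtomSelection,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> RmsdReport:
    """Per-model RMSD to the converged mean structure over a selection.

    Iterates: superpose every model on the current mean (model 1 seeds the
    first round), recompute the mean, until the mean moves ≤ ``tol`` Å.
    Reports per-model RMSDs to the converged mean plus their mean ± sd —
    the ensemble-precision statistic of NMR structure tables.
    """
    mask = selection.mask(ens.atoms)
    n_sel = int(mask.sum())
    if n_sel < 3:
        raise ValueError("selection must contain at least 3 atoms")
    X = ens.coords[:, mask, :].copy()
    reference = X[0]
    for iteration in range(1, max_iter + 1):
        for i in range(X.shape[0]):
            transform, _ = superpose(X[i], reference)
            X[i] = transform.apply(X[i])
        new_mean = X.mean(axis=0)
        shift = float(np.max(np.linalg.norm(new_mean - reference, axis=1))) if iteration > 1 else math.inf
        reference = new_mean
        if shift <= tol:
            break
    else:
        raise RuntimeError(f"mean structure did not converge in {max_iter} iterations")
    per_model = np.sqrt(np.mean(np.sum((X - reference) ** 2, axis=2), axis=1))
    return RmsdReport(
        selection=selection,
        per_model_rmsd=per_model,
        mean=float(per_model.mean()),
        sd=float(per_model.std(ddof=1)),
        n_atoms=n_sel,
        n_iterations=iteration,
    )


__all__ = [
    "Ensemble",
    "AtomSelection",
    "Transform",
    "read_ensemble",
    "write_ensemble",
    "superpose",
    "rmsd_from_mean",
    "RmsdReport",
    "BACKBONE_ATOMS",
    "BACKBONE_ATOMS_WITH_O",
]
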