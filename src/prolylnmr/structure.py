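"""Ensemble superposition and backbone RMSD for multi-model NMR structures.

Implements least-squares (Kabsch) superposition and two ensemble-precision
conventions: mean RMSD of each model to the iteratively refined mean
coordinates ("to_mean", the default), and the mean over all pairwise
superpositions ("pairwise").  Backbone is N, CA, C; selections are given as
inclusive residue-number ranges, with an optional numbering offset for
deposited files whose numbering differs from the native sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StructureEnsemble",
    "ResidueSelection",
    "BACKBONE_ATOMS",
    "kabsch_superpose",
    "select_atoms",
    "ensemble_backbone_rmsd",
    "read_pdb_ensemble",
    "parse_ranges",
]

BACKBONE_ATOMS = ("N", "CA", "C")


@dataclass
class StructureEnsemble:
    """Multi-model atom records sharing one atom-identity list.

    ``models``: list of models, each a list of atom dicts with keys
    name, resnum, chain, element, coord (x, y, z in Angstrom).
    """

    models: list[list[dict]]

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("empty ensemble")
        ids0 = [(a["chain"], a["resnum"], a["name"]) for a in self.models[0]]
        for i, m in enumerate(self.models[1:], start=2):
            ids = [(a["chain"], a["resnum"], a["name"]) for a in m]
            if ids != ids0:
                first = next(((x, y) for x, y in zip(ids0, ids) if x != y),
                             (len(ids0), len(ids)))
                raise ValueError(f"model {i} atom list differs from model 1: first mismatch {first}")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def coords(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate array."""
        arr = np.array([[a["coord"] for a in m] for m in self.models], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite coordinates in ensemble")
        return arr

    def residue_numbers(self) -> list[int]:
        return sorted({a["resnum"] for a in self.models[0]})


@dataclass(frozen=True)
class ResidueSelection:
    """Inclusive residue-number ranges plus the atom-name set to keep."""

    ranges: tuple[tuple[int, int], ...]
    atom_names: tuple[str, ...] = BACKBONE_ATOMS
    offset: int = 0  # added to range bounds before matching file numbering

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("empty range list")
        prev_end = None
        for lo, hi in self.ranges:
            if lo > hi:
                raise ValueError(f"bad range {lo}-{hi}")
            if prev_end is not None and lo <= prev_end:
                raise ValueError("ranges must be ordered and non-overlapping")
            prev_end = hi

    def contains(self, resnum: int) -> bool:
        return any(lo + self.offset <= resnum <= hi + self.offset for lo, hi in self.ranges)


def parse_ranges(text: str) -> tuple[tuple[int, int], ...]:
    """Parse a range string like ``"14-47,56-105"`` into interval tuples."""
    out = []
    for part in text.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-", 1)
            out.append((int(lo), int(hi)))
        else:
            out.append((int(part), int(part)))
    return tuple(out)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns (rotation matrix with det +1, translation vector, RMSD in the
    coordinate units) such that ``mobile @ R.T + t`` best matches
    ``reference`` in the least-squares sense.
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need >= 3 atoms for superposition")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    # degenerate spread: collinear/coincident points give a rank-<2 covariance
    if S[1] <= 1e-10 * max(S[0], 1e-300):
        raise ValueError("degenerate geometry: atoms are collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    diff = X0 @ R.T - Y0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def select_atoms(ensemble: StructureEnsemble, selection: ResidueSelection) -> StructureEnsemble:
    """Filter every model by residue ranges and atom names, order preserved."""
    keep = [i for i, a in enumerate(ensemble.models[0])
            if selection.contains(a["resnum"]) and a["name"] in selection.atom_names]
    if not keep:
        avail = ensemble.residue_numbers()
        raise ValueError(
            f"selection matches zero atoms; available residues {avail[0]}..{avail[-1]} "
            f"({len(avail)} residues)")
    return StructureEnsemble(models=[[m[i] for i in keep] for m in ensemble.models])


def ensemble_backbone_rmsd(ensemble: StructureEnsemble,
                           selection: ResidueSelection | None = None,
                           mode: str = "to_mean",
                           n_mean_iterations: int = 2) -> float:
    """Ensemble precision (Angstrom) over the selected backbone atoms.

    mode "to_mean": superpose all models onto the coordinate mean, refine
    the mean over ``n_mean_iterations`` rounds, and report the mean RMSD of
    models to the mean.  mode "pairwise": mean RMSD over all model pairs
    after pairwise superposition.
    """
    if ensemble.n_models < 2:
        raise ValueError("need >= 2 models")
    if selection is not None:
        ensemble = select_atoms(ensemble, selection)
    coords = ensemble.coords()
    if mode == "pairwise":
        vals = [kabsch_superpose(coords[i], coords[j])[2]
                for i in range(len(coords)) for j in range(i + 1, len(coords))]
        return float(np.mean(vals))
    if mode != "to_mean":
        raise ValueError(f"unknown mode {mode!r}")
    aligned = coords.copy()
    mean = aligned[0]
    for _ in range(1 + n_mean_iterations):
        for k in range(len(aligned)):
            R, t, _ = kabsch_superpose(aligned[k], mean)
            aligned[k] = aligned[k] @ R.T + t
        mean = aligned.mean(axis=0)
    rmsds = [np.sqrt(((m - mean) ** 2).sum() / m.shape[0]) for m in aligned]
    return float(np.mean(rmsds))


def read_pdb_ensemble(path: str, chain: str | None = None) -> StructureEnsemble:
    """Read a multi-model PDB file (MODEL/ENDMDL records) into an ensemble."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        struct = parser.get_structure("ens", path)
    models = []
    for model in struct:
        atoms = []
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                if res.id[0] != " ":  # skip heteroatoms/waters
                    continue
                for atom in res:
                    atoms.append({
                        "name": atom.get_name(), "resnum": res.id[1],
                        "chain": ch.id, "element": atom.element or atom.get_name()[0],
                        "coord": tuple(map(float, atom.coord)),
                    })
        models.append(atoms)
    if not models:
        raise ValueError(f"no models found in {path}")
    return StructureEnsemble(models=models)
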