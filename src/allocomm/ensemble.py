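"""Conformational ensembles: containers, readers, superposition and fluctuations.

An ensemble is a stack of F coordinate frames (Å) over a fixed set of A atoms,
partitioned into residues.  Every residue carries exactly one Cα atom; all
downstream communication statistics are residue-level and most of them are
computed on the Cα coordinates.  Frames are equally weighted throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    DegenerateEnsembleError,
    FormatError,
    InvalidPairError,
    SelectionError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueRecord",
    "ConformationalEnsemble",
    "FluctuationProfile",
    "load_ensemble",
    "superpose",
    "kabsch_rotation",
    "ca_distance_series",
    "rmsf",
    "write_pdb",
    "write_fluctuation_tsv",
]


@dataclass(frozen=True)
class ResidueRecord:
    """One residue of the analysed chain.

    ``index`` is the contiguous 0-based internal index used by every matrix in
    the package; ``seq_id`` is the author residue number used in reports.
    ``atoms`` lists the residue's atom indices into the coordinate array and is
    always contiguous and sorted; ``ca_atom`` is one of them.
    """

    index: int
    seq_id: int
    name: str
    chain_id: str
    ca_atom: int
    atoms: tuple[int, ...]
    atom_names: tuple[str, ...]
    elements: tuple[str, ...]

    @property
    def heavy_atoms(self) -> tuple[int, ...]:
        return tuple(a for a, e in zip(self.atoms, self.elements) if e.upper() != "H")

    @property
    def polar_atoms(self) -> tuple[int, ...]:
        """Atoms that can act as hydrogen-bond donors/acceptors (N or O)."""
        return tuple(a for a, e in zip(self.atoms, self.elements) if e.upper() in ("N", "O"))


@dataclass
class ConformationalEnsemble:
    """F frames of 3D coordinates for A atoms plus residue metadata.

    Invariants: ``coords`` has shape (F, A, 3) with finite entries; residue
    internal indices run 0..N-1; every residue has exactly one Cα.
    """

    coords: np.ndarray
    residues: list[ResidueRecord]
    frame_times: np.ndarray | None = None
    source: str = ""
    superposed: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError(f"coords must be (F, A, 3); got {self.coords.shape}")
        if not np.isfinite(self.coords).all():
            raise FormatError("non-finite coordinates in ensemble")
        for k, r in enumerate(self.residues):
            if r.index != k:
                raise FormatError(f"residue internal indices not contiguous at {k}")

    # -- basic views -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def seq_ids(self) -> np.ndarray:
        return np.array([r.seq_id for r in self.residues], dtype=int)

    @property
    def ca_indices(self) -> np.ndarray:
        return np.array([r.ca_atom for r in self.residues], dtype=int)

    @property
    def ca_coords(self) -> np.ndarray:
        """Cα coordinates, shape (F, N, 3)."""
        return self.coords[:, self.ca_indices, :]

    @property
    def is_ca_only(self) -> bool:
        return all(len(r.atoms) == 1 for r in self.residues)

    def atom_selection(self, selection: str) -> np.ndarray:
        """Resolve a named selection ('ca', 'backbone', 'heavy', 'all') to atom indices."""
        sel = selection.lower()
        if sel == "ca":
            idx = self.ca_indices
        elif sel == "backbone":
            bb = {"N", "CA", "C", "O"}
            idx = np.array(
                [a for r in self.residues for a, nm in zip(r.atoms, r.atom_names) if nm in bb],
                dtype=int,
            )
        elif sel == "heavy":
            idx = np.array([a for r in self.residues for a in r.heavy_atoms], dtype=int)
        elif sel == "all":
            idx = np.arange(self.n_atoms)
        else:
            raise SelectionError(f"unknown selection {selection!r}")
        if idx.size == 0:
            raise SelectionError(f"selection {selection!r} matched no atoms")
        return idx

    def mean_structure(self) -> np.ndarray:
        """Frame-averaged coordinates, shape (A, 3)."""
        return self.coords.mean(axis=0)


@dataclass
class FluctuationProfile:
    """Per-residue root-mean-square fluctuation (Å) about the ensemble mean."""

    values: np.ndarray
    seq_ids: np.ndarray
    selection: str = "ca"
    reference: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("RMSF values must be non-negative")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _residues_from_universe(u, chain: str | None) -> list[ResidueRecord]:
    records: list[ResidueRecord] = []
    k = 0
    for res in u.residues:
        chain_id = getattr(res.atoms, "chainIDs", None)
        cid = str(chain_id[0]) if chain_id is not None and len(chain_id) else str(
            getattr(res, "segid", "") or ""
        )
        if chain is not None and cid != chain:
            continue
        names = [str(n) for n in res.atoms.names]
        if "CA" not in names:
            logger.warning(
                "residue %s%s has no CA atom; excluded from analysis", res.resname, res.resid
            )
            continue
        try:
            elements = [str(e) for e in res.atoms.elements]
        except Exception:  # element guessing unavailable: fall back to first name letter
            elements = [n[0] for n in names]
        atoms = tuple(int(a) for a in res.atoms.indices)
        records.append(
            ResidueRecord(
                index=k,
                seq_id=int(res.resid),
                name=str(res.resname),
                chain_id=cid,
                ca_atom=atoms[names.index("CA")],
                atoms=atoms,
                atom_names=tuple(names),
                elements=tuple(elements),
            )
        )
        k += 1
    return records


def load_ensemble(
    structure_path,
    trajectory_path=None,
    stride: int = 1,
    frame_range: tuple[int, int] | None = None,
    chain: str | None = None,
) -> ConformationalEnsemble:
    """Read a conformational ensemble.

    Parameters
    ----------
    structure_path
        A PDB file.  If ``trajectory_path`` is None, all MODELs of the PDB form
        the ensemble; otherwise the PDB is the topology/reference.
    trajectory_path
        Optional DCD/XTC/TRR trajectory matching the topology.
    stride
        Keep every ``stride``-th frame (after ``frame_range``).
    frame_range
        Half-open frame interval ``[start, stop)`` applied before striding;
        use it to discard equilibration frames.
    chain
        Restrict the residue table to one chain identifier.  Analysis is
        single-chain; with multi-chain input this argument selects which.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ValueError("stride must be a positive integer")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory_path is None:
            u = mda.Universe(str(structure_path))
        else:
            try:
                u = mda.Universe(str(structure_path), str(trajectory_path))
            except Exception as exc:
                n_top = len(mda.Universe(str(structure_path)).atoms)
                raise FormatError(
                    f"topology {structure_path} ({n_top} atoms) does not match "
                    f"trajectory {trajectory_path}: {exc}"
                ) from exc

    residues = _residues_from_universe(u, chain)
    if not residues:
        raise FormatError(f"no residues with CA atoms found in {structure_path}")

    start, stop = (0, len(u.trajectory)) if frame_range is None else frame_range
    frames, times = [], []
    for k, ts in enumerate(u.trajectory):
        if k < start or k >= stop:
            continue
        if (k - start) % stride:
            continue
        frames.append(ts.positions.astype(float).copy())
        times.append(float(getattr(ts, "time", k)))
    if len(frames) < 2:
        raise DegenerateEnsembleError(
            f"ensemble has {len(frames)} frame(s); at least 2 are required"
        )
    src = str(structure_path) if trajectory_path is None else f"{structure_path}+{trajectory_path}"
    return ConformationalEnsemble(
        coords=np.stack(frames),
        residues=residues,
        frame_times=np.asarray(times),
        source=src,
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares rotation matrix mapping centred ``mobile`` onto centred ``target``."""
    h = mobile.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def superpose(
    ensemble: ConformationalEnsemble,
    atom_selection: str = "ca",
    max_iter: int = 500,
    tol: float = 1e-10,
) -> ConformationalEnsemble:
    """Remove rigid-body motion by least-squares fitting every frame.

    Each frame is fitted (rotation + translation computed on ``atom_selection``,
    applied to all atoms) to the iteratively refined mean structure until the
    mean stops moving (so the operation is idempotent), at most ``max_iter``
    rounds.
    """
    sel = ensemble.atom_selection(atom_selection)
    coords = ensemble.coords.copy()
    prev_ref = None
    for _ in range(max_iter):
        ref = coords[:, sel, :].mean(axis=0)
        if prev_ref is not None and np.abs(ref - prev_ref).max() < tol:
            break
        prev_ref = ref
        ref_c = ref - ref.mean(axis=0)
        for f in range(coords.shape[0]):
            sub = coords[f, sel, :]
            cen = sub.mean(axis=0)
            rot = kabsch_rotation(sub - cen, ref_c)
            coords[f] = (coords[f] - cen) @ rot + ref.mean(axis=0)
    return replace(ensemble, coords=coords, superposed=True)


# ---------------------------------------------------------------------------
# residue-level statistics
# ---------------------------------------------------------------------------

def ca_distance_series(ensemble: ConformationalEnsemble, i: int, j: int) -> np.ndarray:
    """Time series of Cα(i)–Cα(j) Euclidean distances (Å), length F."""
    if i == j:
        raise InvalidPairError(f"distance series requires two distinct residues (got {i}, {j})")
    ca = ensemble.ca_coords
    return np.linalg.norm(ca[:, i, :] - ca[:, j, :], axis=1)


def rmsf(ensemble: ConformationalEnsemble, atom_selection: str = "ca") -> FluctuationProfile:
    """Per-residue RMSF about the ensemble mean, averaged over selected atoms.

    The per-atom RMSF is sqrt(mean over frames of the squared displacement from
    the mean position); residue values average the per-atom RMSF over the
    residue's atoms inside the selection.
    """
    if not ensemble.superposed:
        logger.warning("rmsf called on a non-superposed ensemble; values include rigid-body motion")
    sel = set(ensemble.atom_selection(atom_selection).tolist())
    mean = ensemble.mean_structure()
    per_atom = np.sqrt(((ensemble.coords - mean) ** 2).sum(axis=2).mean(axis=0))
    values = np.empty(ensemble.n_residues)
    for r in ensemble.residues:
        atoms = [a for a in r.atoms if a in sel] or [r.ca_atom]
        values[r.index] = per_atom[atoms].mean()
    return FluctuationProfile(
        values=values, seq_ids=ensemble.seq_ids, selection=atom_selection, reference=mean
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_pdb(ensemble: ConformationalEnsemble, path, frames: slice | None = None) -> None:
    """Write the ensemble as a multi-model PDB (fixed-width, element column set)."""
    frames = frames or slice(None)
    idx = range(*frames.indices(ensemble.n_frames))
    with open(path, "w") as fh:
        for model_no, f in enumerate(idx, start=1):
            fh.write(f"MODEL     {model_no:4d}\n")
            serial = 1
            for r in ensemble.residues:
                for a, nm, el in zip(r.atoms, r.atom_names, r.elements):
                    x, y, z = ensemble.coords[f, a]
                    name = nm if len(nm) == 4 else f" {nm:<3s}"
                    fh.write(
                        f"ATOM  {serial:5d} {name}{r.name:>4s} {r.chain_id or 'A'}"
                        f"{r.seq_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                        f"          {el.upper():>2s}\n"
                    )
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_mean_structure(ensemble: ConformationalEnsemble, path) -> None:
    """Write the frame-averaged structure as a single-model PDB."""
    mean = ConformationalEnsemble(
        coords=ensemble.mean_structure()[None, :, :].repeat(2, axis=0),
        residues=ensemble.residues,
        source=f"mean({ensemble.source})",
    )
    write_pdb(mean, path, frames=slice(0, 1))


def write_fluctuation_tsv(profile: FluctuationProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-residue RMSF (A) about the ensemble mean; selection=%s\n" % profile.selection)
        fh.write("residue\trmsf\n")
        for sid, v in zip(profile.seq_ids, profile.values):
            fh.write(f"{sid}\t{v:.6f}\n")
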