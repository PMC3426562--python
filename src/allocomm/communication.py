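"""Commute-time communication analysis and pathway growth.

The commute time (CT) of a residue pair is the variance, over the ensemble,
of their Cα–Cα distance: the smaller the variance, the more efficiently the
pair communicates.  Residue pairs additionally interacting through persistent
non-bonded contacts form the scaffold along which communication pathways
(CPs) are grown: ordered chains in which consecutive members are persistent
contacts, no consecutive members are sequence-adjacent, and every member pair
has CT at or below the calibrated threshold ε.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import ConformationalEnsemble
from .exceptions import CalibrationError, DegenerateEnsembleError

logger = logging.getLogger(__name__)

__all__ = [
    "CommuteTimeMatrix",
    "ContactMap",
    "CommunicationPathway",
    "PathwaySet",
    "PathwayStats",
    "compute_commute_times",
    "calibrate_threshold",
    "detect_hbonds",
    "detect_contacts",
    "neighbors",
    "grow_pathways",
    "grow_all_pathways",
    "pathway_stats",
]

_FRAME_CHUNK = 500  # frames per block when streaming distance statistics


@dataclass
class CommuteTimeMatrix:
    """Symmetric N×N matrix of inter-residue Cα distance variances (Å²)."""

    ct: np.ndarray
    n_frames: int
    seq_ids: np.ndarray
    epsilon: float | None = None
    target_fraction: float | None = None

    @property
    def n_residues(self) -> int:
        return self.ct.shape[0]

    def fast_fractions(self, epsilon: float | None = None) -> np.ndarray:
        """Per-residue fraction of *other* residues with CT <= epsilon."""
        eps = self.epsilon if epsilon is None else epsilon
        if eps is None:
            raise CalibrationError("epsilon not calibrated; call calibrate_threshold first")
        n = self.n_residues
        fast = (self.ct <= eps)
        np.fill_diagonal(fast, False)
        return fast.sum(axis=1) / (n - 1)


@dataclass
class ContactMap:
    """Per-pair interaction occupancy over frames and the persistent-contact graph.

    A frame counts as interacting for a pair when any inter-residue heavy-atom
    distance is within ``heavy_atom_cutoff`` or any N/O–N/O pair is within the
    hydrogen-bond cutoff; persistence requires occupancy >= ``min_occupancy``
    and a sequence separation of at least 2.
    """

    occupancy: np.ndarray
    persistent: np.ndarray
    seq_ids: np.ndarray
    criteria: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CommunicationPathway:
    """One communication pathway: an ordered chain of residue internal indices."""

    members: tuple[int, ...]
    pairwise_ct: float

    @property
    def start(self) -> int:
        return self.members[0]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PathwaySet:
    """All maximal pathways grown from one start residue."""

    start: int
    paths: list[CommunicationPathway]
    truncated: bool = False

    def __iter__(self):
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)


@dataclass
class PathwayStats:
    """Per-residue communication summary (fast-CT percentage, longest path, path count)."""

    table: pd.DataFrame  # columns: residue, fast_fraction, max_path_length, n_paths, is_hub
    hub_fraction: float

    @property
    def hubs(self) -> list[int]:
        return self.table.loc[self.table.is_hub, "residue"].tolist()


# ---------------------------------------------------------------------------
# commute times
# ---------------------------------------------------------------------------

def _pairwise_ca_distances(ca: np.ndarray) -> np.ndarray:
    diff = ca[:, :, None, :] - ca[:, None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def compute_commute_times(ensemble: ConformationalEnsemble) -> CommuteTimeMatrix:
    """Population variance over frames of every Cα–Cα distance (two-pass)."""
    f = ensemble.n_frames
    if f < 2:
        raise DegenerateEnsembleError(f"variance needs at least 2 frames; got {f}")
    ca = ensemble.ca_coords
    n = ca.shape[1]
    mean = np.zeros((n, n))
    for lo in range(0, f, _FRAME_CHUNK):
        mean += _pairwise_ca_distances(ca[lo:lo + _FRAME_CHUNK]).sum(axis=0)
    mean /= f
    var = np.zeros((n, n))
    for lo in range(0, f, _FRAME_CHUNK):
        d = _pairwise_ca_distances(ca[lo:lo + _FRAME_CHUNK]) - mean
        var += (d**2).sum(axis=0)
    var /= f
    np.fill_diagonal(var, 0.0)
    return CommuteTimeMatrix(ct=var, n_frames=f, seq_ids=ensemble.seq_ids)


def calibrate_threshold(
    ct: CommuteTimeMatrix, target_fraction: float = 0.20
) -> float:
    """Smallest ε at which the best-connected residue reaches the target
    fraction of fast commute times.

    For each residue the candidate ε is the k-th smallest off-diagonal CT of
    its row, k = ceil(target_fraction·(N−1)); the calibrated ε is the minimum
    over residues, which equals an exhaustive scan of the sorted unique CT
    values with ties broken toward the smaller value.
    """
    if not 0.0 < target_fraction <= 1.0:
        raise CalibrationError(f"target_fraction must be in (0, 1]; got {target_fraction}")
    n = ct.n_residues
    off = ct.ct[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    if np.allclose(off, 0.0):
        raise CalibrationError(
            "all commute times are zero (rigid ensemble); set epsilon manually"
        )
    k = int(np.ceil(target_fraction * (n - 1)))
    kth = np.partition(off, k - 1, axis=1)[:, k - 1]
    eps = float(kth.min())
    ct.epsilon = eps
    ct.target_fraction = target_fraction
    return eps


# ---------------------------------------------------------------------------
# contacts and hydrogen bonds
# ---------------------------------------------------------------------------

def _residue_min_distance_stack(
    coords: np.ndarray, atom_idx: np.ndarray, owner: np.ndarray, n_res: int
) -> np.ndarray:
    """Per-frame minimum inter-residue distance over the given atoms.

    Returns (F, N, N); assumes ``atom_idx`` sorted so that each residue's
    atoms are contiguous (true for our containers).
    """
    sub = coords[:, atom_idx, :]
    diff = sub[:, :, None, :] - sub[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    starts = np.searchsorted(owner, np.arange(n_res))
    red1 = np.minimum.reduceat(d, starts, axis=1)
    return np.minimum.reduceat(red1, starts, axis=2)


def _iter_min_distances(ensemble: ConformationalEnsemble, atom_idx, owner):
    n = ensemble.n_residues
    for lo in range(0, ensemble.n_frames, _FRAME_CHUNK):
        yield _residue_min_distance_stack(
            ensemble.coords[lo:lo + _FRAME_CHUNK], atom_idx, owner, n
        )


def _polar_atoms(ensemble: ConformationalEnsemble):
    idx, owner, names, elements = [], [], [], []
    for r in ensemble.residues:
        for a, nm, el in zip(r.atoms, r.atom_names, r.elements):
            if el.upper() in ("N", "O"):
                idx.append(a)
                owner.append(r.index)
                names.append(nm)
                elements.append(el.upper())
    return (np.array(idx, dtype=int), np.array(owner, dtype=int), names, elements)


def detect_hbonds(
    ensemble: ConformationalEnsemble, distance_cutoff: float = 3.5
) -> pd.DataFrame:
    """Hydrogen-bond occupancy table using a heavy-atom distance criterion.

    Every inter-residue pair of N/O atoms within ``distance_cutoff`` counts as
    hydrogen bonded (no angle cutoff; hydrogens are not required).  When one
    atom is nitrogen and the other oxygen the nitrogen is reported as the
    donor; otherwise the lower residue index takes the donor role.  Rows with
    zero occupancy are dropped.
    """
    idx, owner, names, elements = _polar_atoms(ensemble)
    cols = ["donor_res", "donor_atom", "acceptor_res", "acceptor_atom", "occupancy"]
    if idx.size == 0:
        logger.warning("no N/O atoms present; hydrogen-bond table is empty")
        return pd.DataFrame(columns=cols)
    sub = ensemble.coords[:, idx, :]
    counts = np.zeros((idx.size, idx.size), dtype=int)
    for lo in range(0, ensemble.n_frames, _FRAME_CHUNK):
        block = sub[lo:lo + _FRAME_CHUNK]
        diff = block[:, :, None, :] - block[:, None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        counts += (d <= distance_cutoff).sum(axis=0)
    occ = counts / ensemble.n_frames
    rows = []
    seq = ensemble.seq_ids
    for a in range(idx.size):
        for b in range(a + 1, idx.size):
            if owner[a] == owner[b] or occ[a, b] == 0.0:
                continue
            if elements[a] == "N" and elements[b] == "O":
                don, acc = a, b
            elif elements[a] == "O" and elements[b] == "N":
                don, acc = b, a
            else:
                don, acc = (a, b) if owner[a] <= owner[b] else (b, a)
            rows.append(
                (int(seq[owner[don]]), names[don], int(seq[owner[acc]]), names[acc],
                 float(occ[a, b]))
            )
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["donor_res", "acceptor_res"], ignore_index=True
    )


def detect_contacts(
    ensemble: ConformationalEnsemble,
    heavy_atom_cutoff: float = 4.0,
    min_occupancy: float = 0.5,
    hbond_cutoff: float = 3.5,
    ca_fallback_cutoff: float = 7.0,
) -> ContactMap:
    """Persistent non-bonded contact detection.

    A residue pair interacts in a frame if any inter-residue heavy-atom pair
    is within ``heavy_atom_cutoff`` Å or any N/O–N/O pair is within
    ``hbond_cutoff`` Å.  Persistence requires interaction in at least
    ``min_occupancy`` of the frames.  Sequence-adjacent pairs (|Δseq| <= 1)
    never enter the persistent graph.  Cα-only ensembles fall back to a Cα
    distance criterion (``ca_fallback_cutoff``).
    """
    n = ensemble.n_residues
    f = ensemble.n_frames
    counts = np.zeros((n, n), dtype=int)
    if ensemble.is_ca_only:
        logger.warning(
            "Ca-only ensemble: falling back to Ca-distance contacts at %.1f A",
            ca_fallback_cutoff,
        )
        ca = ensemble.ca_coords
        for lo in range(0, f, _FRAME_CHUNK):
            counts += (_pairwise_ca_distances(ca[lo:lo + _FRAME_CHUNK])
                       <= ca_fallback_cutoff).sum(axis=0)
        criteria = {"mode": "ca_fallback", "ca_cutoff": ca_fallback_cutoff,
                    "min_occupancy": min_occupancy}
    else:
        heavy_idx, heavy_owner = [], []
        for r in ensemble.residues:
            for a in r.heavy_atoms:
                heavy_idx.append(a)
                heavy_owner.append(r.index)
        heavy_idx = np.array(heavy_idx, dtype=int)
        heavy_owner = np.array(heavy_owner, dtype=int)
        polar_idx, polar_owner, _, _ = _polar_atoms(ensemble)
        for lo in range(0, f, _FRAME_CHUNK):
            block = ensemble.coords[lo:lo + _FRAME_CHUNK]
            dmin = _residue_min_distance_stack(block, heavy_idx, heavy_owner, n)
            inter = dmin <= heavy_atom_cutoff
            if polar_idx.size and hbond_cutoff > heavy_atom_cutoff:
                dno = _residue_min_distance_stack(block, polar_idx, polar_owner, n)
                inter |= dno <= hbond_cutoff
            counts += inter.sum(axis=0)
        criteria = {"mode": "all_atom", "heavy_atom_cutoff": heavy_atom_cutoff,
                    "hbond_cutoff": hbond_cutoff, "min_occupancy": min_occupancy}
    occ = counts / f
    np.fill_diagonal(occ, 0.0)
    seq = ensemble.seq_ids
    seq_sep = np.abs(seq[:, None] - seq[None, :])
    persistent = (occ >= min_occupancy) & (seq_sep >= 2)
    return ContactMap(occupancy=occ, persistent=persistent, seq_ids=seq, criteria=criteria)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def neighbors(
    i: int,
    ct: CommuteTimeMatrix,
    contacts: ContactMap,
    min_seq_sep: int = 2,
) -> list[int]:
    """Residues j that (a) are ≥ ``min_seq_sep`` apart in sequence from i,
    (b) are persistent contacts of i and (c) have CT(i,j) ≤ ε.  Sorted."""
    if ct.epsilon is None:
        raise CalibrationError("epsilon not calibrated; call calibrate_threshold first")
    seq = ct.seq_ids
    mask = (
        contacts.persistent[i]
        & (np.abs(seq - seq[i]) >= min_seq_sep)
        & (ct.ct[i] <= ct.epsilon)
    )
    mask[i] = False
    return np.flatnonzero(mask).tolist()


def grow_pathways(
    start: int,
    ct: CommuteTimeMatrix,
    contacts: ContactMap,
    max_paths: int = 100_000,
    min_seq_sep: int = 2,
) -> PathwaySet:
    """Enumerate all maximal communication pathways from ``start``.

    One initial pathway per neighbor of ``start``; a pathway is extended by
    any neighbor of its terminal residue that is not yet a member and whose
    CT to *every* current member is ≤ ε.  Extension candidates are examined
    in ascending CT to the terminal residue (ties by residue index), so the
    enumeration order is deterministic.  Maximal paths (no admissible
    extension) are emitted, deduplicated as ordered tuples; exceeding
    ``max_paths`` truncates the enumeration and flags the result.
    """
    eps = ct.epsilon
    if eps is None:
        raise CalibrationError("epsilon not calibrated; call calibrate_threshold first")
    nb_cache: dict[int, list[int]] = {}

    def nb(r: int) -> list[int]:
        if r not in nb_cache:
            nb_cache[r] = neighbors(r, ct, contacts, min_seq_sep)
        return nb_cache[r]

    emitted: dict[tuple[int, ...], CommunicationPathway] = {}
    truncated = False

    def extend(path: list[int]) -> None:
        nonlocal truncated
        if truncated:
            return
        term = path[-1]
        cands = [
            j for j in nb(term)
            if j not in path and (ct.ct[j, path] <= eps).all()
        ]
        if not cands:
            members = tuple(path)
            if members not in emitted:
                sub = ct.ct[np.ix_(path, path)]
                emitted[members] = CommunicationPathway(
                    members=members, pairwise_ct=float(sub.max())
                )
                if len(emitted) >= max_paths:
                    truncated = True
                    logger.warning(
                        "pathway enumeration from residue %d truncated at %d paths",
                        start, max_paths,
                    )
            return
        for j in sorted(cands, key=lambda j: (ct.ct[term, j], j)):
            extend(path + [j])

    for j in sorted(nb(start), key=lambda j: (ct.ct[start, j], j)):
        extend([start, j])
    return PathwaySet(start=start, paths=list(emitted.values()), truncated=truncated)


def grow_all_pathways(
    ct: CommuteTimeMatrix,
    contacts: ContactMap,
    max_paths: int = 100_000,
    min_seq_sep: int = 2,
) -> dict[int, PathwaySet]:
    """Grow pathways from every residue; keys are internal residue indices."""
    return {
        i: grow_pathways(i, ct, contacts, max_paths=max_paths, min_seq_sep=min_seq_sep)
        for i in range(ct.n_residues)
    }


def pathway_stats(
    ct: CommuteTimeMatrix,
    all_paths: dict[int, PathwaySet],
    hub_fraction: float | None = None,
) -> PathwayStats:
    """Per-residue communication statistics.

    ``fast_fraction`` is the percentage of other residues with CT ≤ ε;
    ``max_path_length`` counts member residues of the longest pathway grown
    from the residue (1 when it seeds no pathway); ``n_paths`` counts maximal
    pathways.  Hubs are residues whose fast fraction reaches the calibration
    target (about 20% of the protein by default).
    """
    if hub_fraction is None:
        hub_fraction = ct.target_fraction if ct.target_fraction is not None else 0.20
    fast = 100.0 * ct.fast_fractions()
    rows = []
    for i in range(ct.n_residues):
        pset = all_paths.get(i)
        n_paths = len(pset) if pset is not None else 0
        max_len = max((len(p) for p in pset), default=1) if pset is not None else 1
        rows.append(
            {
                "residue": int(ct.seq_ids[i]),
                "fast_fraction": float(fast[i]),
                "max_path_length": int(max_len),
                "n_paths": int(n_paths),
                "is_hub": bool(fast[i] >= 100.0 * hub_fraction),
            }
        )
    return PathwayStats(table=pd.DataFrame(rows), hub_fraction=hub_fraction)


# ---------------------------------------------------------------------------
# plain-text export
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix: np.ndarray, seq_ids: np.ndarray, path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("residue\t" + "\t".join(str(s) for s in seq_ids) + "\n")
        for sid, row in zip(seq_ids, matrix):
            fh.write(str(sid) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_paths_json(all_paths: dict[int, PathwaySet], seq_ids: np.ndarray, path) -> None:
    payload = {
        str(int(seq_ids[i])): {
            "truncated": pset.truncated,
            "paths": [[int(seq_ids[m]) for m in p.members] for p in pset.paths],
        }
        for i, pset in all_paths.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
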