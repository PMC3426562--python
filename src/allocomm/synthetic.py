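"""Synthetic conformational ensembles with planted statistical structure.

The generator emulates, statistically, what a molecular-dynamics ensemble
offers the analysis stages: blocks of residues whose displacements are
mutually correlated (what local feature analysis should segment), ordered
residue "chains" whose pairwise distances barely fluctuate (what the
commute-time pathway search should recover), and uncorrelated Gaussian
background motion.  No force field and no Boltzmann weighting are involved;
fixtures are statistical, not physical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble import ConformationalEnsemble, ResidueRecord
from .exceptions import DesignError

logger = logging.getLogger(__name__)

__all__ = [
    "PlantedDesign",
    "make_toy_structure",
    "sample_ensemble",
    "plant_contacts",
]


@dataclass(frozen=True)
class PlantedDesign:
    """Statistical design of a synthetic ensemble.

    Parameters
    ----------
    n_residues
        Number of residues N.
    blocks
        Disjoint residue-index sets whose displacements are correlated with
        coefficient ``rho_in`` inside a block and ``rho_out`` between blocks.
    chain
        Ordered residue indices that move quasi-rigidly together so that their
        pairwise Cα distance variance is approximately
        ``chain_distance_variance`` (Å²) — a planted low-commute-time pathway.
    background_sigma2
        Isotropic per-axis displacement variance σ² (Å²) of every residue.
    seed
        RNG seed, recorded in the ensemble provenance.
    """

    n_residues: int
    blocks: tuple[tuple[int, ...], ...] = ()
    rho_in: float = 0.9
    rho_out: float = 0.0
    chain: tuple[int, ...] = ()
    chain_distance_variance: float = 0.01
    background_sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for b in self.blocks:
            if seen & set(b):
                raise DesignError(f"blocks are not disjoint: residue overlap in {b}")
            seen |= set(b)
        if self.blocks and not (0.0 <= self.rho_out < self.rho_in <= 1.0):
            raise DesignError(
                f"need 0 <= rho_out < rho_in <= 1; got rho_in={self.rho_in}, rho_out={self.rho_out}"
            )
        if self.chain_distance_variance < 0:
            raise DesignError("chain_distance_variance must be >= 0")
        if self.background_sigma2 < 0:
            raise DesignError("background_sigma2 must be >= 0")
        bad = [i for b in self.blocks for i in b if not 0 <= i < self.n_residues]
        bad += [i for i in self.chain if not 0 <= i < self.n_residues]
        if bad:
            raise DesignError(f"residue indices out of range: {sorted(set(bad))}")

    # plain key=value round-trip so a fixture can sit beside its design on disk
    def to_config(self) -> str:
        lines = [
            f"n_residues = {self.n_residues}",
            "blocks = " + ";".join(",".join(map(str, b)) for b in self.blocks),
            f"rho_in = {self.rho_in}",
            f"rho_out = {self.rho_out}",
            "chain = " + ",".join(map(str, self.chain)),
            f"chain_distance_variance = {self.chain_distance_variance}",
            f"background_sigma2 = {self.background_sigma2}",
            f"seed = {self.seed}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_config(cls, text: str) -> "PlantedDesign":
        kv = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            kv[k.strip()] = v.strip()
        blocks = tuple(
            tuple(int(x) for x in grp.split(",") if x)
            for grp in kv.get("blocks", "").split(";")
            if grp
        )
        chain = tuple(int(x) for x in kv.get("chain", "").split(",") if x)
        return cls(
            n_residues=int(kv["n_residues"]),
            blocks=blocks,
            rho_in=float(kv.get("rho_in", 0.9)),
            rho_out=float(kv.get("rho_out", 0.0)),
            chain=chain,
            chain_distance_variance=float(kv.get("chain_distance_variance", 0.01)),
            background_sigma2=float(kv.get("background_sigma2", 1.0)),
            seed=int(kv.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "blocks": [list(b) for b in self.blocks],
            "rho_in": self.rho_in,
            "rho_out": self.rho_out,
            "chain": list(self.chain),
            "chain_distance_variance": self.chain_distance_variance,
            "background_sigma2": self.background_sigma2,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedDesign":
        d = dict(d)
        d["blocks"] = tuple(tuple(b) for b in d.get("blocks", ()))
        d["chain"] = tuple(d.get("chain", ()))
        return cls(**d)


# ---------------------------------------------------------------------------
# reference geometries
# ---------------------------------------------------------------------------

# idealised alpha-helix parameters: ~100 deg twist and 1.5 A rise per residue
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = np.deg2rad(100.0)
_CA_SPACING = 3.8


def make_toy_structure(
    n_residues: int,
    geometry: str = "extended",
    polar_atoms: bool = True,
) -> ConformationalEnsemble:
    """Build a single-frame reference structure with one Cα per residue.

    Consecutive Cα atoms are 3.8 Å apart along either a straight line
    (``extended``) or a helix-like curve whose i→i+3/i+4 spatial proximity
    mimics an α-helix.  With ``polar_atoms`` each residue also carries a donor
    nitrogen ("ND") and an acceptor oxygen ("OA") pseudo-atom at fixed offsets,
    which the contact and hydrogen-bond detectors can see; Cα-only structures
    (``polar_atoms=False``) exercise the Cα-distance fallback contact rule.
    """
    if n_residues < 4:
        raise DesignError(f"toy structure needs at least 4 residues; got {n_residues}")
    geometry = geometry.lower()
    ca = np.zeros((n_residues, 3))
    radial = np.zeros((n_residues, 3))
    if geometry == "extended":
        ca[:, 0] = _CA_SPACING * np.arange(n_residues)
        radial[:, 1] = 1.0
    elif geometry in ("helix", "helix-like"):
        t = _HELIX_TWIST * np.arange(n_residues)
        ca[:, 0] = _HELIX_RADIUS * np.cos(t)
        ca[:, 1] = _HELIX_RADIUS * np.sin(t)
        ca[:, 2] = _HELIX_RISE * np.arange(n_residues)
        # rescale rise so consecutive Ca are exactly 3.8 A apart
        d0 = np.linalg.norm(ca[1] - ca[0])
        ca[:, 2] *= np.sqrt(
            max((_CA_SPACING**2 - (d0**2 - _HELIX_RISE**2)), 0.0)
        ) / _HELIX_RISE
        radial[:, 0] = np.cos(t)
        radial[:, 1] = np.sin(t)
    else:
        raise DesignError(f"unknown geometry {geometry!r}")

    coords, residues = [], []
    atom_idx = 0
    for i in range(n_residues):
        atoms, names, elements = [], [], []
        coords.append(ca[i])
        atoms.append(atom_idx)
        names.append("CA")
        elements.append("C")
        atom_idx += 1
        if polar_atoms:
            coords.append(ca[i] + 1.0 * radial[i] + np.array([0.0, 0.0, 0.4]))
            atoms.append(atom_idx)
            names.append("ND")
            elements.append("N")
            atom_idx += 1
            coords.append(ca[i] + 1.0 * radial[i] - np.array([0.0, 0.0, 0.4]))
            atoms.append(atom_idx)
            names.append("OA")
            elements.append("O")
            atom_idx += 1
        residues.append(
            ResidueRecord(
                index=i,
                seq_id=i + 1,
                name="GLY",
                chain_id="A",
                ca_atom=atoms[0],
                atoms=tuple(atoms),
                atom_names=tuple(names),
                elements=tuple(elements),
            )
        )
    ref = np.asarray(coords)[None, :, :]
    return ConformationalEnsemble(
        coords=ref, residues=residues, source=f"toy:{geometry}:N={n_residues}"
    )


# ---------------------------------------------------------------------------
# ensemble sampling
# ---------------------------------------------------------------------------

def _design_correlation(design: PlantedDesign, free: np.ndarray) -> np.ndarray:
    """Residue displacement correlation matrix over the non-chain residues."""
    n = free.size
    pos = {r: k for k, r in enumerate(free)}
    corr = np.eye(n)
    block_of = {}
    for b_id, b in enumerate(design.blocks):
        for i in b:
            if i in pos:
                block_of[i] = b_id
    for i, bi in block_of.items():
        for j, bj in block_of.items():
            if i == j:
                continue
            corr[pos[i], pos[j]] = design.rho_in if bi == bj else design.rho_out
    return corr


def sample_ensemble(
    design: PlantedDesign,
    reference: ConformationalEnsemble,
    n_frames: int,
) -> ConformationalEnsemble:
    """Sample an ensemble around ``reference`` following the planted design.

    Each residue is displaced rigidly (all its atoms together) by a zero-mean
    Gaussian vector; displacements are isotropic in x,y,z and correlated
    across residues per the block design.  Chain residues share one common
    displacement plus independent jitter of per-axis variance v/2, so the
    pairwise distance variance of chain members is approximately v (the
    distance fluctuation projects the 2·(v/2) relative jitter onto the
    inter-residue axis).
    """
    if n_frames < 2:
        raise DesignError(f"need at least 2 frames; got {n_frames}")
    if reference.n_residues != design.n_residues:
        raise DesignError(
            f"reference has {reference.n_residues} residues, design expects {design.n_residues}"
        )
    rng = np.random.default_rng(design.seed)
    n = design.n_residues
    sigma = np.sqrt(design.background_sigma2)
    chain = np.asarray(design.chain, dtype=int)
    free = np.setdiff1d(np.arange(n), chain)

    disp = np.zeros((n_frames, n, 3))
    if free.size and sigma > 0:
        corr = _design_correlation(design, free)
        vals, vecs = np.linalg.eigh(corr)
        if vals.min() < -1e-10:
            if vals.min() < -0.05 * max(vals.max(), 1.0):
                b = design.blocks[:2] if len(design.blocks) >= 2 else design.blocks
                raise DesignError(
                    f"requested correlation matrix is not positive semidefinite "
                    f"(min eigenvalue {vals.min():.3g}); offending blocks: {b}"
                )
            logger.warning(
                "design correlation slightly indefinite (min eig %.3g); clipped to PSD",
                vals.min(),
            )
        vals = np.clip(vals, 0.0, None)
        factor = vecs * np.sqrt(vals)  # corr = factor @ factor.T
        z = rng.standard_normal((n_frames, 3, free.size))
        disp[:, free, :] = sigma * np.transpose(z @ factor.T, (0, 2, 1))
    if chain.size:
        common = sigma * rng.standard_normal((n_frames, 1, 3))
        jitter = np.sqrt(design.chain_distance_variance / 2.0) * rng.standard_normal(
            (n_frames, chain.size, 3)
        )
        disp[:, chain, :] = common + jitter

    coords = np.repeat(reference.coords[:1], n_frames, axis=0)
    for r in reference.residues:
        coords[:, list(r.atoms), :] += disp[:, r.index, None, :]
    return ConformationalEnsemble(
        coords=coords,
        residues=reference.residues,
        source=f"{reference.source}|design(seed={design.seed})",
        superposed=True,  # displacements are zero-mean about the reference
    )


def plant_contacts(
    reference: ConformationalEnsemble,
    pairs: list[tuple[int, int]],
    occupancy,
    n_frames: int,
    seed: int = 0,
) -> ConformationalEnsemble:
    """Build an ensemble where listed donor→acceptor pairs meet the 3.5 Å
    hydrogen-bond rule in exactly ``round(occupancy*F)`` frames.

    ``pairs`` are (donor_residue, acceptor_residue) internal indices; the
    donor residue's "ND" atom and the acceptor residue's "OA" atom are used.
    In contact frames the acceptor atom sits 3.3 Å from the donor, otherwise
    7.0 Å away along the same direction.  Occupancy may be a scalar or one
    fraction per pair.
    """
    occ = np.broadcast_to(np.asarray(occupancy, dtype=float), (len(pairs),)).copy()
    if ((occ < 0) | (occ > 1)).any():
        raise DesignError("occupancy must lie in [0, 1]")
    acceptors = [j for _, j in pairs]
    if len(set(acceptors)) != len(acceptors):
        raise DesignError(
            "conflicting pair geometry: an acceptor residue appears in more than one pair"
        )
    rng = np.random.default_rng(seed)
    coords = np.repeat(reference.coords[:1], n_frames, axis=0)

    def _atom(res: ResidueRecord, name: str) -> int:
        try:
            return res.atoms[res.atom_names.index(name)]
        except ValueError as exc:
            raise DesignError(f"residue {res.seq_id} lacks required atom {name}") from exc

    for (i, j), frac in zip(pairs, occ):
        don = _atom(reference.residues[i], "ND")
        acc = _atom(reference.residues[j], "OA")
        d0 = reference.coords[0, don]
        direction = reference.coords[0, acc] - d0
        nrm = np.linalg.norm(direction)
        direction = direction / nrm if nrm > 1e-9 else np.array([1.0, 0.0, 0.0])
        k = int(round(frac * n_frames))
        in_contact = np.zeros(n_frames, dtype=bool)
        in_contact[rng.permutation(n_frames)[:k]] = True
        coords[in_contact, acc, :] = d0 + 3.3 * direction
        coords[~in_contact, acc, :] = d0 + 7.0 * direction
    return ConformationalEnsemble(
        coords=coords,
        residues=reference.residues,
        source=f"{reference.source}|planted_contacts(seed={seed})",
    )
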