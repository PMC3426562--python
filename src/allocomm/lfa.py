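"""Local feature analysis of collective motions and independent dynamic segments.

Principal component analysis of the superposed Cα fluctuations yields global
modes ψ_k with variances λ_k.  Local feature analysis (LFA) turns the retained
modes into per-residue output functions with minimal spatial correlation; its
sparsification picks *seed* residues that best reconstruct all outputs.
Independent dynamic segments (IDSs) are spatially connected residue clusters
grown around the seeds while the cluster's mean residual correlation stays
above a calibrated threshold.

Conventions (the source formulas for this formalism are frequently quoted
only in part; the choices here are spelled out in the methods note):

* outputs ``O = Σ_k ψ_k a_k`` over the m retained modes, so the full basis
  reproduces the original fluctuations exactly;
* residual correlation ``P(i,j) = Σ_α Σ_k ψ_k(3i+α) ψ_k(3j+α)`` (α over
  x,y,z), normalised to unit diagonal, so the full basis is completely
  decorrelated by space (P → identity);
* sparsification scores reconstruction error on the λ-weighted output
  covariance, making the first seed the maximal-variance residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .communication import _FRAME_CHUNK, _residue_min_distance_stack
from .ensemble import ConformationalEnsemble, FluctuationProfile
from .exceptions import CalibrationError, DegenerateEnsembleError

logger = logging.getLogger(__name__)

__all__ = [
    "PCABasis",
    "LFAResult",
    "DynamicSegment",
    "compute_pca",
    "lfa_outputs",
    "residual_correlation",
    "output_covariance",
    "select_seeds",
    "mean_smallest_distance_matrix",
    "calibrate_rho_threshold",
    "grow_segment",
    "grow_all_segments",
    "segment_fluctuation_share",
    "run_lfa",
]


@dataclass
class PCABasis:
    """Eigenbasis of the 3N×3N Cα fluctuation covariance.

    ``eigenvectors`` holds ψ_k as columns (orthonormal), ``eigenvalues`` the
    λ_k in Å², sorted descending; ``n_retained`` modes cover at least the
    retention target of the total variance.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    n_retained: int
    retention: float
    mean: np.ndarray = field(repr=False, default=None)

    @property
    def n_dof(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_residues(self) -> int:
        return self.n_dof // 3

    @property
    def cumulative_fraction(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return np.cumsum(self.eigenvalues) / tot if tot > 0 else np.zeros_like(self.eigenvalues)

    @property
    def retained_fraction(self) -> float:
        return float(self.cumulative_fraction[self.n_retained - 1])


@dataclass(frozen=True)
class DynamicSegment:
    """One independent dynamic segment: seed residue plus its grown members."""

    seed: int
    members: tuple[int, ...]
    mean_internal_correlation: float
    label: str = ""


@dataclass
class LFAResult:
    """LFA decomposition: outputs, projections, residual correlations and seeds."""

    basis: PCABasis
    outputs: np.ndarray          # (F, 3N) retained-mode outputs
    projections: np.ndarray      # (F, m) mode projections a_k
    residual: np.ndarray         # (N, N) normalized residual correlation P
    seeds: tuple[int, ...]
    err_trace: np.ndarray        # mean reconstruction error per sparsification step


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def compute_pca(ensemble: ConformationalEnsemble, retention: float = 0.80) -> PCABasis:
    """Eigendecomposition of the Cα covariance; retain the smallest mode count
    whose cumulative variance fraction reaches ``retention``."""
    f = ensemble.n_frames
    if f < 2:
        raise DegenerateEnsembleError("PCA needs at least 2 frames")
    if not ensemble.superposed:
        logger.warning("PCA on a non-superposed ensemble mixes internal and rigid-body motion")
    x = ensemble.ca_coords.reshape(f, -1)
    if f <= x.shape[1]:
        logger.warning(
            "fewer frames (%d) than Cartesian degrees of freedom (%d); covariance is rank-deficient",
            f, x.shape[1],
        )
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / f
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    tot = vals.sum()
    if tot <= 0:
        raise DegenerateEnsembleError("zero total fluctuation variance (rigid ensemble)")
    m = int(np.searchsorted(np.cumsum(vals) / tot, retention) + 1)
    m = min(m, vals.size)
    return PCABasis(
        eigenvectors=vecs, eigenvalues=vals, n_retained=m, retention=retention, mean=mean
    )


def lfa_outputs(basis: PCABasis, ensemble: ConformationalEnsemble):
    """Mode projections a_k and retained-mode output functions O.

    ``a_k(t)`` is the projection of the frame-t fluctuation onto ψ_k;
    ``O(t) = Σ_k ψ_k a_k(t)`` over the retained modes only, i.e. the
    fluctuations filtered through the retained subspace.
    """
    m = basis.n_retained
    x = ensemble.ca_coords.reshape(ensemble.n_frames, -1) - basis.mean
    psi = basis.eigenvectors[:, :m]
    a = x @ psi
    return a @ psi.T, a


def residual_correlation(basis: PCABasis, normalize: bool = True) -> np.ndarray:
    """Residue-level residual correlation P of the retained-mode subspace.

    P(i,j) accumulates ψ_k(3i+α)ψ_k(3j+α) over the x,y,z components α and the
    retained modes k; with all 3N modes P is the identity (outputs completely
    decorrelated by space).  ``normalize`` rescales to unit diagonal.
    """
    m = basis.n_retained
    psi = basis.eigenvectors[:, :m].reshape(basis.n_residues, 3, m)
    p = np.einsum("iak,jak->ij", psi, psi)
    p = 0.5 * (p + p.T)
    if normalize:
        d = np.sqrt(np.clip(np.diag(p), 1e-300, None))
        p = p / np.outer(d, d)
        np.fill_diagonal(p, 1.0)
    return p


def output_covariance(basis: PCABasis) -> np.ndarray:
    """Residue-level covariance of the retained-mode outputs (λ-weighted P)."""
    m = basis.n_retained
    psi = basis.eigenvectors[:, :m].reshape(basis.n_residues, 3, m)
    lam = basis.eigenvalues[:m]
    c = np.einsum("iak,jak,k->ij", psi, psi, lam)
    return 0.5 * (c + c.T)


# ---------------------------------------------------------------------------
# sparsification
# ---------------------------------------------------------------------------

def select_seeds(
    basis: PCABasis,
    n_seeds: int | None = None,
) -> tuple[tuple[int, ...], np.ndarray]:
    """Iterative sparsification of the LFA outputs.

    Starting from the empty seed set (reconstruction ≡ 0, so every residue's
    error equals its output variance), each step reconstructs all outputs
    from the current seeds by linear least squares and adds the not-yet-chosen
    residue with the largest mean-square reconstruction error.  Ties break
    toward the lower residue index.  Returns the ordered seed tuple and the
    trace of the mean reconstruction error after each addition.
    """
    n = basis.n_residues
    if n_seeds is None:
        # one seed per retained mode, never more than one per residue
        n_seeds = min(basis.n_retained, n)
    if n_seeds > n:
        raise ValueError(f"n_seeds={n_seeds} exceeds residue count {n}")
    cov = output_covariance(basis)
    err = np.diag(cov).copy()
    seeds: list[int] = []
    trace = []
    for _ in range(n_seeds):
        masked = err.copy()
        masked[seeds] = -np.inf
        seeds.append(int(np.argmax(masked)))
        sub = cov[np.ix_(seeds, seeds)]
        if np.linalg.cond(sub) > 1e12:
            logger.warning("seed covariance submatrix is rank-deficient; using pseudo-inverse")
        inv = np.linalg.pinv(sub, hermitian=True)
        cross = cov[:, seeds]
        err = np.clip(np.diag(cov) - np.einsum("ij,jk,ik->i", cross, inv, cross), 0.0, None)
        trace.append(float(err.mean()))
    return tuple(seeds), np.asarray(trace)


# ---------------------------------------------------------------------------
# spatial proximity and segment growth
# ---------------------------------------------------------------------------

def mean_smallest_distance_matrix(ensemble: ConformationalEnsemble) -> np.ndarray:
    """Frame-averaged minimum inter-atomic distance between every residue pair."""
    atom_idx, owner = [], []
    for r in ensemble.residues:
        for a in r.atoms:
            atom_idx.append(a)
            owner.append(r.index)
    atom_idx = np.array(atom_idx, dtype=int)
    owner = np.array(owner, dtype=int)
    n = ensemble.n_residues
    acc = np.zeros((n, n))
    for lo in range(0, ensemble.n_frames, _FRAME_CHUNK):
        acc += _residue_min_distance_stack(
            ensemble.coords[lo:lo + _FRAME_CHUNK], atom_idx, owner, n
        ).sum(axis=0)
    acc /= ensemble.n_frames
    np.fill_diagonal(acc, 0.0)
    return acc


def calibrate_rho_threshold(p: np.ndarray, above_fraction: float = 0.0125) -> float:
    """Correlation threshold leaving ``above_fraction`` of the off-diagonal
    |P| values above it (default 1.25%, inside the 1.0–1.5% working band)."""
    n = p.shape[0]
    vals = np.sort(np.abs(p[np.triu_indices(n, k=1)]))
    if vals.size == 0 or vals[0] == vals[-1]:
        raise CalibrationError(
            "residual correlations are constant; set the threshold manually"
        )
    rank = int(np.ceil((1.0 - above_fraction) * vals.size))
    return float(vals[min(rank, vals.size) - 1])


def grow_segment(
    seed: int,
    p: np.ndarray,
    distances: np.ndarray,
    rho_threshold: float,
    d_threshold: float = 6.0,
    aggregation: str = "min",
    label: str = "",
) -> DynamicSegment:
    """Grow one independent dynamic segment around ``seed``.

    Breadth-first growth over spatial neighbors (mean smallest distance below
    ``d_threshold``): candidates are examined in ascending distance to the
    seed (ties by index); a candidate is admitted only if the aggregated
    residual correlation of the tentative member set — the mean (or min) of
    the off-diagonal entries of the P submatrix — stays at or above
    ``rho_threshold``.  Rejected candidates are not revisited.
    """
    members = [seed]
    in_set = {seed}
    examined = {seed}
    agg = {"mean": np.mean, "min": np.min}[aggregation]

    def admissible(tentative: list[int]) -> bool:
        sub = p[np.ix_(tentative, tentative)]
        off = sub[~np.eye(len(tentative), dtype=bool)]
        return bool(agg(off) >= rho_threshold)

    frontier = sorted(
        np.flatnonzero(distances[seed] < d_threshold).tolist(),
        key=lambda j: (distances[seed, j], j),
    )
    queue = [j for j in frontier if j != seed]
    while queue:
        queue.sort(key=lambda j: (distances[seed, j], j))
        j = queue.pop(0)
        if j in examined:
            continue
        examined.add(j)
        if admissible(members + [j]):
            members.append(j)
            in_set.add(j)
            for k in np.flatnonzero(distances[j] < d_threshold):
                if k not in examined:
                    queue.append(int(k))
    members_t = tuple(sorted(in_set))
    if len(members_t) > 1:
        sub = p[np.ix_(members_t, members_t)]
        mic = float(sub[~np.eye(len(members_t), dtype=bool)].mean())
    else:
        mic = 1.0  # singleton: self-correlation only
    return DynamicSegment(
        seed=seed, members=members_t, mean_internal_correlation=mic, label=label
    )


def grow_all_segments(
    seeds,
    p: np.ndarray,
    distances: np.ndarray,
    rho_threshold: float,
    d_threshold: float = 6.0,
    aggregation: str = "min",
) -> list[DynamicSegment]:
    return [
        grow_segment(s, p, distances, rho_threshold, d_threshold, aggregation,
                     label=f"S{k + 1}")
        for k, s in enumerate(seeds)
    ]


def segment_fluctuation_share(segments, profile: FluctuationProfile) -> float:
    """Fraction of the total per-residue RMSF carried by segment members."""
    total = float(profile.values.sum())
    if total == 0.0 or not segments:
        return 0.0
    union: set[int] = set()
    for s in segments:
        union |= set(s.members)
    return float(profile.values[sorted(union)].sum() / total)


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

def run_lfa(
    ensemble: ConformationalEnsemble,
    retention: float = 0.80,
    n_seeds: int | None = None,
) -> LFAResult:
    """PCA → LFA outputs → residual correlation → sparsification, bundled."""
    basis = compute_pca(ensemble, retention=retention)
    outputs, projections = lfa_outputs(basis, ensemble)
    p = residual_correlation(basis)
    seeds, trace = select_seeds(basis, n_seeds=n_seeds)
    return LFAResult(
        basis=basis, outputs=outputs, projections=projections,
        residual=p, seeds=seeds, err_trace=trace,
    )
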