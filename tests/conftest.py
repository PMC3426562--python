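"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk except
files the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pytest

from allocomm.communication import CommuteTimeMatrix, ContactMap
from allocomm.ensemble import ConformationalEnsemble, ResidueRecord


def ensemble_from_ca(ca: np.ndarray, superposed: bool = True) -> ConformationalEnsemble:
    """Cα-only ensemble from a (F, N, 3) coordinate stack."""
    ca = np.asarray(ca, dtype=float)
    residues = [
        ResidueRecord(
            index=i, seq_id=i + 1, name="GLY", chain_id="A",
            ca_atom=i, atoms=(i,), atom_names=("CA",), elements=("C",),
        )
        for i in range(ca.shape[1])
    ]
    return ConformationalEnsemble(coords=ca, residues=residues, superposed=superposed)


def random_instance(rng: np.random.Generator, n: int):
    """Random commute-time matrix + contact graph with calibrated epsilon."""
    ct = rng.uniform(0.0, 1.0, (n, n))
    ct = (ct + ct.T) / 2.0
    np.fill_diagonal(ct, 0.0)
    adj = rng.random((n, n)) < 0.45
    adj = adj | adj.T
    np.fill_diagonal(adj, False)
    seq = np.arange(1, n + 1)
    sep = np.abs(seq[:, None] - seq[None, :])
    ctm = CommuteTimeMatrix(
        ct=ct, n_frames=10, seq_ids=seq,
        epsilon=float(rng.uniform(0.25, 0.6)), target_fraction=0.2,
    )
    cmap = ContactMap(
        occupancy=adj.astype(float), persistent=adj & (sep >= 2), seq_ids=seq
    )
    return ctm, cmap


def oracle_paths(start, ct, eps, persistent, seq_ids, min_sep=2):
    """Exhaustive recursive enumeration of maximal communication pathways."""
    n = len(seq_ids)

    def nbrs(r):
        return [
            j for j in range(n)
            if j != r
            and persistent[r][j]
            and abs(seq_ids[r] - seq_ids[j]) >= min_sep
            and ct[r][j] <= eps
        ]

    results = set()

    def rec(path):
        cands = [
            j for j in nbrs(path[-1])
            if j not in path and all(ct[j][m] <= eps for m in path)
        ]
        if not cands:
            results.add(tuple(path))
            return
        for j in cands:
            rec(path + [j])

    for j in nbrs(start):
        rec([start, j])
    return results


def ar1_ensemble(rng: np.random.Generator, n_res: int, n_frames: int, phi: float):
    """Residues far apart on the x axis, each with AR(1) x displacement.

    Every pair distance then carries the same AR(1) autocorrelation phi^t.
    """
    x = np.zeros((n_frames, n_res))
    innov = rng.standard_normal((n_frames, n_res)) * np.sqrt(1.0 - phi**2)
    for t in range(1, n_frames):
        x[t] = phi * x[t - 1] + innov[t]
    base = 50.0 * np.arange(n_res)
    ca = np.zeros((n_frames, n_res, 3))
    ca[:, :, 0] = base + x
    return ensemble_from_ca(ca)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
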