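"""Modular network assembly, convergence diagnostics, comparison and export.

The modular network is the union of the communication pathways (chains of
efficiently communicating, persistently interacting residues) and the
independent dynamic segments (clusters of locally coupled residues), with
per-residue statistics, the hub set and full provenance of every threshold
used — enough to rebuild the network bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .communication import (
    CommuteTimeMatrix,
    ContactMap,
    PathwaySet,
    PathwayStats,
    CommunicationPathway,
)
from .ensemble import ConformationalEnsemble, ca_distance_series
from .exceptions import AssemblyError, ComparisonError, DegenerateEnsembleError
from .lfa import DynamicSegment

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceReport",
    "ModularNetwork",
    "ComparisonReport",
    "distance_autocorrelation",
    "fit_exponential",
    "assemble_network",
    "compare_networks",
    "export_visualization",
]


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def distance_autocorrelation(
    ensemble: ConformationalEnsemble,
    max_lag: int | None = None,
    max_pairs: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Pair-averaged normalized time autocorrelation of Cα–Cα distances.

    Every pair's distance series is mean-centred and variance-normalized
    before averaging, so C(0)=1; the pre-factor is one over the number of
    contributing pairs.  Constant series carry no fluctuation signal and are
    excluded with a warning.  ``max_pairs`` caps the number of pairs by a
    seeded subsample (all pairs by default).
    """
    f = ensemble.n_frames
    if f < 10:
        raise DegenerateEnsembleError(f"autocorrelation needs at least 10 frames; got {f}")
    if max_lag is None:
        max_lag = f // 2
    n = ensemble.n_residues
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = rng or np.random.default_rng(0)
        keep = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(keep)]
    series = np.stack([ca_distance_series(ensemble, i, j) for i, j in pairs], axis=1)
    series = series - series.mean(axis=0)
    var = series.var(axis=0)
    ok = var > 1e-12
    if not ok.all():
        logger.warning("%d constant distance series excluded from C(t)", (~ok).sum())
    series = series[:, ok]
    if series.shape[1] == 0:
        raise DegenerateEnsembleError("all distance series are constant; C(t) undefined")
    # biased autocovariance via FFT, then per-pair normalization by lag 0
    nfft = int(2 ** np.ceil(np.log2(2 * f)))
    spec = np.fft.rfft(series, n=nfft, axis=0)
    acov = np.fft.irfft(spec * np.conj(spec), n=nfft, axis=0)[: max_lag + 1] / f
    acf = acov / acov[0]
    return acf.mean(axis=1)


@dataclass
class ConvergenceReport:
    """Exponential-decay fit A·exp(−t/τ) to the mean distance autocorrelation."""

    curve: np.ndarray
    amplitude: float | None
    tau: float | None
    fit_correlation: float | None
    success: bool
    offset: float | None = None

    def summary(self) -> str:
        if not self.success:
            return "exponential fit failed (non-decaying curve)"
        parts = [f"A = {self.amplitude:.3f}", f"tau = {self.tau:.1f} frames",
                 f"fit correlation = {self.fit_correlation:.3f}"]
        if self.offset is not None:
            parts.append(f"offset = {self.offset:.3f}")
        return ", ".join(parts)


def fit_exponential(
    curve: np.ndarray, with_offset: bool = False
) -> ConvergenceReport:
    """Least-squares fit of A·exp(−t/τ) (optional additive offset) to C(t).

    The fit window runs from lag 0 up to the first zero crossing or the end
    of the curve, whichever comes first.  Initial values: A from C(1) pulled
    back one decay step, τ from the log-slope of the early positive stretch.
    """
    c = np.asarray(curve, dtype=float)
    crossings = np.flatnonzero(c <= 0)
    stop = int(crossings[0]) if crossings.size else c.size
    t = np.arange(stop, dtype=float)
    y = c[:stop]
    if stop < 10 or y[1] <= 0 or y[-1] >= y[0]:
        return ConvergenceReport(curve=c, amplitude=None, tau=None,
                                 fit_correlation=None, success=False)
    # log-slope initial guess over the early window
    k = max(3, min(stop // 4, 50))
    slope = np.polyfit(t[1:k], np.log(y[1:k]), 1)[0]
    tau0 = -1.0 / slope if slope < 0 else float(stop)
    a0 = float(y[1] * np.exp(1.0 / tau0))
    try:
        if with_offset:
            popt, _ = curve_fit(
                lambda t, a, tau, c0: a * np.exp(-t / tau) + c0,
                t, y, p0=[a0, tau0, 0.0], maxfev=20000,
            )
            a, tau, c0 = (float(v) for v in popt)
        else:
            popt, _ = curve_fit(
                lambda t, a, tau: a * np.exp(-t / tau),
                t, y, p0=[a0, tau0], maxfev=20000,
            )
            a, tau = (float(v) for v in popt)
            c0 = None
    except RuntimeError:
        return ConvergenceReport(curve=c, amplitude=None, tau=None,
                                 fit_correlation=None, success=False)
    if tau <= 0:
        return ConvergenceReport(curve=c, amplitude=None, tau=None,
                                 fit_correlation=None, success=False)
    model = a * np.exp(-t / tau) + (c0 or 0.0)
    r = float(pearsonr(y, model)[0]) if stop > 2 else 1.0
    return ConvergenceReport(curve=c, amplitude=a, tau=tau,
                             fit_correlation=r, success=True, offset=c0)


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------

@dataclass
class ModularNetwork:
    """Communication pathways + dynamic segments + per-residue statistics.

    ``provenance`` records every threshold, seed and input fingerprint so the
    network can be rebuilt bit-identically.
    """

    seq_ids: np.ndarray
    pathways: dict[int, PathwaySet]
    segments: list[DynamicSegment]
    stats: PathwayStats
    hubs: list[int]
    provenance: dict = field(default_factory=dict)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seq_ids": [int(s) for s in self.seq_ids],
            "pathways": {
                str(i): {
                    "truncated": ps.truncated,
                    "paths": [
                        {"members": list(p.members), "pairwise_ct": p.pairwise_ct}
                        for p in ps.paths
                    ],
                }
                for i, ps in self.pathways.items()
            },
            "segments": [
                {
                    "seed": s.seed,
                    "members": list(s.members),
                    "mean_internal_correlation": s.mean_internal_correlation,
                    "label": s.label,
                }
                for s in self.segments
            ],
            "stats": self.stats.table.to_dict(orient="records"),
            "hub_fraction": self.stats.hub_fraction,
            "hubs": list(self.hubs),
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ModularNetwork":
        pathways = {
            int(i): PathwaySet(
                start=int(i),
                truncated=rec["truncated"],
                paths=[
                    CommunicationPathway(tuple(p["members"]), p["pairwise_ct"])
                    for p in rec["paths"]
                ],
            )
            for i, rec in d["pathways"].items()
        }
        segments = [
            DynamicSegment(
                seed=s["seed"], members=tuple(s["members"]),
                mean_internal_correlation=s["mean_internal_correlation"],
                label=s.get("label", ""),
            )
            for s in d["segments"]
        ]
        stats = PathwayStats(table=pd.DataFrame(d["stats"]), hub_fraction=d["hub_fraction"])
        return cls(
            seq_ids=np.array(d["seq_ids"], dtype=int),
            pathways=pathways, segments=segments, stats=stats,
            hubs=list(d["hubs"]), provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, text: str) -> "ModularNetwork":
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ModularNetwork":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _fingerprint(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def assemble_network(
    ct: CommuteTimeMatrix,
    contacts: ContactMap,
    all_paths: dict[int, PathwaySet],
    stats: PathwayStats,
    segments: list[DynamicSegment],
    config: dict | None = None,
) -> ModularNetwork:
    """Bundle all computed components into one consistent network.

    Raises :class:`AssemblyError` when the components disagree on the residue
    set.  Hubs are residues whose fast-CT percentage reaches the hub
    threshold (by default the calibration target fraction, about 20%).
    """
    n = ct.n_residues
    sets = {
        "commute_times": n,
        "contacts": contacts.occupancy.shape[0],
        "stats": len(stats.table),
    }
    if len(set(sets.values())) != 1:
        raise AssemblyError(f"residue sets differ between components: {sets}")
    for i, ps in all_paths.items():
        for p in ps.paths:
            if any(not 0 <= m < n for m in p.members):
                raise AssemblyError(f"pathway from residue {i} references invalid residues")
    for s in segments:
        if any(not 0 <= m < n for m in s.members):
            raise AssemblyError(f"segment {s.label or s.seed} references invalid residues")
    provenance = {
        "epsilon": ct.epsilon,
        "target_fraction": ct.target_fraction,
        "hub_fraction": stats.hub_fraction,
        "n_frames": ct.n_frames,
        "contact_criteria": contacts.criteria,
        "ct_fingerprint": _fingerprint(ct.ct),
        "occupancy_fingerprint": _fingerprint(contacts.occupancy),
    }
    if config:
        provenance.update(config)
    return ModularNetwork(
        seq_ids=ct.seq_ids,
        pathways=all_paths,
        segments=segments,
        stats=stats,
        hubs=stats.hubs,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Per-residue differences between two modular networks (b − a)."""

    deltas: pd.DataFrame
    hubs_gained: list[int]
    hubs_lost: list[int]
    segment_shifts: list[dict]

    def summary(self) -> str:
        lines = [
            f"hubs gained: {self.hubs_gained or 'none'}",
            f"hubs lost: {self.hubs_lost or 'none'}",
        ]
        for s in self.segment_shifts:
            lines.append(
                f"segment around seed {s['seed']}: residues "
                f"{s['range_a'][0]}–{s['range_a'][1]} -> {s['range_b'][0]}–{s['range_b'][1]}"
            )
        return "\n".join(lines)


def compare_networks(a: ModularNetwork, b: ModularNetwork) -> ComparisonReport:
    """Differences in communication statistics, hubs and segment boundaries.

    Both networks must live on the same residue universe (indices matched
    positionally, so point mutations are allowed).  Deltas are b − a and are
    antisymmetric under operand swap.
    """
    if len(a.seq_ids) != len(b.seq_ids):
        raise ComparisonError(
            f"residue universes differ: {len(a.seq_ids)} vs {len(b.seq_ids)} residues"
        )
    ta = a.stats.table.set_index("residue")
    tb = b.stats.table.set_index("residue")
    cols = ["fast_fraction", "max_path_length", "n_paths"]
    deltas = (tb[cols] - ta[cols].values).reset_index()
    hubs_gained = sorted(set(b.hubs) - set(a.hubs))
    hubs_lost = sorted(set(a.hubs) - set(b.hubs))
    seg_b = {s.seed: s for s in b.segments}
    shifts = []
    for s in a.segments:
        other = seg_b.get(s.seed)
        if other is None or set(other.members) == set(s.members):
            continue
        shifts.append(
            {
                "seed": s.seed,
                "range_a": [min(s.members), max(s.members)],
                "range_b": [min(other.members), max(other.members)],
                "gained": sorted(set(other.members) - set(s.members)),
                "lost": sorted(set(s.members) - set(other.members)),
            }
        )
    return ComparisonReport(
        deltas=deltas, hubs_gained=hubs_gained, hubs_lost=hubs_lost, segment_shifts=shifts
    )


# ---------------------------------------------------------------------------
# visualization export
# ---------------------------------------------------------------------------

_SEGMENT_COLORS = [
    "marine", "orange", "forest", "deeppurple", "firebrick", "teal",
    "wheat", "slate", "salmon", "olive",
]


def export_visualization(network: ModularNetwork, out_dir) -> dict:
    """Write visualization artifacts for the network.

    Produces a PyMOL-dialect command script (segments as colored cartoon
    selections, pathways as sphere-and-line chains), a GraphML graph of
    pathway adjacencies with segment membership as node attributes, an
    edge-list TSV and the per-residue statistics TSV.  Returns the mapping of
    artifact name to path.
    """
    import os

    import networkx as nx

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    seq = network.seq_ids

    # --- molecular-graphics script ---------------------------------------
    pml = os.path.join(out_dir, "network.pml")
    with open(pml, "w") as fh:
        fh.write("# modular communication network: dynamic segments and pathways\n")
        fh.write("hide everything\nshow cartoon\ncolor grey80\n")
        for k, s in enumerate(network.segments):
            resis = "+".join(str(int(seq[m])) for m in sorted(s.members))
            name = s.label or f"S{k + 1}"
            color = _SEGMENT_COLORS[k % len(_SEGMENT_COLORS)]
            fh.write(f"select {name}, resi {resis}\n")
            fh.write(f"color {color}, {name}\n")
        edge_seen = set()
        for i, ps in network.pathways.items():
            for p in ps.paths:
                resis = "+".join(str(int(seq[m])) for m in p.members)
                fh.write(f"show spheres, resi {resis} and name CA\n")
                for u, v in zip(p.members, p.members[1:]):
                    if (min(u, v), max(u, v)) in edge_seen:
                        continue
                    edge_seen.add((min(u, v), max(u, v)))
                    fh.write(
                        f"distance path_edges, resi {int(seq[u])} and name CA, "
                        f"resi {int(seq[v])} and name CA\n"
                    )
        fh.write("set sphere_scale, 0.4\nhide labels, path_edges\ncolor black, path_edges\n")
    paths["script"] = pml

    # --- graph ------------------------------------------------------------
    g = nx.Graph()
    for i in range(len(seq)):
        seg_label = ""
        for s in network.segments:
            if i in s.members:
                seg_label = s.label or f"seed{s.seed}"
                break
        g.add_node(int(seq[i]), segment=seg_label, is_hub=int(seq[i]) in network.hubs)
    for ps in network.pathways.values():
        for p in ps.paths:
            for u, v in zip(p.members, p.members[1:]):
                g.add_edge(int(seq[u]), int(seq[v]))
    graphml = os.path.join(out_dir, "network.graphml")
    nx.write_graphml(g, graphml)
    paths["graph"] = graphml

    edges_tsv = os.path.join(out_dir, "path_edges.tsv")
    with open(edges_tsv, "w") as fh:
        fh.write("residue_i\tresidue_j\n")
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{v}\n")
    paths["edges"] = edges_tsv

    stats_tsv = os.path.join(out_dir, "per_residue_stats.tsv")
    network.stats.table.to_csv(stats_tsv, sep="\t", index=False)
    paths["stats"] = stats_tsv
    return paths
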