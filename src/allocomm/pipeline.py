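"""End-to-end analysis pipeline: ensemble in, modular network out.

``analyze_ensemble`` chains the commute-time, contact, pathway, PCA/LFA and
segment stages with one configuration record, and stores that record in the
network provenance.  For synthetic ensembles the provenance additionally
carries the generator design, which makes a network reproducible from its
provenance block alone (``reproduce``).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

from .communication import (
    calibrate_threshold,
    compute_commute_times,
    detect_contacts,
    grow_all_pathways,
    pathway_stats,
)
from .ensemble import ConformationalEnsemble
from .lfa import (
    calibrate_rho_threshold,
    grow_all_segments,
    mean_smallest_distance_matrix,
    run_lfa,
)
from .network import ModularNetwork, assemble_network
from .synthetic import PlantedDesign, make_toy_structure, sample_ensemble

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "analyze_ensemble", "build_synthetic_network", "reproduce"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the full analysis.

    ``epsilon``/``rho_threshold`` of None mean automatic calibration (the
    20%-connectivity rule and the 1.25%-tail rule respectively).
    """

    target_fraction: float = 0.20
    epsilon: float | None = None
    heavy_atom_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    min_occupancy: float = 0.5
    min_seq_sep: int = 2
    max_paths: int = 100_000
    retention: float = 0.80
    rho_threshold: float | None = None
    d_threshold: float = 6.0
    n_seeds: int | None = None
    hub_fraction: float | None = None
    segment_aggregation: str = "min"


def analyze_ensemble(
    ensemble: ConformationalEnsemble, config: AnalysisConfig | None = None
) -> ModularNetwork:
    """Run the complete two-component analysis on a (superposed) ensemble."""
    cfg = config or AnalysisConfig()
    ct = compute_commute_times(ensemble)
    if cfg.epsilon is not None:
        ct.epsilon = cfg.epsilon
        ct.target_fraction = cfg.target_fraction
    else:
        calibrate_threshold(ct, target_fraction=cfg.target_fraction)
    contacts = detect_contacts(
        ensemble,
        heavy_atom_cutoff=cfg.heavy_atom_cutoff,
        min_occupancy=cfg.min_occupancy,
        hbond_cutoff=cfg.hbond_cutoff,
    )
    all_paths = grow_all_pathways(
        ct, contacts, max_paths=cfg.max_paths, min_seq_sep=cfg.min_seq_sep
    )
    stats = pathway_stats(ct, all_paths, hub_fraction=cfg.hub_fraction)

    lfa = run_lfa(ensemble, retention=cfg.retention, n_seeds=cfg.n_seeds)
    distances = mean_smallest_distance_matrix(ensemble)
    rho = (
        cfg.rho_threshold
        if cfg.rho_threshold is not None
        else calibrate_rho_threshold(lfa.residual)
    )
    segments = grow_all_segments(
        lfa.seeds, lfa.residual, distances, rho_threshold=rho,
        d_threshold=cfg.d_threshold, aggregation=cfg.segment_aggregation,
    )
    network = assemble_network(
        ct, contacts, all_paths, stats, segments,
        config={
            "analysis": asdict(cfg),
            "rho_threshold": rho,
            "n_retained_modes": lfa.basis.n_retained,
            "retained_variance_fraction": lfa.basis.retained_fraction,
            "lfa_seeds": list(lfa.seeds),
        },
    )
    return network


def build_synthetic_network(
    design: PlantedDesign,
    n_frames: int,
    geometry: str = "helix",
    polar_atoms: bool = True,
    config: AnalysisConfig | None = None,
) -> ModularNetwork:
    """Generate a synthetic ensemble from ``design`` and analyze it.

    The provenance embeds the design and generation parameters, so
    :func:`reproduce` can rebuild the identical network.
    """
    reference = make_toy_structure(design.n_residues, geometry, polar_atoms=polar_atoms)
    ensemble = sample_ensemble(design, reference, n_frames)
    network = analyze_ensemble(ensemble, config)
    network.provenance["synthetic"] = {
        "design": design.to_dict(),
        "n_frames": n_frames,
        "geometry": geometry,
        "polar_atoms": polar_atoms,
    }
    return network


def reproduce(network: ModularNetwork) -> ModularNetwork:
    """Rebuild a synthetic-provenance network from its provenance block."""
    syn = network.provenance.get("synthetic")
    if syn is None:
        raise ValueError("network provenance carries no synthetic generation record")
    design = PlantedDesign.from_dict(syn["design"])
    cfg = AnalysisConfig(**network.provenance["analysis"])
    return build_synthetic_network(
        design,
        n_frames=syn["n_frames"],
        geometry=syn["geometry"],
        polar_atoms=syn["polar_atoms"],
        config=cfg,
    )
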