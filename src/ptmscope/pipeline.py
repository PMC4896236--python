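"""End-to-end descriptor extraction for one system.

Chains the ensemble-averaged descriptors, the representative-conformation
interface geometry and the free-energy-landscape markers into a complete
nine-entry descriptor vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .descriptors import DescriptorConfig, DescriptorVector, trajectory_mean_descriptors
from .fel import fel_markers
from .interface_geometry import gap_analysis, representative_structure
from .model_io import StructureModel, TrajectoryEnsemble, select_equilibrated

__all__ = ["PipelineConfig", "compute_descriptors"]


@dataclass
class PipelineConfig:
    """All knobs of the per-system descriptor pipeline."""

    descriptor: DescriptorConfig = field(default_factory=DescriptorConfig)
    cluster_cutoff: float = 0.3  # nm
    grid_interval: float = 0.8  # Å
    distance_cutoff: float = 5.0  # Å
    min_gap_radius: float = 1.0  # Å
    asa_mode: str = "per_side"
    fel_bins: int = 20
    fel_box: int = 3
    fel_frac: float = 0.7
    auto_equilibrate: bool = False


def compute_descriptors(
    t: TrajectoryEnsemble,
    cfg: PipelineConfig | None = None,
) -> DescriptorVector:
    """Full nine-parameter descriptor vector for one conformational ensemble.

    Ensemble averages (surfaces, hydrogen bonds, Lennard-Jones energy) come
    from the equilibrated window; the gap volume and gap index are computed
    on the representative conformation (central structure of the largest
    conformational cluster); the stability markers come from the landscape
    over the first two essential-dynamics components.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if cfg.auto_equilibrate:
        t = select_equilibrated(t)
    vec = trajectory_mean_descriptors(t, cfg.descriptor)

    rep: StructureModel = representative_structure(t, cfg.cluster_cutoff)
    region = gap_analysis(
        rep,
        grid_interval=cfg.grid_interval,
        distance_cutoff=cfg.distance_cutoff,
        min_gap_radius=cfg.min_gap_radius,
        asa_mode=cfg.asa_mode,
        probe=cfg.descriptor.probe,
        n_points=cfg.descriptor.n_points,
    )
    vec.volume = region.gap_volume
    vec.gap_index = region.gap_index

    abs_min, n_min, _ = fel_markers(
        t, n_bins=cfg.fel_bins, box=cfg.fel_box, frac=cfg.fel_frac
    )
    vec.abs_min = abs_min
    vec.n_min = float(n_min)
    return vec
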