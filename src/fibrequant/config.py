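"""Pipeline configuration: every tunable of the quantification pipeline.

A single :class:`PipelineConfig` travels through detection, colocalization,
quantification and statistics, can be round-tripped through YAML, and hashes
to a short digest that is stamped into every output file for provenance.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

CHANNELS = ("PGP95", "SP", "NR2B", "NGF")
MARKERS = ("SP", "NR2B", "NGF")
TISSUES = ("myocyte", "connective")


@dataclass
class PipelineConfig:
    """Tunables of the fibre-quantification pipeline.

    Parameters
    ----------
    pixel_size_um : physical pixel size in micrometres; when ``None`` it must
        be recoverable from the image metadata.
    channel_order : channel names in storage order of the multichannel TIFF.
    threshold_mode : ``"iterative"`` (default) estimates background mean/SD on
        the whole raster, excludes pixels above mean + 2 SD once and
        re-estimates; ``"naive"`` uses the single full-raster pass.
    merge_distance_um : maximum gap between signal components that still
        belong to the same fibre (boundary-to-boundary, pixel centers).
    orientation_gate_deg : maximum angle between principal axes for two
        components to count as "sharing the same path"; ``None`` disables the
        gate (purely distance-based merging).
    min_axis_px : component size below which a principal axis is considered
        unstable.
    isotropy_elongation : components with axis-length ratio below this are
        treated as directionless and always orientation-compatible.
    small_component_policy : ``"exclude"`` (default) — components smaller than
        ``min_axis_px`` never merge; ``"merge"`` — they merge on distance and
        tissue alone.
    l_min_um, w_min_um : minimum Feret length/width for a component to count
        as a positive nerve fibre.
    size_filter_before_merge : apply the size rule to raw components before
        merging instead of after (non-default alternative).
    marker_size_filter : apply the same Feret size rule to marker-channel mask
        components before overlap scoring (default) instead of scoring against
        the raw thresholded mask.
    min_overlap_px : minimum footprint/marker-mask overlap, in pixels, for a
        marker flag to be set.
    exclusive_combinations : report the 7 marker combinations as mutually
        exclusive states instead of non-exclusive intersections.
    combined_density : ``"pooled"`` (total count / total area, default) or
        ``"mean"`` (average of per-tissue densities) for the both-tissues rows.
    mw_mode : Mann-Whitney mode, ``"auto"`` | ``"exact"`` | ``"approx"``.
    spearman_permutations : if > 0, permutation p-values (that many draws) are
        used for Spearman tests on samples with n < 15.
    alpha : family-wise significance level.
    n_family_tests : size of the multiplicity family for the age correlations
        (the 7 marker combinations).
    tissue_test : ``"mannwhitney"`` (unpaired, default) or ``"wilcoxon"``
        (paired signed-rank alternative) for the tissue comparison.
    seed : RNG seed used by any stochastic statistics option.
    """

    pixel_size_um: float | None = None
    channel_order: tuple[str, ...] = CHANNELS
    threshold_mode: str = "iterative"
    merge_distance_um: float = 5.0
    orientation_gate_deg: float | None = 30.0
    min_axis_px: int = 10
    isotropy_elongation: float = 1.5
    small_component_policy: str = "exclude"
    l_min_um: float = 4.0
    w_min_um: float = 4.0
    size_filter_before_merge: bool = False
    marker_size_filter: bool = True
    min_overlap_px: int = 1
    exclusive_combinations: bool = False
    combined_density: str = "pooled"
    mw_mode: str = "auto"
    spearman_permutations: int = 0
    alpha: float = 0.05
    n_family_tests: int = 7
    tissue_test: str = "mannwhitney"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("merge_distance_um", "l_min_um", "w_min_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.small_component_policy not in ("exclude", "merge"):
            raise ValueError("small_component_policy must be 'exclude' or 'merge'")
        if self.threshold_mode not in ("iterative", "naive"):
            raise ValueError("threshold_mode must be 'iterative' or 'naive'")
        if self.combined_density not in ("pooled", "mean"):
            raise ValueError("combined_density must be 'pooled' or 'mean'")
        if self.mw_mode not in ("auto", "exact", "approx"):
            raise ValueError("mw_mode must be 'auto', 'exact' or 'approx'")

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channel_order"] = list(self.channel_order)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "channel_order" in d:
            d["channel_order"] = tuple(d["channel_order"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Short stable digest of the configuration, for output provenance."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:10]

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
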