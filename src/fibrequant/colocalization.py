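"""Marker co-expression scoring of detected fibres by mask overlap.

Each PGP 9.5 fibre is scored for SP, NR2B and NGF expression: the marker
channel is thresholded at its own background mean + 2 SD, cleaned with the
same 4 um size rule that defines a positive signal, and a marker flag is set
when the fibre footprint overlaps the marker mask by at least
``min_overlap_px`` pixels. The three flags generate the seven combinations
reported in the field (three singles, three pairs, one triple), read
non-exclusively by default ("SP/NR2B" = expresses both, NGF free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MARKERS, PipelineConfig
from .detection import (
    CalibratedImage,
    ChannelMask,
    Fibre,
    FibreSet,
    background_stats,
    extract_components,
    make_mask,
)

COMBINATIONS = (
    "SP",
    "NR2B",
    "NGF",
    "SP/NR2B",
    "SP/NGF",
    "NR2B/NGF",
    "SP/NR2B/NGF",
)

__all__ = [
    "COMBINATIONS",
    "ExpressionProfile",
    "combination_membership",
    "build_marker_masks",
    "score_fibre",
    "score_fibres",
    "combination_counts",
]


def combination_membership(
    flags: dict[str, bool], exclusive: bool = False
) -> dict[str, bool]:
    """Map the three marker flags to the 7 combination booleans.

    Non-exclusive (default): a combination is true when *all* its markers are
    expressed, regardless of the others — so a triple-positive fibre counts
    toward every combination. Exclusive: true when the expressed marker set
    equals the combination exactly.
    """
    out: dict[str, bool] = {}
    for comb in COMBINATIONS:
        members = comb.split("/")
        if exclusive:
            out[comb] = all(flags[m] for m in members) and not any(
                flags[m] for m in MARKERS if m not in members
            )
        else:
            out[comb] = all(flags[m] for m in members)
    return out


@dataclass
class ExpressionProfile:
    """Marker expression flags of one fibre plus derived combinations."""

    fibre_id: int
    flags: dict[str, bool]
    exclusive: bool = False

    @property
    def combinations(self) -> dict[str, bool]:
        return combination_membership(self.flags, self.exclusive)


def _clean_marker_mask(
    mask: ChannelMask, pixel_size_um: float, l_min_um: float, w_min_um: float
) -> ChannelMask:
    """Remove mask components failing the positive-signal size rule."""
    from ._geometry import feret_diameters

    cleaned = np.zeros_like(mask.mask)
    l_min_px = l_min_um / pixel_size_um
    w_min_px = w_min_um / pixel_size_um
    for coords in extract_components(mask):
        h = coords[:, 0].max() - coords[:, 0].min() + 1
        w = coords[:, 1].max() - coords[:, 1].min() + 1
        if np.hypot(h, w) < l_min_px or min(h, w) < w_min_px:
            continue
        fmax, fmin = feret_diameters(coords)
        if fmax >= l_min_px and fmin >= w_min_px:
            cleaned[coords[:, 0], coords[:, 1]] = True
    return ChannelMask(
        channel=mask.channel,
        mask=cleaned,
        background_mean=mask.background_mean,
        background_sd=mask.background_sd,
    )


def build_marker_masks(
    image: CalibratedImage, config: PipelineConfig | None = None
) -> dict[str, ChannelMask]:
    """Positive-signal masks for the SP / NR2B / NGF channels.

    Background is estimated per channel. With ``marker_size_filter`` (default)
    components smaller than the 4 um x 4 um signal rule are dropped from each
    mask; no merging is applied to marker masks.
    """
    cfg = config or PipelineConfig()
    masks: dict[str, ChannelMask] = {}
    for marker in MARKERS:
        raster = image.channels[marker]
        mu, sd = background_stats(raster, mode=cfg.threshold_mode)
        mask = make_mask(raster, mu, sd, channel=marker)
        if cfg.marker_size_filter:
            mask = _clean_marker_mask(
                mask, image.pixel_size_um, cfg.l_min_um, cfg.w_min_um
            )
        masks[marker] = mask
    return masks


def score_fibre(
    fibre: Fibre,
    marker_masks: dict[str, ChannelMask],
    min_overlap_px: int = 1,
    exclusive: bool = False,
) -> ExpressionProfile:
    """Expression flags of one fibre from footprint/marker-mask overlap.

    Flag for marker X is true iff at least ``min_overlap_px`` footprint pixels
    fall inside X's positive mask.
    """
    coords = np.asarray(fibre.pixels)
    flags: dict[str, bool] = {}
    for marker in MARKERS:
        m = marker_masks[marker].mask
        if (coords[:, 0].min() < 0 or coords[:, 1].min() < 0
                or coords[:, 0].max() >= m.shape[0]
                or coords[:, 1].max() >= m.shape[1]):
            raise ValueError("fibre footprint outside marker mask bounds")
        overlap = int(np.count_nonzero(m[coords[:, 0], coords[:, 1]]))
        flags[marker] = overlap >= min_overlap_px
    fibre.marker_flags = dict(flags)
    return ExpressionProfile(fibre_id=fibre.fibre_id, flags=flags, exclusive=exclusive)


def score_fibres(
    fibres: FibreSet,
    image: CalibratedImage,
    config: PipelineConfig | None = None,
    marker_masks: dict[str, ChannelMask] | None = None,
) -> list[ExpressionProfile]:
    """Score every fibre of an image; fills each fibre's ``marker_flags``."""
    cfg = config or PipelineConfig()
    masks = marker_masks if marker_masks is not None else build_marker_masks(image, cfg)
    return [
        score_fibre(f, masks, cfg.min_overlap_px, cfg.exclusive_combinations)
        for f in fibres.fibres
    ]


def combination_counts(profiles: list[ExpressionProfile]) -> dict[str, int]:
    """Number of fibres belonging to each of the 7 combinations.

    With the default non-exclusive reading one fibre may count toward several
    combinations, so the monotonicity triple <= pairwise <= single holds.
    """
    counts = {c: 0 for c in COMBINATIONS}
    for p in profiles:
        for c, member in p.combinations.items():
            counts[c] += int(member)
    return counts
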