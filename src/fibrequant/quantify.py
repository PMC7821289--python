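"""Per-image and per-participant aggregation of fibre detections.

Densities are fibre counts normalised to the area (mm^2) of the tissue
actually present on the image; expression frequencies are the fraction of
positive fibres carrying a marker combination. Both are averaged over a
participant's images, counting only images where the quantity is defined:
an image without a tissue contributes no density for it, and an image with
zero fibres in a tissue contributes no frequency (0 fibres is not 0%
expressing). Cohort tables report medians and interquartile ranges
(75th - 25th percentile, linear interpolation between order statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colocalization import COMBINATIONS, ExpressionProfile
from .config import TISSUES
from .detection import FibreSet, TissueLabelMap

SCOPES = ("combined",) + TISSUES  # reporting scopes: both tissues + each alone

__all__ = [
    "SCOPES",
    "TissueQuant",
    "ImageQuant",
    "ParticipantSummary",
    "image_quant_from_counts",
    "quantify_image",
    "summarize_participant",
    "tissue_percentage",
    "cohort_table",
    "summaries_frame",
]


@dataclass
class TissueQuant:
    """Counts, area, density and combination frequencies for one scope."""

    count: int
    area_mm2: float
    density: float | None  # fibres / mm^2; None when the tissue is absent
    comb_counts: dict[str, int]
    frequencies: dict[str, float | None]  # None when count == 0


@dataclass
class ImageQuant:
    participant_id: str
    image_id: str
    scopes: dict[str, TissueQuant]


@dataclass
class ParticipantSummary:
    """Per-participant means over images, per scope.

    ``densities``/``frequencies`` hold means over the images where the
    quantity was defined (``None`` when no image defines it);
    ``mean_counts`` are mean per-image fibre counts (used by the
    tissue-percentage split).
    """

    participant_id: str
    sex: str
    age: float
    n_images: int
    densities: dict[str, float | None]
    frequencies: dict[str, dict[str, float | None]]
    mean_counts: dict[str, float]
    tissues_present: tuple[str, ...] = field(default_factory=tuple)


def image_quant_from_counts(
    participant_id: str,
    image_id: str,
    counts: dict[str, int],
    comb_counts: dict[str, dict[str, int]],
    areas_mm2: dict[str, float],
    combined_density: str = "pooled",
) -> ImageQuant:
    """Assemble an :class:`ImageQuant` from per-tissue counts and areas.

    This is the single formula path for detected data and for ground truth:
    density = count / area (undefined when the tissue is absent), frequency =
    expressing / total (undefined when total is 0). The combined scope pools
    counts and areas across tissues; ``combined_density="mean"`` instead
    averages the per-tissue densities.
    """
    scopes: dict[str, TissueQuant] = {}
    for t in TISSUES:
        area = float(areas_mm2.get(t, 0.0))
        n = int(counts.get(t, 0))
        cc = {c: int(comb_counts.get(t, {}).get(c, 0)) for c in COMBINATIONS}
        density = (n / area) if area > 0 else None
        freqs = {c: (cc[c] / n if n > 0 else None) for c in COMBINATIONS}
        scopes[t] = TissueQuant(n, area, density, cc, freqs)

    total_n = sum(scopes[t].count for t in TISSUES)
    total_area = sum(scopes[t].area_mm2 for t in TISSUES)
    total_cc = {
        c: sum(scopes[t].comb_counts[c] for t in TISSUES) for c in COMBINATIONS
    }
    if combined_density == "mean":
        parts = [scopes[t].density for t in TISSUES if scopes[t].density is not None]
        density = float(np.mean(parts)) if parts else None
    else:
        density = (total_n / total_area) if total_area > 0 else None
    freqs = {c: (total_cc[c] / total_n if total_n > 0 else None) for c in COMBINATIONS}
    scopes["combined"] = TissueQuant(total_n, total_area, density, total_cc, freqs)
    return ImageQuant(participant_id, image_id, scopes)


def quantify_image(
    fibres: FibreSet,
    profiles: list[ExpressionProfile],
    labels: TissueLabelMap,
    combined_density: str = "pooled",
) -> ImageQuant:
    """Per-tissue counts, densities and combination frequencies of one image."""
    if labels is None:
        raise ValueError("tissue label map required")
    prof_by_id = {p.fibre_id: p for p in profiles}
    counts: dict[str, int] = {t: 0 for t in TISSUES}
    comb_counts: dict[str, dict[str, int]] = {
        t: {c: 0 for c in COMBINATIONS} for t in TISSUES
    }
    for f in fibres.fibres:
        counts[f.tissue] += 1
        p = prof_by_id.get(f.fibre_id)
        if p is not None:
            for c, member in p.combinations.items():
                comb_counts[f.tissue][c] += int(member)
    return image_quant_from_counts(
        fibres.participant_id,
        fibres.image_id,
        counts,
        comb_counts,
        labels.area_mm2,
        combined_density=combined_density,
    )


def _mean_defined(values: list[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def summarize_participant(
    quants: list[ImageQuant], sex: str, age: float
) -> ParticipantSummary:
    """Average a participant's image-level quantities over their images."""
    if not quants:
        raise ValueError("participant has no images")
    pid = quants[0].participant_id
    if any(q.participant_id != pid for q in quants):
        raise ValueError("quants mix participants")
    densities = {
        s: _mean_defined([q.scopes[s].density for q in quants]) for s in SCOPES
    }
    frequencies = {
        s: {
            c: _mean_defined([q.scopes[s].frequencies[c] for q in quants])
            for c in COMBINATIONS
        }
        for s in SCOPES
    }
    mean_counts = {
        s: float(np.mean([q.scopes[s].count for q in quants])) for s in SCOPES
    }
    present = tuple(
        t for t in TISSUES if any(q.scopes[t].area_mm2 > 0 for q in quants)
    )
    return ParticipantSummary(
        participant_id=pid,
        sex=sex,
        age=float(age),
        n_images=len(quants),
        densities=densities,
        frequencies=frequencies,
        mean_counts=mean_counts,
        tissues_present=present,
    )


def tissue_percentage(summaries: list[ParticipantSummary]) -> dict[str, float]:
    """Percentage split of positive fibres between the two tissues.

    The cohort-average per-image fibre count in each tissue, divided by the
    cohort-average total count, times 100. The two percentages sum to 100.
    """
    if not summaries:
        raise ValueError("no participants")
    avg = {t: float(np.mean([s.mean_counts[t] for s in summaries])) for t in TISSUES}
    total = sum(avg.values())
    if total <= 0:
        raise ValueError("zero total fibre count")
    return {t: 100.0 * avg[t] / total for t in TISSUES}


def _median_iqr(values: np.ndarray) -> tuple[float, float]:
    q25, q50, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(q50), float(q75 - q25)


def summaries_frame(summaries: list[ParticipantSummary]) -> pd.DataFrame:
    """Long-format participant table: one row per participant x scope."""
    rows = []
    for s in summaries:
        for scope in SCOPES:
            row = {
                "participant_id": s.participant_id,
                "sex": s.sex,
                "age": s.age,
                "n_images": s.n_images,
                "scope": scope,
                "density": s.densities[scope],
                "mean_count": s.mean_counts[scope],
            }
            for c in COMBINATIONS:
                row[f"freq_{c}"] = s.frequencies[scope][c]
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_table(summaries: list[ParticipantSummary]) -> pd.DataFrame:
    """Cohort report: median (IQR) density and frequencies, stratified.

    Strata are All/Men/Women x Combined/Myocytes/Connective. A participant
    enters a tissue stratum only when that tissue appeared on at least one of
    their images; ``n`` is the per-stratum participant count. Frequencies are
    reported in percent.
    """
    if not summaries:
        raise ValueError("no participants")
    rows = []
    sex_groups = {
        "All": summaries,
        "Men": [s for s in summaries if s.sex == "M"],
        "Women": [s for s in summaries if s.sex == "F"],
    }
    for scope in SCOPES:
        for group_name, group in sex_groups.items():
            if scope in TISSUES:
                eligible = [s for s in group if scope in s.tissues_present]
            else:
                eligible = list(group)
            row: dict[str, object] = {
                "scope": scope,
                "group": group_name,
                "n": len(eligible),
            }
            dens = np.array(
                [s.densities[scope] for s in eligible
                 if s.densities[scope] is not None]
            )
            if dens.size:
                med, iqr = _median_iqr(dens)
                row["density_median"] = med
                row["density_iqr"] = iqr
            else:
                row["density_median"] = row["density_iqr"] = np.nan
            for c in COMBINATIONS:
                vals = np.array(
                    [s.frequencies[scope][c] for s in eligible
                     if s.frequencies[scope][c] is not None]
                )
                if vals.size:
                    med, iqr = _median_iqr(100.0 * vals)
                    row[f"{c}_median_pct"] = med
                    row[f"{c}_iqr_pct"] = iqr
                else:
                    row[f"{c}_median_pct"] = row[f"{c}_iqr_pct"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
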