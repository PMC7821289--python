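"""End-to-end pipeline: manifest in, fibre tables / cohort report / stats out.

Ties the detection, colocalization, quantification and statistics stages into
one reproducible run. Every output CSV carries the software version and a
configuration hash; images without any labelled tissue are excluded and
logged, never dropped silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as fio
from .colocalization import score_fibres
from .config import PipelineConfig
from .detection import detect_fibres
from .quantify import (
    ParticipantSummary,
    cohort_table,
    quantify_image,
    summaries_frame,
    summarize_participant,
    tissue_percentage,
)
from .stats import battery_frame, run_study_battery

log = logging.getLogger("fibrequant")

__all__ = ["PipelineResult", "run_pipeline", "validate_inputs", "process_image"]


@dataclass
class PipelineResult:
    fibre_table: pd.DataFrame
    summaries: list[ParticipantSummary]
    summary_table: pd.DataFrame
    cohort_report: pd.DataFrame
    stats_report: pd.DataFrame
    tissue_percent: dict[str, float]
    exclusions: list[dict]


def process_image(image, labels, config: PipelineConfig):
    """Detect, score and quantify a single image."""
    fibres = detect_fibres(image, labels, config)
    profiles = score_fibres(fibres, image, config)
    quant = quantify_image(
        fibres, profiles, labels, combined_density=config.combined_density
    )
    return fibres, profiles, quant


def _fibre_rows(fibres, profiles):
    prof = {p.fibre_id: p for p in profiles}
    for f in fibres.fibres:
        combos = prof[f.fibre_id].combinations if f.fibre_id in prof else {}
        r0, c0 = f.centroid
        yield {
            "participant_id": fibres.participant_id,
            "image_id": fibres.image_id,
            "fibre_id": f.fibre_id,
            "tissue": f.tissue,
            "length_um": round(f.length_um, 3),
            "width_um": round(f.width_um, 3),
            "area_px": f.area_px,
            "centroid_row": round(r0, 2),
            "centroid_col": round(c0, 2),
            "sp": f.marker_flags["SP"],
            "nr2b": f.marker_flags["NR2B"],
            "ngf": f.marker_flags["NGF"],
            **{f"comb_{k.replace('/', '_')}": v for k, v in combos.items()},
        }


def run_pipeline(
    manifest: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    base_dir: str | Path | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full quantification on a manifest of images.

    ``manifest`` is a DataFrame or CSV path with columns participant_id, sex,
    age, image_path, labels_path. Deterministic for fixed inputs and
    configuration. Unreadable images are logged and skipped (the participant
    is flagged in the exclusion log); images whose label map contains no
    tissue are excluded the same way.
    """
    cfg = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest_path = Path(manifest)
        base_dir = base_dir if base_dir is not None else manifest_path.parent
        manifest = fio.read_manifest(manifest_path)
    if manifest.empty:
        raise ValueError("empty manifest")
    base = Path(base_dir) if base_dir is not None else Path(".")

    exclusions: list[dict] = []
    fibre_rows: list[dict] = []
    quants_by_pid: dict[str, list] = {}
    meta_by_pid: dict[str, tuple[str, float]] = {}

    for _, row in manifest.iterrows():
        pid = str(row.participant_id)
        meta_by_pid[pid] = (str(row.sex), float(row.age))
        image_id = str(row.get("image_id", Path(str(row.image_path)).stem))
        try:
            image = fio.read_image(
                base / row.image_path,
                pixel_size_um=cfg.pixel_size_um,
                channel_order=cfg.channel_order,
                participant_id=pid,
                image_id=image_id,
            )
            labels = fio.read_labels(
                base / row.labels_path, pixel_size_um=image.pixel_size_um
            )
        except (OSError, ValueError) as exc:
            log.warning("excluding %s: %s", image_id, exc)
            exclusions.append(
                {"participant_id": pid, "image_id": image_id,
                 "reason": f"unreadable: {exc}"}
            )
            continue
        if not labels.tissues_present():
            log.info("excluding %s: no labelled tissue", image_id)
            exclusions.append(
                {"participant_id": pid, "image_id": image_id,
                 "reason": "no labelled tissue"}
            )
            continue
        fibres, profiles, quant = process_image(image, labels, cfg)
        log.info(
            "%s: %d fibres (%s)", image_id, len(fibres),
            ", ".join(f"{t}={n}" for t, n in fibres.counts.items()),
        )
        fibre_rows.extend(_fibre_rows(fibres, profiles))
        quants_by_pid.setdefault(pid, []).append(quant)

    summaries = []
    for pid, quants in quants_by_pid.items():
        sex, age = meta_by_pid[pid]
        summaries.append(summarize_participant(quants, sex, age))
    for pid in meta_by_pid:
        if pid not in quants_by_pid:
            exclusions.append(
                {"participant_id": pid, "image_id": "",
                 "reason": "no analysable images"}
            )
    if not summaries:
        raise ValueError("no analysable images in manifest")

    result = PipelineResult(
        fibre_table=pd.DataFrame(fibre_rows),
        summaries=summaries,
        summary_table=summaries_frame(summaries),
        cohort_report=cohort_table(summaries),
        stats_report=battery_frame(run_study_battery(summaries, cfg)),
        tissue_percent=tissue_percentage(summaries),
        exclusions=exclusions,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fio.write_csv_report(result.fibre_table, outdir / "fibres.csv", cfg)
        fio.write_csv_report(result.summary_table, outdir / "participants.csv", cfg)
        fio.write_csv_report(result.cohort_report, outdir / "cohort_report.csv", cfg)
        fio.write_csv_report(result.stats_report, outdir / "stats_report.csv", cfg)
        fio.write_csv_report(
            pd.DataFrame(result.exclusions,
                         columns=["participant_id", "image_id", "reason"]),
            outdir / "exclusions.csv", cfg,
        )
        pct = pd.DataFrame(
            [{"tissue": t, "percent": p} for t, p in result.tissue_percent.items()]
        )
        fio.write_csv_report(pct, outdir / "tissue_percent.csv", cfg)
    return result


def validate_inputs(
    manifest: pd.DataFrame,
    config: PipelineConfig | None = None,
    base_dir: str | Path = ".",
) -> list[dict]:
    """Non-mutating input validation; returns a list of problem records.

    Flags missing files, image/label dimension mismatches, missing pixel
    calibration, label maps with values outside {0, 1, 2} and duplicate
    image ids.
    """
    cfg = config or PipelineConfig()
    base = Path(base_dir)
    problems: list[dict] = []
    seen_ids: set[str] = set()
    for _, row in manifest.iterrows():
        image_id = str(row.get("image_id", Path(str(row.image_path)).stem))
        if image_id in seen_ids:
            problems.append({"image_id": image_id, "problem": "duplicate image id"})
        seen_ids.add(image_id)
        try:
            image = fio.read_image(
                base / row.image_path, pixel_size_um=cfg.pixel_size_um,
                channel_order=cfg.channel_order,
            )
        except (OSError, ValueError) as exc:
            problems.append({"image_id": image_id, "problem": str(exc)})
            continue
        try:
            labels = fio.read_labels(
                base / row.labels_path, pixel_size_um=image.pixel_size_um
            )
        except (OSError, ValueError) as exc:
            problems.append({"image_id": image_id, "problem": str(exc)})
            continue
        if labels.labels.shape != image.shape:
            problems.append(
                {"image_id": image_id,
                 "problem": f"dimension mismatch: image {image.shape}, "
                            f"labels {labels.labels.shape}"}
            )
        if not set(map(int, pd.unique(labels.labels.ravel()))) <= {0, 1, 2}:
            problems.append(
                {"image_id": image_id, "problem": "non {0,1,2} label values"}
            )
    return problems
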