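"""File I/O: multichannel TIFFs, label maps, manifests, reports.

Images are stored as (channels, rows, cols) float32 TIFFs with a JSON
ImageDescription carrying the pixel size and channel order; label maps as
uint8 TIFFs (0 = none, 1 = myocyte, 2 = connective). Every CSV report is
stamped with the software version and a configuration hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import CHANNELS, PipelineConfig
from .detection import CalibratedImage, TissueLabelMap

__all__ = [
    "write_image",
    "read_image",
    "write_labels",
    "read_labels",
    "read_manifest",
    "write_csv_report",
    "write_dataset",
]


def write_image(image: CalibratedImage, path: str | Path) -> None:
    order = [ch for ch in CHANNELS if ch in image.channels]
    stack = np.stack([image.channels[ch] for ch in order]).astype(np.float32)
    desc = json.dumps(
        {"pixel_size_um": image.pixel_size_um, "channels": order}
    )
    tifffile.imwrite(path, stack, description=desc, photometric="minisblack")


def read_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel_order: tuple[str, ...] | None = None,
    participant_id: str = "",
    image_id: str = "",
) -> CalibratedImage:
    """Read a multichannel TIFF; config calibration overrides file metadata."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    order = tuple(channel_order or meta.get("channels") or CHANNELS)
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(
            f"{path}: pixel size missing from both configuration and metadata"
        )
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(order):
        raise ValueError(
            f"{path}: {stack.shape[0]} planes but {len(order)} channel names"
        )
    channels = {ch: stack[i].astype(float) for i, ch in enumerate(order)}
    return CalibratedImage(channels, float(px), participant_id, image_id)


def write_labels(labels: TissueLabelMap, path: str | Path) -> None:
    desc = json.dumps({"pixel_size_um": labels.pixel_size_um})
    tifffile.imwrite(path, labels.labels.astype(np.uint8), description=desc)


def read_labels(path: str | Path, pixel_size_um: float | None = None) -> TissueLabelMap:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    px = pixel_size_um
    if px is None and desc:
        try:
            px = json.loads(desc).get("pixel_size_um")
        except (json.JSONDecodeError, TypeError):
            px = None
    if px is None:
        raise ValueError(f"{path}: pixel size missing")
    return TissueLabelMap(arr.astype(np.uint8), float(px))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Participant manifest CSV: participant_id, sex, age, image/label paths."""
    df = pd.read_csv(path, comment="#")
    required = {"participant_id", "sex", "age", "image_path", "labels_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def write_csv_report(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None
) -> None:
    """CSV with provenance header lines (# version, # config hash)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# fibrequant {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config.config_hash()}\n")
        df.to_csv(fh, index=False)


def write_dataset(dataset, outdir: str | Path) -> Path:
    """Write a synthetic dataset to disk: TIFFs, manifest, ground truth.

    Returns the manifest path. Layout::

        outdir/images/<image_id>.tif
        outdir/labels/<image_id>_labels.tif
        outdir/manifest.csv
        outdir/truth_fibres.csv
        outdir/truth_participants.csv
        outdir/sim_config.json
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "labels").mkdir(parents=True, exist_ok=True)

    rows = []
    for image, labelmap in zip(dataset.images, dataset.labelmaps):
        img_path = outdir / "images" / f"{image.image_id}.tif"
        lab_path = outdir / "labels" / f"{image.image_id}_labels.tif"
        write_image(image, img_path)
        write_labels(labelmap, lab_path)
        row = dataset.manifest[dataset.manifest.image_id == image.image_id].iloc[0]
        rows.append(
            {
                "participant_id": row.participant_id,
                "sex": row.sex,
                "age": row.age,
                "image_id": image.image_id,
                "image_path": str(img_path.relative_to(outdir)),
                "labels_path": str(lab_path.relative_to(outdir)),
            }
        )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest_path, index=False)

    dataset.truth.fibre_frame().to_csv(outdir / "truth_fibres.csv", index=False)
    dataset.truth.participants.to_csv(
        outdir / "truth_participants.csv", index=False
    )
    cfg = dataset.config
    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()
    }
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(cfg_dict, fh, indent=2, default=str)
    return manifest_path
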