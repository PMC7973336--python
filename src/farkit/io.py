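"""File formats: TIFF stacks and images, CSV margin tables, JSON records.

All round-trips are lossless for their schemas: raw stacks as multi-page
16-bit TIFF with a JSON metadata sidecar, processed images as 32-bit float
TIFF, margin tables as CSV with a documented header, ROIs as JSON polygon
lists or boolean-mask TIFF, injection records and hotspot reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import polygon as draw_polygon

from .imaging import FarImage, FrameStack, OverlayTransform
from .margins import MARGIN_NAMES
from .phantom import InjectionRecord
from .quant import Roi

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "write_far_image",
    "read_far_image",
    "MARGIN_CSV_COLUMNS",
    "write_margin_table",
    "read_margin_table",
    "write_injection_records",
    "read_injection_records",
    "roi_to_json",
    "roi_from_json",
    "write_roi_mask",
    "read_roi_mask",
    "render_overlay",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame_stack(stack: FrameStack, path) -> None:
    """Write raw frames as multi-page uint16 TIFF plus a JSON sidecar."""
    path = Path(path)
    frames = stack.frames
    if not np.allclose(frames, np.round(frames)):
        raise ValueError("raw frame counts must be integral for 16-bit storage")
    if frames.max() > np.iinfo(np.uint16).max:
        raise ValueError("counts exceed 16-bit range")
    tifffile.imwrite(path, frames.astype(np.uint16), photometric="minisblack")
    meta = {
        "frame_exposure": stack.frame_exposure,
        "pixel_pitch": stack.pixel_pitch,
        "bin_factor": stack.bin_factor,
        "metadata": stack.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_frame_stack(path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar(path).read_text())
    return FrameStack(
        frames=frames.astype(float),
        frame_exposure=meta["frame_exposure"],
        pixel_pitch=meta["pixel_pitch"],
        bin_factor=meta["bin_factor"],
        metadata=meta.get("metadata", {}),
    )


def write_far_image(image: FarImage, path) -> None:
    """Write a processed image as 32-bit float TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, image.radiance.astype(np.float32))
    t = image.overlay_transform
    meta = {
        "pixel_pitch": image.pixel_pitch,
        "overlay": {"scale": t.scale, "translation": list(t.translation)},
        "provenance": image.provenance,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_far_image(path) -> FarImage:
    path = Path(path)
    rad = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    ov = meta.get("overlay", {"scale": 1.0, "translation": [0.0, 0.0]})
    return FarImage(
        radiance=rad,
        pixel_pitch=meta["pixel_pitch"],
        overlay_transform=OverlayTransform(
            scale=ov["scale"], translation=tuple(ov["translation"])
        ),
        provenance=meta.get("provenance", {}),
    )


MARGIN_CSV_COLUMNS = (
    "patient_id",
    "margin",
    "site_rule",
    "invasive_mm",
    "dcis_mm",
    "histo_status",
    "far_status",
)


def write_margin_table(margins: pd.DataFrame, path) -> None:
    missing = set(MARGIN_CSV_COLUMNS) - set(margins.columns)
    if missing:
        raise ValueError(f"margin table missing columns {sorted(missing)}")
    margins.to_csv(path, index=False)


def read_margin_table(path) -> pd.DataFrame:
    """Read and validate a margin-level CSV."""
    df = pd.read_csv(path, dtype={"patient_id": str, "grade": str})
    missing = set(MARGIN_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: margin table missing columns {sorted(missing)}")
    bad = ~df["margin"].isin(MARGIN_NAMES)
    if bad.any():
        raise ValueError(
            f"{path}: unknown margin names at rows {list(df.index[bad][:5])}"
        )
    for col in ("histo_status", "far_status"):
        bad = ~df[col].isin(["positive", "negative"]) & df[col].notna()
        if bad.any():
            raise ValueError(f"{path}: invalid {col} at rows {list(df.index[bad][:5])}")
    return df


def write_injection_records(records: dict[str, InjectionRecord], path) -> None:
    payload = {
        pid: {
            "injected_activity_mbq": r.injected_activity,
            "minutes_post_injection": r.minutes_post_injection,
            "half_life_min": r.half_life,
        }
        for pid, r in records.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_injection_records(path) -> dict[str, InjectionRecord]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for pid, r in payload.items():
        try:
            out[pid] = InjectionRecord(
                injected_activity=r["injected_activity_mbq"],
                minutes_post_injection=r["minutes_post_injection"],
                half_life=r.get("half_life_min", InjectionRecord.half_life),
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: malformed injection record {pid!r}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# ROI exchange


def roi_to_json(roi: Roi, path=None) -> str:
    """Serialise an ROI as label + mask run-lengths (exact) for exchange."""
    flat = roi.mask.ravel()
    # run-length encoding keeps the JSON small and the round trip exact
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    runs = np.diff(np.concatenate([[0], change, [flat.size]])).tolist()
    payload = json.dumps(
        {
            "label": roi.label,
            "margin_tag": roi.margin_tag,
            "shape": list(roi.mask.shape),
            "first_value": bool(flat[0]),
            "runs": runs,
        }
    )
    if path is not None:
        Path(path).write_text(payload)
    return payload


def roi_from_json(payload_or_path) -> Roi:
    text = str(payload_or_path)
    if not text.lstrip().startswith("{"):
        text = Path(text).read_text()
    d = json.loads(text)
    flat = np.zeros(int(np.prod(d["shape"])), dtype=bool)
    val, pos = d["first_value"], 0
    for run in d["runs"]:
        flat[pos : pos + run] = val
        pos += run
        val = not val
    return Roi(label=d["label"], mask=flat.reshape(d["shape"]), margin_tag=d["margin_tag"])


def polygon_roi(label: str, vertices_rc, shape, margin_tag=None) -> Roi:
    """Rasterise a polygon (list of (row, col) vertices) into an ROI mask."""
    v = np.asarray(vertices_rc, dtype=float)
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return Roi(label=label, mask=mask, margin_tag=margin_tag)


def write_roi_mask(roi: Roi, path) -> None:
    tifffile.imwrite(Path(path), roi.mask.astype(np.uint8))


def read_roi_mask(path, label: str, margin_tag=None) -> Roi:
    return Roi(label=label, mask=tifffile.imread(Path(path)) > 0, margin_tag=margin_tag)


def render_overlay(image: FarImage, reference: np.ndarray, path, *, alpha=0.5) -> None:
    """Render the FAR image over a reference photograph as a PNG.

    Display-only: the radiance image is resampled bilinearly into reference
    coordinates via the stored similarity transform; quantification always
    runs on the native grid.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import ndimage as ndi

    t = image.overlay_transform
    ref = np.asarray(reference, dtype=float)
    inv = t.inverse()
    rows = np.arange(ref.shape[0])
    cols = np.arange(ref.shape[1])
    cgrid, rgrid = np.meshgrid(cols, rows)
    src = np.stack(
        [inv.apply(np.stack([rgrid.ravel(), cgrid.ravel()], axis=1))[:, 0],
         inv.apply(np.stack([rgrid.ravel(), cgrid.ravel()], axis=1))[:, 1]]
    )
    resampled = ndi.map_coordinates(image.radiance, src, order=1, mode="constant").reshape(
        ref.shape
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(ref, cmap="gray")
    ax.imshow(resampled, cmap="hot", alpha=alpha)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
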