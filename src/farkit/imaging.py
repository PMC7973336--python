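"""The FAR image-formation chain: binning, spatio-temporal median combination,
Gaussian smoothing, count-to-radiance conversion and overlay registration.

The acquisition protocol takes three 100 s emCCD frames so that any transient
confined to a single frame — chiefly direct 511 keV gamma strikes on the
sensor — occupies at most 9 of the 27 samples in a 3x3 pixel x 3 frame
neighbourhood and is therefore fully rejected by the spatio-temporal median,
regardless of amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FrameStack",
    "FarImage",
    "OverlayTransform",
    "bin_pixels",
    "median_combine",
    "gaussian_smooth",
    "counts_to_radiance",
    "register_overlay",
    "process_stack",
]


@dataclass
class FrameStack:
    """An ordered stack of 2-D emCCD count frames with acquisition metadata."""

    frames: np.ndarray  # (n_frames, h, w)
    frame_exposure: float
    pixel_pitch: float  # um, at the current binning level
    bin_factor: int = 1  # binning already applied to `frames`
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (n>=1, h, w) array")
        if (self.frames < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class OverlayTransform:
    """Similarity transform (isotropic scale + translation) from FAR pixel
    coordinates to reference-photo coordinates.  Analysis always runs in
    native FAR coordinates; the transform is for display only."""

    scale: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.scale == 0:
            raise ValueError("overlay scale must be non-zero")

    def apply(self, xy):
        xy = np.asarray(xy, dtype=float)
        return xy * self.scale + np.asarray(self.translation, dtype=float)

    def inverse(self) -> "OverlayTransform":
        t = np.asarray(self.translation, dtype=float)
        return OverlayTransform(
            scale=1.0 / self.scale, translation=tuple(-t / self.scale)
        )


@dataclass
class FarImage:
    """A processed FAR radiance image (photons/s/cm^2/sr)."""

    radiance: np.ndarray
    pixel_pitch: float  # um after binning
    overlay_transform: OverlayTransform = field(default_factory=OverlayTransform)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.radiance = np.asarray(self.radiance, dtype=float)
        if (self.radiance < 0).any():
            raise ValueError("radiance must be non-negative")

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_pitch / 1000.0) ** 2


def bin_pixels(frame: np.ndarray, bin_factor: int) -> np.ndarray:
    """Sum-bin a frame into ``bin_factor`` x ``bin_factor`` blocks.

    On-camera binning accumulates charge, so output pixels are block *sums*
    and the output pitch is the input pitch times ``bin_factor``.  Trailing
    rows/columns that do not fill a whole block are cropped with a warning.
    """
    if bin_factor < 1 or int(bin_factor) != bin_factor:
        raise ValueError("bin_factor must be a positive integer")
    bin_factor = int(bin_factor)
    frame = np.asarray(frame)
    if bin_factor == 1:
        return frame.copy()
    h, w = frame.shape
    h2, w2 = (h // bin_factor) * bin_factor, (w // bin_factor) * bin_factor
    if (h2, w2) != (h, w):
        warnings.warn(
            f"frame shape {frame.shape} not divisible by {bin_factor}; "
            f"cropping to {(h2, w2)}",
            stacklevel=2,
        )
        frame = frame[:h2, :w2]
    return frame.reshape(h2 // bin_factor, bin_factor, w2 // bin_factor, bin_factor).sum(
        axis=(1, 3)
    )


def median_combine(stack: FrameStack) -> np.ndarray:
    """Combine exactly three frames with a 3x3 pixel x 3 frame median.

    Each output pixel is the median of the 27 values in its 3x3 spatial
    neighbourhood across all three frames; spatial edges use replicate
    padding.  The output is bounded pixel-wise by the neighbourhood min/max,
    and any transient confined to one frame is rejected outright.
    """
    if stack.n_frames != 3:
        raise ValueError(
            f"the acquisition protocol is 3 frames; got {stack.n_frames}"
        )
    arr = stack.frames
    # 'nearest' replicates edges; taking the middle temporal slice makes the
    # 3-wide temporal window cover the three real frames exactly.
    return ndimage.median_filter(arr, size=(3, 3, 3), mode="nearest")[1]


def gaussian_smooth(image: np.ndarray, sigma_px: float = 3.0) -> np.ndarray:
    """Smooth with a normalised discrete Gaussian, truncated at 4 sigma,
    replicate padding."""
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=float), sigma_px, mode="nearest", truncate=4.0
    )


def counts_to_radiance(
    image: np.ndarray,
    settings,
    *,
    bin_factor: int = 1,
) -> np.ndarray:
    """Convert a (possibly binned, median-combined) count image to radiance.

    The inverse of the acquisition gain model: a binned pixel sums
    ``bin_factor**2`` native pixels, each with expected counts
    ``radiance * gain * frame_exposure + dark_offset`` per frame, so

        ``radiance = (counts - dark*bf^2) / (gain * frame_exposure * bf^2)``

    clipped at zero.  Radiance is intensive (per cm^2 per sr) and therefore
    independent of pixel area once the binning factor is divided out.
    """
    if settings.gain <= 0:
        raise ValueError("gain must be > 0")
    if settings.frame_exposure <= 0:
        raise ValueError("frame_exposure must be > 0")
    bf2 = bin_factor**2
    rad = (np.asarray(image, dtype=float) - settings.dark_offset * bf2) / (
        settings.gain * settings.frame_exposure * bf2
    )
    return np.clip(rad, 0.0, None)


def register_overlay(
    far_image: FarImage,
    reference_image: np.ndarray | None,
    scale: float,
    translation: tuple[float, float],
) -> FarImage:
    """Attach the similarity transform mapping FAR pixels to the reference
    photograph.  Display resampling uses bilinear interpolation (see
    :func:`farkit.io.render_overlay`); quantification never resamples."""
    if scale == 0:
        raise ValueError("overlay scale must be non-zero")
    far_image.overlay_transform = OverlayTransform(scale=scale, translation=tuple(translation))
    if reference_image is not None:
        far_image.provenance["reference_shape"] = tuple(np.shape(reference_image))
    return far_image


def process_stack(
    stack: FrameStack,
    settings,
    *,
    bin_factor: int | None = None,
    sigma_px: float = 3.0,
    bin_before_median: bool = True,
) -> FarImage:
    """Run the full processing chain: bin, median-combine, smooth, convert.

    Binning is applied per raw frame before median combination by default
    (on-camera binning semantics); set ``bin_before_median=False`` to combine
    first.  ``sigma_px`` acts on the binned grid (938 um pixels under the
    default 8x8 binning of 117.25 um native pixels).
    """
    bf = settings.bin_factor if bin_factor is None else bin_factor
    if bin_before_median:
        binned = FrameStack(
            frames=np.stack([bin_pixels(f, bf) for f in stack.frames]),
            frame_exposure=stack.frame_exposure,
            pixel_pitch=stack.pixel_pitch * bf,
            bin_factor=stack.bin_factor * bf,
            metadata=stack.metadata,
        )
        combined = median_combine(binned)
        pitch = binned.pixel_pitch
        total_bf = binned.bin_factor
    else:
        combined = bin_pixels(median_combine(stack), bf)
        pitch = stack.pixel_pitch * bf
        total_bf = stack.bin_factor * bf
    smoothed = gaussian_smooth(combined, sigma_px)
    radiance = counts_to_radiance(smoothed, settings, bin_factor=total_bf)
    return FarImage(
        radiance=radiance,
        pixel_pitch=pitch,
        provenance={
            "bin_factor": total_bf,
            "sigma_px": sigma_px,
            "bin_before_median": bin_before_median,
            "frame_exposure": stack.frame_exposure,
            "n_frames": stack.n_frames,
        },
    )
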