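"""Compressed overview frame and pixel-wise perfusion parameter maps.

The cine sequence is first compressed into a single frame by a per-pixel
minimum-intensity projection (contrast is dark, so the MinIP shows every
pixel opacified at any time). The five perfusion maps (CBF, CBV, MTT, TTP,
MAX) are then computed pixel-by-pixel inside the aneurysm ROI by chaining
TDC extraction -> gamma-variate fit -> perfusion parameters; pixels whose
fit fails are excluded via a validity mask and carry NaN, never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .perfusion import (FrameSequence, TDCFitConfig, compute_perfusion_params,
                        extract_tdc, fit_gamma_variate)

__all__ = ["MAP_NAMES", "CompressedFrame", "ParameterMapSet",
           "compress_sequence", "build_maps"]

logger = logging.getLogger(__name__)

MAP_NAMES = ("CBF", "CBV", "MTT", "TTP", "MAX")


@dataclass(frozen=True)
class CompressedFrame:
    """Single-frame summary of a cine run."""

    data: np.ndarray
    method: str = "minip"


@dataclass(frozen=True)
class ParameterMapSet:
    """The five 2D perfusion maps for one case.

    Maps share one shape and one validity mask; invalid pixels are NaN.
    """

    maps: dict[str, np.ndarray]
    validity: np.ndarray
    spacing_mm: float

    def __post_init__(self):
        shapes = {m.shape for m in self.maps.values()} | {self.validity.shape}
        if len(shapes) != 1:
            raise ValueError("all maps must share the validity-mask shape")
        if set(self.maps) != set(MAP_NAMES):
            raise ValueError(f"maps must be keyed by {MAP_NAMES}")

    def to_npz(self, path) -> Path:
        path = Path(path)
        np.savez(path, validity=self.validity,
                 spacing_mm=np.float64(self.spacing_mm),
                 **{k: v for k, v in self.maps.items()})
        return path

    @classmethod
    def from_npz(cls, path) -> "ParameterMapSet":
        with np.load(path) as z:
            return cls({k: z[k] for k in MAP_NAMES}, z["validity"],
                       float(z["spacing_mm"]))

    def write_png_previews(self, directory) -> None:
        """8-bit-scaled 16-bit PNG previews plus the validity mask."""
        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.maps.items():
            finite = arr[np.isfinite(arr)]
            lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 1.0)
            scale = (hi - lo) or 1.0
            img = np.where(np.isfinite(arr), (arr - lo) / scale, 0.0)
            Image.fromarray((img * 65535).astype(np.uint16)).save(
                directory / f"{name}.png")
        Image.fromarray(self.validity.astype(np.uint8) * 255).save(
            directory / "validity.png")


def compress_sequence(frames: FrameSequence) -> CompressedFrame:
    """Per-pixel minimum-intensity projection over time."""
    if frames.n_frames < 1:
        raise ValueError("need at least one frame")
    return CompressedFrame(frames.data.min(axis=0), "minip")


def build_maps(frames: FrameSequence, mask: np.ndarray,
               config: TDCFitConfig | None = None,
               restrict_to_bbox: bool = True) -> ParameterMapSet:
    """Fit every masked pixel and assemble the five perfusion maps.

    Computation is restricted to the mask's bounding box for speed; since
    each pixel's fit depends only on its own curve, the result is
    independent of this optimization (``restrict_to_bbox=False`` computes
    positions from the full frame and must agree exactly).
    """
    config = config or TDCFitConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frames.frame_shape:
        raise ValueError("mask shape must match frame shape")
    if not mask.any():
        raise ValueError("mask is empty")

    if restrict_to_bbox:
        rr, cc = np.nonzero(mask)
        pixels = list(zip(rr.tolist(), cc.tolist()))
    else:
        pixels = [(r, c) for r in range(mask.shape[0])
                  for c in range(mask.shape[1]) if mask[r, c]]

    maps = {k: np.full(mask.shape, np.nan) for k in MAP_NAMES}
    validity = np.zeros(mask.shape, dtype=bool)
    n_invalid = 0
    for r, c in pixels:
        tdc = extract_tdc(frames, (r, c), config.baseline_frames)
        fit = fit_gamma_variate(tdc, config)
        params = compute_perfusion_params(fit, config)
        if not params.valid:
            n_invalid += 1
            continue
        validity[r, c] = True
        for k, v in params.as_dict().items():
            maps[k][r, c] = v

    n_masked = int(mask.sum())
    if n_invalid > 0.5 * n_masked:
        logger.warning("%d/%d masked pixels had invalid fits",
                       n_invalid, n_masked)
    return ParameterMapSet(maps, validity, frames.pixel_spacing_mm)
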