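"""MIP images to binary vessel masks and 1-px centerline skeletons.

The fixed, fully parameterized pipeline is: local contrast equalization
(CLAHE) -> rolling-ball background subtraction -> global Otsu (or local
adaptive) threshold -> small-object removal -> topology-preserving thinning.
All parameters live in the call signatures so a run is reproducible without
interactive choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure, filters, morphology, restoration

from .rf_preprocessing import MIPImage, ValidationError

__all__ = [
    "VesselMask",
    "SkeletonMask",
    "enhance_and_subtract",
    "binarize",
    "skeletonize",
]

DEFAULT_CLAHE_CLIP = 0.01
DEFAULT_BALL_RADIUS_PX = 25
DEFAULT_MIN_OBJECT_AREA_PX = 10


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel mask with physical pixel size."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.mask.ndim != 2 or self.mask.dtype != bool:
            raise ValidationError("mask must be a 2D boolean array")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def area_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass(frozen=True)
class SkeletonMask:
    """1-px-wide centerline mask (8-connectivity), subset of its vessel mask."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.mask.ndim != 2 or self.mask.dtype != bool:
            raise ValidationError("mask must be a 2D boolean array")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")


def enhance_and_subtract(
    mip: MIPImage,
    clahe_clip: float = DEFAULT_CLAHE_CLIP,
    ball_radius_px: int = DEFAULT_BALL_RADIUS_PX,
) -> MIPImage:
    """CLAHE followed by rolling-ball background removal.

    The image is first rescaled to [0, 1] (which absorbs any constant offset),
    locally equalized, and the rolling-ball background estimate subtracted.
    Output is nonnegative.  A constant image maps to zeros.
    """
    if clahe_clip <= 0:
        raise ValidationError("clahe_clip must be positive")
    rows, cols = mip.shape
    if ball_radius_px <= 0 or ball_radius_px >= min(rows, cols):
        raise ValidationError(
            f"ball_radius_px must be in (0, {min(rows, cols)}) for this image"
        )
    img = mip.intensity
    lo, hi = img.min(), img.max()
    if hi == lo:
        return MIPImage(np.zeros_like(img), mip.pixel_size_um)
    scaled = (img - lo) / (hi - lo)
    eq = exposure.equalize_adapthist(scaled, clip_limit=clahe_clip)
    background = restoration.rolling_ball(eq, radius=ball_radius_px)
    out = np.clip(eq - background, 0.0, None)
    return MIPImage(out, mip.pixel_size_um)


def binarize(
    img: MIPImage,
    method: str = "otsu",
    min_object_area_px: int = DEFAULT_MIN_OBJECT_AREA_PX,
    adaptive_block_size: int = 51,
) -> VesselMask:
    """Threshold a MIP into a vessel mask; drop specks below the area floor.

    ``method`` is "otsu" (global) or "adaptive" (local mean threshold with the
    given odd block size).  A constant image cannot be Otsu-thresholded and
    raises "degenerate histogram".
    """
    data = img.intensity
    if method == "otsu":
        if data.min() == data.max():
            raise ValidationError("degenerate histogram: constant image")
        thr = filters.threshold_otsu(data)
        mask = data > thr
    elif method == "adaptive":
        if adaptive_block_size % 2 == 0:
            raise ValidationError("adaptive_block_size must be odd")
        thr = filters.threshold_local(data, block_size=adaptive_block_size)
        mask = data > thr
    else:
        raise ValidationError(f"unknown binarization method: {method!r}")
    if min_object_area_px > 0:
        # max_size semantics: removes objects with area <= max_size
        mask = morphology.remove_small_objects(mask, max_size=min_object_area_px - 1)
    return VesselMask(mask=mask, pixel_size_um=img.pixel_size_um)


def _break_thick_blocks(skel: np.ndarray) -> np.ndarray:
    """Remove redundant pixels from fully set 2x2 blocks.

    Thinning occasionally leaves a 2x2 junction block.  Deleting one pixel of
    such a block keeps the remaining three mutually 8-adjacent; a pixel is
    safe to delete when each of its skeleton neighbors outside the block is
    still 8-adjacent to one of the other block pixels, so connectivity is
    preserved.
    """
    skel = skel.copy()
    rows, cols = skel.shape

    def neighbors(r: int, c: int) -> list[tuple[int, int]]:
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and skel[rr, cc]:
                    out.append((rr, cc))
        return out

    for _ in range(16):  # each pass strictly reduces set pixels
        full = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        br, bc = np.nonzero(full)
        if br.size == 0:
            break
        for r, c in zip(br, bc):
            block = [(r, c), (r, c + 1), (r + 1, c), (r + 1, c + 1)]
            if not all(skel[p] for p in block):
                continue

            def ring_components(cand: tuple[int, int]) -> int:
                """8-connected components of cand's set neighbors (cand removed)."""
                ring = [q for q in neighbors(*cand) if q != cand]
                comps = 0
                seen: set[tuple[int, int]] = set()
                for q in ring:
                    if q in seen:
                        continue
                    comps += 1
                    stack = [q]
                    seen.add(q)
                    while stack:
                        a = stack.pop()
                        for b in ring:
                            if b not in seen and abs(a[0] - b[0]) <= 1 and abs(a[1] - b[1]) <= 1:
                                seen.add(b)
                                stack.append(b)
                return comps

            simple = [cand for cand in block if ring_components(cand) == 1]
            if simple:
                # prefer the simple pixel with the fewest neighbors
                cand = min(simple, key=lambda p: (len(neighbors(*p)), p))
            else:  # fall back to the least-connected pixel of the block
                cand = min(block, key=lambda p: (len(neighbors(*p)), p))
            skel[cand] = False
    return skel


def skeletonize(mask: VesselMask) -> SkeletonMask:
    """Topology-preserving iterative thinning to 1-px centerlines.

    Preserves the number of connected components; an empty mask yields an
    empty skeleton.
    """
    skel = morphology.skeletonize(mask.mask)
    skel = _break_thick_blocks(skel)
    return SkeletonMask(mask=skel, pixel_size_um=mask.pixel_size_um)
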