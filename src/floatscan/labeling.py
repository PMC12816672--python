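"""Headless generation of "ground truth" masks from index rasters.

Replaces an interactive labeling workflow with declarative regions, each
carrying either an absolute index cutoff or a robust (median + k * MAD)
rule, with negate regions forcing known confounders (cloud edges, shadows,
shallow water, noise) to true negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from skimage.draw import polygon as draw_polygon

from .indices import IndexRaster

__all__ = ["LabelRegion", "resolve_threshold", "make_labels", "load_regions"]

MIN_ROBUST_PIXELS = 10


@dataclass(frozen=True)
class LabelRegion:
    """One labeling region.

    geometry: ``(row0, col0, row1, col1)`` half-open pixel box, or an
    ``(N, 2)`` array of polygon vertices in (row, col) image coordinates.
    Exactly one of ``threshold`` (absolute) or ``robust_k`` (median + k*MAD)
    must be set unless ``negate`` is True.  ``floor``: pixels above this
    provisional absolute value are excluded from the robust statistics.
    """

    geometry: tuple[int, int, int, int] | np.ndarray
    threshold: float | None = None
    robust_k: float | None = None
    negate: bool = False
    floor: float = np.inf

    def __post_init__(self) -> None:
        if not self.negate:
            if (self.threshold is None) == (self.robust_k is None):
                raise ValueError("set exactly one of threshold / robust_k")

    def pixel_mask(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        geom = self.geometry
        if isinstance(geom, np.ndarray) or (
            len(geom) and isinstance(geom[0], (list, tuple, np.ndarray))
        ):
            verts = np.asarray(geom, dtype=float)
            if verts.min() < 0 or verts[:, 0].max() > h or verts[:, 1].max() > w:
                raise ValueError("polygon outside image bounds")
            rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
            mask = np.zeros(shape, dtype=bool)
            mask[rr, cc] = True
            return mask
        r0, c0, r1, c1 = geom
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w or r0 >= r1 or c0 >= c1:
            raise ValueError(f"box {geom} outside image bounds {shape}")
        mask = np.zeros(shape, dtype=bool)
        mask[r0:r1, c0:c1] = True
        return mask


def resolve_threshold(afai: IndexRaster, region: LabelRegion) -> float:
    """Resolve a region's rule to a concrete index cutoff.

    Absolute rules return their value.  Robust rules return
    ``median + k * MAD`` over the region's valid pixels at or below the
    provisional floor; deterministic, and requires at least
    ``MIN_ROBUST_PIXELS`` contributing pixels.
    """
    if region.threshold is not None:
        return float(region.threshold)
    sel = region.pixel_mask(afai.values.shape) & afai.valid_mask
    vals = afai.values[sel]
    vals = vals[vals <= region.floor]
    if vals.size == 0:
        raise ValueError("region has no valid pixels for the robust rule")
    if vals.size < MIN_ROBUST_PIXELS:
        raise ValueError(
            f"robust rule needs >= {MIN_ROBUST_PIXELS} valid water pixels, got {vals.size}"
        )
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med + float(region.robust_k) * mad


def make_labels(afai: IndexRaster, regions) -> np.ndarray:
    """Binary truth mask from an index raster and an ordered region list.

    Positive regions set their pixels to ``index > threshold`` (later regions
    override earlier ones); negate regions are applied after all positives
    and force their pixels to 0.  Pixels outside every region are 0.
    """
    regions = list(regions)
    if not regions:
        raise ValueError("need at least one region")
    mask = np.zeros(afai.values.shape, dtype=bool)
    for region in regions:
        if region.negate:
            continue
        sel = region.pixel_mask(mask.shape)
        thr = resolve_threshold(afai, region)
        mask[sel] = (afai.values > thr)[sel] & afai.valid_mask[sel]
    for region in regions:
        if region.negate:
            mask[region.pixel_mask(mask.shape)] = False
    return mask


def load_regions(path) -> list[LabelRegion]:
    """Read a YAML region list (keys: box/polygon, threshold, robust_k, negate, floor)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    regions = []
    for item in raw:
        geom = tuple(item["box"]) if "box" in item else np.asarray(item["polygon"], dtype=float)
        regions.append(
            LabelRegion(
                geometry=geom,
                threshold=item.get("threshold"),
                robust_k=item.get("robust_k"),
                negate=bool(item.get("negate", False)),
                floor=float(item.get("floor", np.inf)),
            )
        )
    return regions
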