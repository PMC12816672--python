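"""Scene-to-model-input preprocessing: band normalization and tiling.

The model consumes 8-layer arrays: the 7 reflectance bands affinely mapped
to [0, 1] by fixed per-band clip ranges, plus the red-edge index clipped to
its own range but left unscaled.  Scenes are cut into fixed-size tiles with
NaN padding at the edges; reassembly is lossless on non-padded cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..indices import compute_afai

__all__ = ["NormalizeParams", "TileSet", "normalize_bands", "denormalize_bands", "tile", "untile"]

#: Default per-band clip range for reflectance layers (dimensionless).
DEFAULT_REFLECTANCE_CLIP = (0.0, 0.25)
#: Clip range for the appended index layer (kept unscaled).
DEFAULT_INDEX_CLIP = (-0.02, 0.1)


@dataclass(frozen=True)
class NormalizeParams:
    """Recorded affine transform parameters, one (lo, hi) per layer.

    Reflectance layers are mapped ``x -> (clip(x, lo, hi) - lo) / (hi - lo)``;
    the index layer is only clipped (``scaled=False``).
    """

    clips: tuple[tuple[float, float], ...]
    scaled: tuple[bool, ...]


def normalize_bands(
    scene,
    reflectance_clip: tuple[float, float] = DEFAULT_REFLECTANCE_CLIP,
    index_clip: tuple[float, float] = DEFAULT_INDEX_CLIP,
    band_clips: dict[float, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, NormalizeParams]:
    """Build the 8-layer model input from a scene.

    Returns ``(stack, params)`` where ``stack`` is (n_bands+1, H, W) with the
    index appended last; invalid pixels are NaN throughout.  ``band_clips``
    overrides the default clip range for specific wavelengths.
    """
    clips = []
    layers = []
    for wl, band in zip(scene.wavelengths, scene.bands):
        lo, hi = (band_clips or {}).get(wl, reflectance_clip)
        if hi <= lo:
            raise ValueError(f"degenerate clip range for {wl} nm")
        x = (np.clip(band, lo, hi) - lo) / (hi - lo)
        layers.append(np.where(scene.valid_mask, x, np.nan))
        clips.append((lo, hi))
    afai = compute_afai(scene)
    lo, hi = index_clip
    layers.append(np.where(scene.valid_mask, np.clip(afai.values, lo, hi), np.nan))
    clips.append((lo, hi))
    params = NormalizeParams(clips=tuple(clips), scaled=tuple([True] * (len(layers) - 1) + [False]))
    return np.stack(layers), params


def denormalize_bands(stack: np.ndarray, params: NormalizeParams) -> np.ndarray:
    """Invert the affine mapping (exact inside the clip ranges)."""
    out = np.empty_like(np.asarray(stack, dtype=float))
    for i, ((lo, hi), scaled) in enumerate(zip(params.clips, params.scaled)):
        out[i] = stack[i] * (hi - lo) + lo if scaled else stack[i]
    return out


@dataclass
class TileSet:
    """Fixed-size tiles of one source array plus reassembly bookkeeping."""

    tiles: np.ndarray  # (T, C, ts, ts), NaN on padded cells
    origins: tuple[tuple[int, int], ...]
    tile_size: int
    source_shape: tuple[int, int]  # (H, W) of the source grid
    pad_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pad_mask is None:
            h, w = self.source_shape
            ts = self.tile_size
            pm = np.zeros((len(self.origins), ts, ts), dtype=bool)
            for k, (r, c) in enumerate(self.origins):
                pm[k, : min(ts, h - r), : min(ts, w - c)] = False
                pm[k, min(ts, h - r) :, :] = True
                pm[k, :, min(ts, w - c) :] = True
            self.pad_mask = pm


def tile(array: np.ndarray, tile_size: int = 256) -> TileSet:
    """Cut a (C, H, W) array into NaN-padded tiles covering the grid."""
    if tile_size < 32:
        raise ValueError("tile_size must be at least 32")
    array = np.asarray(array, dtype=float)
    if array.ndim == 2:
        array = array[None]
    c, h, w = array.shape
    origins = [
        (r, col)
        for r in range(0, h, tile_size)
        for col in range(0, w, tile_size)
    ]
    tiles = np.full((len(origins), c, tile_size, tile_size), np.nan)
    for k, (r, col) in enumerate(origins):
        sub = array[:, r : r + tile_size, col : col + tile_size]
        tiles[k, :, : sub.shape[1], : sub.shape[2]] = sub
    return TileSet(tiles=tiles, origins=tuple(origins), tile_size=tile_size, source_shape=(h, w))


def untile(tileset: TileSet) -> np.ndarray:
    """Reassemble tiles to the source grid, dropping padded cells."""
    h, w = tileset.source_shape
    c = tileset.tiles.shape[1]
    out = np.full((c, h, w), np.nan)
    ts = tileset.tile_size
    for k, (r, col) in enumerate(tileset.origins):
        hh = min(ts, h - r)
        ww = min(ts, w - col)
        out[:, r : r + hh, col : col + ww] = tileset.tiles[k, :, :hh, :ww]
    return out
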