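"""FA type inference from spectral shape and sub-pixel cover by linear unmixing.

The target-minus-water reflectance difference has the same spectral shape as
the endmember spectrum (scaled by the sub-pixel cover chi), so type is
inferred by a shape-only similarity and chi by the ratio of index
differences.  Both steps are exact on noise-free linearly mixed pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .indices import IndexRaster, afai_from_spectrum, compute_afai, delta_index
from .scenes import Scene, SpectralLibrary

__all__ = [
    "DeltaSpectrum",
    "Detection",
    "extract_delta",
    "classify_type",
    "unmix_chi",
    "quantify_scene",
]


@dataclass
class DeltaSpectrum:
    """Target-minus-water reflectance difference at one pixel."""

    wavelengths: tuple[float, ...]
    delta: np.ndarray
    source_pixel: tuple[int, int]
    water_ref_pixel: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if len(self.wavelengths) != self.delta.size:
            raise ValueError("wavelengths/delta length mismatch")
        if self.water_ref_pixel is not None and tuple(self.water_ref_pixel) == tuple(
            self.source_pixel
        ):
            raise ValueError("water reference pixel must differ from source pixel")


@dataclass
class Detection:
    """Per-scene detection product: mask, sub-pixel cover, type, score.

    ``fa_type`` holds integer codes indexed into ``type_legend``; -1 off-mask.
    ``observed`` marks pixels validly observed in the source scene (used by
    compositing to exclude clouds/invalid pixels from the mean denominator).
    """

    mask: np.ndarray
    chi: np.ndarray
    fa_type: np.ndarray
    similarity: np.ndarray
    type_legend: tuple[str, ...]
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_clipped: int = 0
    chi_mode: str = "exact"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.chi = np.asarray(self.chi, dtype=float)
        if self.observed is None:
            self.observed = np.ones_like(self.mask)
        self.observed = np.asarray(self.observed, dtype=bool)
        on = self.mask
        if np.nanmin(np.where(on, self.chi, 0.0)) < 0 or np.nanmax(
            np.where(on, self.chi, 0.0)
        ) > 1:
            raise ValueError("chi outside [0, 1] on the detection mask")
        if ((self.fa_type >= 0) != on).any():
            raise ValueError("fa_type must be coded exactly on the mask")

    def type_labels(self) -> np.ndarray:
        """Object array of type names, '' off-mask."""
        out = np.full(self.mask.shape, "", dtype=object)
        for code, name in enumerate(self.type_legend):
            out[self.fa_type == code] = name
        return out


def extract_delta(
    scene: Scene,
    pixel: tuple[int, int],
    fa_mask: np.ndarray,
    water_window: int = 11,
) -> DeltaSpectrum:
    """Target spectrum minus the median nearby-water spectrum, per band.

    The median is taken over valid, non-FA pixels within a
    ``water_window`` x ``water_window`` neighbourhood of ``pixel``.  A flat
    (aerosol-like) offset common to target and neighbourhood cancels exactly.
    """
    r, c = pixel
    h, wd = scene.shape
    half = water_window // 2
    r0, r1 = max(0, r - half), min(h, r + half + 1)
    c0, c1 = max(0, c - half), min(wd, c + half + 1)
    window_ok = scene.valid_mask[r0:r1, c0:c1] & ~np.asarray(fa_mask, dtype=bool)[r0:r1, c0:c1]
    if not window_ok.any():
        raise ValueError(f"no valid water reference within {water_window} px of {pixel}")
    sub = scene.bands[:, r0:r1, c0:c1]
    water_spec = np.median(sub[:, window_ok], axis=1)
    delta = scene.bands[:, r, c] - water_spec
    # representative reference pixel: first valid water cell in the window
    wr, wc = np.argwhere(window_ok)[0]
    return DeltaSpectrum(
        wavelengths=scene.wavelengths,
        delta=delta,
        source_pixel=(r, c),
        water_ref_pixel=(int(r0 + wr), int(c0 + wc)),
    )


def _shape_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of mean-subtracted spectra (flat offsets cancel)."""
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return -np.inf
    return float(a @ b / (na * nb))


def classify_type(
    delta: DeltaSpectrum,
    library: SpectralLibrary,
    water_spectrum: np.ndarray | None = None,
) -> tuple[str, float]:
    """Best-matching FA type for a difference spectrum, plus its similarity.

    Shape similarity is the cosine of mean-subtracted, unit-normalised
    spectra, so any positive scaling of ``delta`` (i.e. the unknown chi)
    leaves the answer unchanged.  When ``water_spectrum`` is given, library
    candidates are compared as ``endmember - water`` (the exact shape of a
    linear mixture difference); otherwise the endmember spectrum itself is
    used, which assumes water reflectance is small against the endmember.
    """
    d = np.asarray(delta.delta, dtype=float)
    if not np.any(d != 0):
        raise ValueError("all-zero difference spectrum cannot be classified")
    best_type, best_sim = None, -np.inf
    for entry in library:
        candidate = entry.reflectance
        if water_spectrum is not None:
            candidate = candidate - np.asarray(water_spectrum, dtype=float)
        sim = _shape_similarity(d, candidate)
        if sim > best_sim:
            best_type, best_sim = entry.fa_type, sim
    return best_type, best_sim


def unmix_chi(
    afai_target: float,
    afai_water: float,
    afai_endmember: float,
    mode: str = "exact",
) -> float:
    """Sub-pixel fractional cover from index values.

    ``mode='exact'`` uses ``(target - water) / (endmember - water)``;
    ``mode='approx'`` uses the open-water shortcut
    ``(target - water) / endmember``.  The result is clipped to [0, 1].
    """
    if afai_endmember <= 0:
        raise ValueError("endmember index must be positive")
    num = delta_index(afai_target, afai_water)
    if mode == "exact":
        den = afai_endmember - afai_water
        if den <= 0:
            raise ValueError("endmember index must exceed the water index in exact mode")
    elif mode == "approx":
        den = afai_endmember
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(np.clip(num / den, 0.0, 1.0))


def quantify_scene(
    scene: Scene,
    fa_mask: np.ndarray,
    library: SpectralLibrary,
    water_window: int = 11,
    chi_mode: str = "exact",
    use_water_shape: bool = True,
    index: IndexRaster | None = None,
) -> Detection:
    """Type and chi for every masked pixel of a scene.

    For each FA pixel: extract the difference spectrum against nearby water,
    classify its shape against the library, then unmix chi from the index
    difference using the chosen type's endmember index constant.
    """
    fa_mask = np.asarray(fa_mask, dtype=bool)
    if index is None:
        index = compute_afai(scene)
    legend = library.types
    code = {t: i for i, t in enumerate(legend)}
    chi = np.zeros(scene.shape, dtype=float)
    types = np.full(scene.shape, -1, dtype=np.int16)
    sims = np.full(scene.shape, np.nan, dtype=float)
    n_clipped = 0
    half = water_window // 2
    h, w = scene.shape
    for r, c in np.argwhere(fa_mask & scene.valid_mask):
        dspec = extract_delta(scene, (int(r), int(c)), fa_mask, water_window)
        water_spec = scene.bands[:, r, c] - dspec.delta
        fa_type, sim = classify_type(
            dspec, library, water_spectrum=water_spec if use_water_shape else None
        )
        # water index from the same reference spectrum, per-pixel
        afai_w = afai_from_spectrum(water_spec, scene.wavelengths)
        afai_t = float(index.values[r, c])
        raw = (afai_t - afai_w) / (
            (library[fa_type].afai_endmember - afai_w)
            if chi_mode == "exact"
            else library[fa_type].afai_endmember
        )
        if raw < 0 or raw > 1:
            n_clipped += 1
        chi[r, c] = unmix_chi(afai_t, afai_w, library[fa_type].afai_endmember, mode=chi_mode)
        types[r, c] = code[fa_type]
        sims[r, c] = sim
    return Detection(
        mask=fa_mask & scene.valid_mask,
        chi=chi,
        fa_type=types,
        similarity=sims,
        type_legend=legend,
        observed=scene.valid_mask.copy(),
        n_clipped=n_clipped,
        chi_mode=chi_mode,
    )
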