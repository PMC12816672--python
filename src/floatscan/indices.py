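"""Baseline-subtraction spectral indices for floating-algae detection.

The central quantity is a red-edge index: reflectance at an NIR wavelength
referenced against the linear baseline drawn between a red and a longer-NIR
wavelength.  The index is linear in the input spectrum and invariant to any
spectrally flat offset, which is what makes sub-pixel linear unmixing of the
index exact (see :mod:`floatscan.unmixing`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_LAMBDAS",
    "IndexRaster",
    "afai_from_spectrum",
    "compute_afai",
    "delta_index",
    "estimate_water_index",
]

#: Nominal wavelength triple (red, red-edge, NIR) in nanometres.
DEFAULT_LAMBDAS = (667.0, 748.0, 869.0)

#: Tolerance (nm) when matching scene wavelengths against nominal centres.
BAND_MATCH_TOL_NM = 10.0


class BandNotFoundError(KeyError):
    """Raised when a scene has no band within tolerance of a wavelength."""

    def __init__(self, wavelength: float, available) -> None:
        self.wavelength = float(wavelength)
        super().__init__(
            f"no band within {BAND_MATCH_TOL_NM:g} nm of {wavelength:g} nm "
            f"(available: {list(np.asarray(available, dtype=float))})"
        )


@dataclass
class IndexRaster:
    """A single-layer index raster with provenance metadata.

    Attributes
    ----------
    values
        2-D float array; NaN where any contributing band was invalid.
    wavelengths_used
        The (lambda1, lambda2, lambda3) triple actually used, nm.
    valid_mask
        Boolean raster, True where ``values`` is defined.
    """

    values: np.ndarray
    wavelengths_used: tuple[float, float, float]
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        l1, l2, l3 = self.wavelengths_used
        if not (l1 < l2 < l3):
            raise ValueError(f"wavelengths must be strictly increasing, got {self.wavelengths_used}")
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.values.shape:
            raise ValueError("valid_mask shape mismatch")


def match_band(wavelengths, target: float, tol: float = BAND_MATCH_TOL_NM) -> int:
    """Return the index of the band nearest ``target`` within ``tol`` nm."""
    wl = np.asarray(wavelengths, dtype=float)
    i = int(np.argmin(np.abs(wl - target)))
    if abs(wl[i] - target) > tol:
        raise BandNotFoundError(target, wl)
    return i


def afai_from_spectrum(reflectance, wavelengths, lambdas=DEFAULT_LAMBDAS) -> float:
    """Evaluate the index on a single spectrum (1-D reflectance array)."""
    refl = np.asarray(reflectance, dtype=float)
    wl = np.asarray(wavelengths, dtype=float)
    i1, i2, i3 = (match_band(wl, lam) for lam in lambdas)
    l1, l2, l3 = wl[i1], wl[i2], wl[i3]
    ratio = (l2 - l1) / (l3 - l2)
    return float(refl[..., i2] - (refl[..., i1] + ratio * (refl[..., i3] - refl[..., i1])))


def compute_afai(scene, lambdas=None) -> IndexRaster:
    """Compute the red-edge index raster from a multiband scene.

    Parameters
    ----------
    scene : Scene
        Must carry bands at (or within 10 nm of) the requested triple.
    lambdas : tuple of 3 floats, optional
        Wavelength triple; defaults to (667, 748, 869) nm.

    Returns
    -------
    IndexRaster
        NaN wherever the scene's valid mask is False.
    """
    if lambdas is None:
        lambdas = DEFAULT_LAMBDAS
    wl = np.asarray(scene.wavelengths, dtype=float)
    i1, i2, i3 = (match_band(wl, lam) for lam in lambdas)
    l1, l2, l3 = wl[i1], wl[i2], wl[i3]
    if not (l1 < l2 < l3):
        raise ValueError("resolved wavelengths not strictly increasing")
    r1, r2, r3 = scene.bands[i1], scene.bands[i2], scene.bands[i3]
    ratio = (l2 - l1) / (l3 - l2)
    values = r2 - (r1 + ratio * (r3 - r1))
    values = np.where(scene.valid_mask, values, np.nan)
    return IndexRaster(values=values, wavelengths_used=(l1, l2, l3))


def delta_index(afai_target: float, afai_water: float) -> float:
    """Target-minus-water index difference (the unmixing numerator)."""
    if not (np.isfinite(afai_target) and np.isfinite(afai_water)):
        raise ValueError("both index values must be finite")
    return float(afai_target) - float(afai_water)


def estimate_water_index(
    index: IndexRaster,
    fa_mask: np.ndarray | None = None,
    pixel: tuple[int, int] | None = None,
    window: int = 11,
) -> float:
    """Estimate the background-water index value.

    Median of the index over valid non-FA pixels — over the whole raster, or
    over a ``window`` x ``window`` neighbourhood centred at ``pixel`` when one
    is given.  Callers that prefer the common open-water approximation can
    simply pass 0 downstream instead.
    """
    vals = index.values
    ok = index.valid_mask.copy()
    if fa_mask is not None:
        ok &= ~np.asarray(fa_mask, dtype=bool)
    if pixel is not None:
        r, c = pixel
        h = window // 2
        sel = np.zeros_like(ok)
        sel[max(0, r - h) : r + h + 1, max(0, c - h) : c + h + 1] = True
        ok &= sel
    if not ok.any():
        raise ValueError("no valid water pixels available for the water-index estimate")
    return float(np.median(vals[ok]))
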