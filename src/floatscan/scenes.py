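"""Synthetic reflectance scenes, truth fields, and monthly area series.

Everything downstream of raw imagery (index computation, labeling, model
training, unmixing, compositing, trend statistics) is exercised against
scenes built here.  FA patches are implanted with the exact linear mixing
model the unmixing stage inverts, so noise-free round trips are exact; a
flat per-scene aerosol offset is shared by target and neighbouring water
pixels so that baseline-index differencing cancels it by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .indices import DEFAULT_LAMBDAS, afai_from_spectrum

__all__ = [
    "FA_TYPES",
    "MODIS_WAVELENGTHS",
    "DEFAULT_WATER_SPECTRUM",
    "EndmemberSpectrum",
    "SpectralLibrary",
    "SceneTruth",
    "Scene",
    "SceneParams",
    "default_library",
    "generate_scene",
    "generate_area_series",
]

#: Canonical FA type labels, macroalgae first.
FA_TYPES = (
    "sargassum_fluitans_natans",
    "ulva_prolifera",
    "sargassum_horneri",
    "trichodesmium",
    "green_noctiluca",
    "dinoflagellate",
    "cyanobacteria",
)

MACROALGAE_TYPES = ("sargassum_fluitans_natans", "ulva_prolifera", "sargassum_horneri")
MICROALGAE_TYPES = ("trichodesmium", "green_noctiluca", "dinoflagellate", "cyanobacteria")

#: Sensor band centres (nm) used throughout.
MODIS_WAVELENGTHS = (412.0, 443.0, 488.0, 547.0, 667.0, 748.0, 869.0)

#: Blue-peaked clear-water background reflectance on the band set above.
DEFAULT_WATER_SPECTRUM = np.array([0.025, 0.023, 0.019, 0.011, 0.004, 0.002, 0.001])

CONFOUNDER_CODES = {"none": 0, "cloud": 1, "shadow": 2, "glint": 3, "shallow": 4}


@dataclass(frozen=True)
class EndmemberSpectrum:
    """A pure-material reflectance spectrum for one FA type."""

    fa_type: str
    wavelengths: tuple[float, ...]
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        refl = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "reflectance", refl)
        if len(self.wavelengths) != refl.size:
            raise ValueError("wavelengths/reflectance length mismatch")
        if refl.min() < 0 or refl.max() > 1:
            raise ValueError(f"reflectance outside [0, 1] for {self.fa_type}")
        if self.afai_endmember <= 0:
            raise ValueError(f"endmember index must be positive for {self.fa_type}")

    @property
    def afai_endmember(self) -> float:
        """Endmember red-edge index, computed from the spectrum itself."""
        return afai_from_spectrum(self.reflectance, self.wavelengths, DEFAULT_LAMBDAS)


class SpectralLibrary:
    """An ordered collection of endmember spectra keyed by FA type."""

    def __init__(self, entries) -> None:
        self._entries: dict[str, EndmemberSpectrum] = {}
        for e in entries:
            if e.fa_type in self._entries:
                raise ValueError(f"duplicate fa_type {e.fa_type!r}")
            self._entries[e.fa_type] = e
        if not self._entries:
            raise ValueError("empty spectral library")
        wls = {e.wavelengths for e in self._entries.values()}
        if len(wls) != 1:
            raise ValueError("all library entries must share one wavelength grid")

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    def __contains__(self, fa_type: str) -> bool:
        return fa_type in self._entries

    def __getitem__(self, fa_type: str) -> EndmemberSpectrum:
        try:
            return self._entries[fa_type]
        except KeyError:
            raise KeyError(f"unknown fa_type {fa_type!r}; known: {self.types}") from None

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(self._entries)

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return next(iter(self._entries.values())).wavelengths

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"fa_type": e.fa_type, "wavelength_nm": wl, "reflectance": r}
            for e in self
            for wl, r in zip(e.wavelengths, e.reflectance)
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralLibrary":
        df = pd.read_csv(path)
        entries = []
        for fa_type, grp in df.groupby("fa_type", sort=False):
            grp = grp.sort_values("wavelength_nm")
            entries.append(
                EndmemberSpectrum(
                    fa_type=str(fa_type),
                    wavelengths=tuple(grp["wavelength_nm"].astype(float)),
                    reflectance=grp["reflectance"].to_numpy(dtype=float),
                )
            )
        return cls(entries)

    def pairwise_min_angle(self) -> float:
        """Smallest pairwise spectral angle (radians) between mean-subtracted entries."""
        specs = [e.reflectance - e.reflectance.mean() for e in self]
        angles = []
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                a, b = specs[i], specs[j]
                cosv = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
                angles.append(np.arccos(np.clip(cosv, -1.0, 1.0)))
        return float(min(angles)) if angles else np.inf


# Seven spectra with elevated red-edge reflectance and deliberately distinct
# visible/NIR structure so shape classification stays reliable under noise:
# each type carries one dominant diagnostic feature (NIR plateau, green peak,
# blue-green shoulder, blue backscatter, low-NIR green, red peak, 443 peak
# with collapsed 869).  Pairwise mean-subtracted angles are all > 0.7 rad.
_DEFAULT_ENDMEMBERS = {
    "sargassum_fluitans_natans": [0.020, 0.030, 0.040, 0.060, 0.050, 0.360, 0.330],
    "ulva_prolifera":            [0.020, 0.040, 0.070, 0.400, 0.050, 0.300, 0.100],
    "sargassum_horneri":         [0.040, 0.060, 0.300, 0.080, 0.110, 0.300, 0.260],
    "trichodesmium":             [0.400, 0.280, 0.120, 0.100, 0.060, 0.220, 0.160],
    "green_noctiluca":           [0.030, 0.060, 0.300, 0.200, 0.050, 0.140, 0.060],
    "dinoflagellate":            [0.040, 0.050, 0.070, 0.100, 0.380, 0.300, 0.120],
    "cyanobacteria":             [0.120, 0.300, 0.200, 0.140, 0.100, 0.280, 0.050],
}


def default_library(min_pairwise_angle: float = 0.5) -> SpectralLibrary:
    """Built-in endmember library covering all seven FA types.

    Every entry has a positive red-edge index and the pairwise
    (mean-subtracted) spectral angles are at least ``min_pairwise_angle``
    radians, so the types are mutually distinguishable by shape.
    """
    lib = SpectralLibrary(
        EndmemberSpectrum(
            fa_type=t, wavelengths=MODIS_WAVELENGTHS, reflectance=np.asarray(v)
        )
        for t, v in _DEFAULT_ENDMEMBERS.items()
    )
    if lib.pairwise_min_angle() < min_pairwise_angle:
        raise ValueError("default library fails the pairwise-angle requirement")
    return lib


@dataclass
class SceneTruth:
    """Ground-truth rasters carried alongside a synthetic scene."""

    fa_mask: np.ndarray
    fa_type_map: np.ndarray  # object array of type labels, "" off-mask
    chi_map: np.ndarray
    confounder_map: np.ndarray  # int-coded per CONFOUNDER_CODES

    def __post_init__(self) -> None:
        self.fa_mask = np.asarray(self.fa_mask, dtype=bool)
        self.chi_map = np.asarray(self.chi_map, dtype=float)
        if not np.array_equal(self.chi_map > 0, self.fa_mask):
            raise ValueError("chi_map must be positive exactly on fa_mask")
        if ((self.fa_type_map != "") != self.fa_mask).any():
            raise ValueError("fa_type_map must be set exactly on fa_mask")
        if (self.fa_mask & (self.confounder_map != 0)).any():
            raise ValueError("FA and confounder labels may not overlap")


@dataclass
class Scene:
    """A multiband reflectance raster with geometry and optional truth.

    ``bands`` is (n_bands, height, width); layer order follows
    ``wavelengths`` (strictly increasing, nm).
    """

    bands: np.ndarray
    wavelengths: tuple[float, ...]
    pixel_area: float = 1.0  # km^2 per pixel
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    truth: SceneTruth | None = None

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=float)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(self.wavelengths):
            raise ValueError("bands must be (n_bands, H, W) matching wavelengths")
        wl = np.asarray(self.wavelengths, dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.bands.shape[1:], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.bands.shape[1:]:
            raise ValueError("valid_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bands.shape[1:]

    def truth_area_km2(self) -> float:
        """Bookkept FA area: integral of the truth chi field times pixel area."""
        if self.truth is None:
            raise ValueError("scene has no truth")
        return float(self.truth.chi_map.sum() * self.pixel_area)


@dataclass(frozen=True)
class SceneParams:
    """Configuration for :func:`generate_scene`.

    chi_range draws per-pixel sub-pixel cover uniformly; the default keeps
    most FA pixels below 1% cover, matching the weak-feature regime the
    detector is designed for.  Confounder fractions are approximate areal
    fractions of the scene.
    """

    n_patches: int = 10
    patch_radius: tuple[int, int] = (1, 4)
    fa_types: tuple[str, ...] | None = None  # None -> sample from library
    chi_range: tuple[float, float] = (0.002, 0.01)
    chi_fixed: float | None = None  # overrides chi_range when set
    noise_sd: float = 0.0
    water_spectrum: np.ndarray | None = None
    aerosol_range: tuple[float, float] = (0.0, 0.005)
    cloud_fraction: float = 0.0
    shadow_fraction: float = 0.0
    glint_fraction: float = 0.0
    shallow_fraction: float = 0.0
    pixel_area: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.chi_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError(f"chi_range outside [0, 1]: {self.chi_range}")
        if self.chi_fixed is not None and not (0 <= self.chi_fixed <= 1):
            raise ValueError(f"chi outside [0, 1]: {self.chi_fixed}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _grow_blob(rng, h, w, radius) -> np.ndarray:
    """A small connected pixel blob: a disc nucleus plus a random-walk fringe."""
    r0 = rng.integers(radius, h - radius) if h > 2 * radius else h // 2
    c0 = rng.integers(radius, w - radius) if w > 2 * radius else w // 2
    rr, cc = np.mgrid[0:h, 0:w]
    blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    r, c = r0, c0
    for _ in range(radius * 4):
        dr, dc = rng.integers(-1, 2, size=2)
        r = int(np.clip(r + dr, 0, h - 1))
        c = int(np.clip(c + dc, 0, w - 1))
        blob[r, c] = True
    return blob


def _scatter_fraction(rng, h, w, fraction, radius=3) -> np.ndarray:
    """Random blobs covering roughly ``fraction`` of the scene."""
    mask = np.zeros((h, w), dtype=bool)
    target = fraction * h * w
    guard = 0
    while mask.sum() < target and guard < 1000:
        mask |= _grow_blob(rng, h, w, rng.integers(max(1, radius - 1), radius + 2))
        guard += 1
    return mask


def generate_scene(
    width: int,
    height: int,
    library: SpectralLibrary,
    params: SceneParams | None = None,
    seed: int = 0,
) -> Scene:
    """Generate a synthetic multiband scene with implanted FA patches.

    FA pixels obey the linear mixing model exactly before noise:
    ``R(l) = chi * R_fa(l) + (1 - chi) * R_water(l) + aerosol`` with the flat
    aerosol offset shared by every pixel of the scene.  Identical
    ``(params, seed)`` produce bit-identical output.

    Raises
    ------
    KeyError
        If ``params.fa_types`` names a type absent from ``library``.
    """
    if params is None:
        params = SceneParams()
    if width < 64 or height < 64:
        raise ValueError("scene must be at least 64 x 64 pixels")
    fa_types = params.fa_types if params.fa_types is not None else library.types
    for t in fa_types:
        if t not in library:
            raise KeyError(f"unknown fa_type {t!r}; library has {library.types}")

    rng = np.random.default_rng(seed)
    h, w = height, width
    wl = library.wavelengths
    nb = len(wl)
    water = (
        np.asarray(params.water_spectrum, dtype=float)
        if params.water_spectrum is not None
        else DEFAULT_WATER_SPECTRUM.copy()
    )
    if water.size != nb:
        raise ValueError("water spectrum length must match library wavelengths")

    aerosol = rng.uniform(*params.aerosol_range)
    bands = np.broadcast_to(water[:, None, None], (nb, h, w)).copy()

    # confounders first; FA placement avoids them so labels never overlap
    confounder = np.zeros((h, w), dtype=np.int8)
    if params.cloud_fraction > 0:
        m = _scatter_fraction(rng, h, w, params.cloud_fraction, radius=4)
        bands[:, m] = bands[:, m] + rng.uniform(0.15, 0.35)
        confounder[m] = CONFOUNDER_CODES["cloud"]
    if params.shadow_fraction > 0:
        m = _scatter_fraction(rng, h, w, params.shadow_fraction, radius=3) & (confounder == 0)
        bands[:, m] = bands[:, m] * rng.uniform(0.4, 0.7)
        confounder[m] = CONFOUNDER_CODES["shadow"]
    if params.glint_fraction > 0:
        m = _scatter_fraction(rng, h, w, params.glint_fraction, radius=4) & (confounder == 0)
        bands[:, m] = bands[:, m] + rng.uniform(0.02, 0.06)
        confounder[m] = CONFOUNDER_CODES["glint"]
    if params.shallow_fraction > 0:
        m = _scatter_fraction(rng, h, w, params.shallow_fraction, radius=3) & (confounder == 0)
        # bottom reflectance raises green/red more than blue
        lift = np.linspace(0.002, 0.02, nb)
        bands[:, m] = bands[:, m] + lift[:, None]
        confounder[m] = CONFOUNDER_CODES["shallow"]

    fa_mask = np.zeros((h, w), dtype=bool)
    chi_map = np.zeros((h, w), dtype=float)
    type_map = np.full((h, w), "", dtype=object)
    lo, hi = params.patch_radius
    for _ in range(params.n_patches):
        radius = int(rng.integers(lo, hi + 1))
        blob = _grow_blob(rng, h, w, radius) & (confounder == 0) & ~fa_mask
        if not blob.any():
            continue
        fa_type = fa_types[int(rng.integers(len(fa_types)))]
        endmember = library[fa_type].reflectance
        if params.chi_fixed is not None:
            chi = np.full(int(blob.sum()), params.chi_fixed)
        else:
            chi = rng.uniform(params.chi_range[0], params.chi_range[1], size=int(blob.sum()))
        idx = np.flatnonzero(blob)
        rr, cc = np.unravel_index(idx, (h, w))
        bands[:, rr, cc] = chi[None, :] * endmember[:, None] + (1.0 - chi[None, :]) * water[:, None]
        fa_mask[rr, cc] = True
        chi_map[rr, cc] = chi
        type_map[rr, cc] = fa_type

    bands += aerosol
    if params.noise_sd > 0:
        bands = bands + rng.normal(0.0, params.noise_sd, size=bands.shape)

    truth = SceneTruth(
        fa_mask=fa_mask, fa_type_map=type_map, chi_map=chi_map, confounder_map=confounder
    )
    return Scene(
        bands=bands,
        wavelengths=wl,
        pixel_area=params.pixel_area,
        valid_mask=np.ones((h, w), dtype=bool),
        truth=truth,
    )


def generate_area_series(
    n_months: int,
    seasonal_amplitude: float,
    trend: float,
    noise_sd: float,
    peak_month: int = 6,
    seed: int = 0,
    offset: float = 0.0,
    fa_type: str = "trichodesmium",
    zone: int = 1,
    start_year: int = 2003,
):
    """Monthly FA-area series: seasonal cosine + linear trend + noise.

    ``area(t) = max(0, offset + A cos(2 pi (month - peak_month)/12) + trend*t
    + N(0, noise_sd))`` for month index ``t = 0..n_months-1``.  Returns an
    :class:`floatscan.compositing.AreaSeries`.
    """
    from .compositing import AreaSeries

    if n_months < 24:
        raise ValueError("need at least 24 months")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 1 <= peak_month <= 12:
        raise ValueError("peak_month must be in 1..12")
    rng = np.random.default_rng(seed)
    t = np.arange(n_months)
    month = (t % 12) + 1
    year = start_year + t // 12
    seasonal = seasonal_amplitude * np.cos(2 * np.pi * (month - peak_month) / 12.0)
    values = offset + seasonal + trend * t
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_months)
    values = np.maximum(values, 0.0)
    df = pd.DataFrame(
        {"year": year, "month": month, "fa_type": fa_type, "zone": zone, "area_km2": values}
    )
    return AreaSeries(df)
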