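"""Synthetic hyperspectral wood-section scenes with known ground truth.

Scenes mimic the structure the multiset analysis assumes: a small stack
of annual-ring section images sharing one wavenumber axis, each pixel
spectrum a non-negative mixture of a few constituent spectra built from
a mid-IR band library, plus a broad low-frequency baseline oscillation
(a Mie-scattering stand-in) and additive noise.  Constituent
presence/absence varies across the ring series: the "sapwood lignin"
profile carries a 1660 cm^-1 band and occupies the early rings, the
"heartwood lignin" profile carries 1640 cm^-1 instead and takes over
from the transition ring onward.

Spatial layout is a cartoon of softwood anatomy: a periodic cell-wall
lattice (cellulose-rich wall flanks, lignin-rich wall centres standing
in for CML/cell corners), a vertical ray stripe (extractives), and lumen
holes (a weak blank profile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hsmcr.io_cube import SpectralImage

__all__ = [
    "BandSpec",
    "TissueGeometry",
    "SceneParams",
    "GroundTruth",
    "PROFILES",
    "build_band_library",
    "render_pure_spectra",
    "render_tissue_maps",
    "simulate_multiset",
    "default_presence",
    "save_ground_truth",
    "load_ground_truth",
]


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: centre/FWHM in cm^-1, height in a.u."""

    center: float
    width: float
    height: float = 1.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.height < 0:
            raise ValueError(f"band height must be >= 0, got {self.height}")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"band shape must be 'gaussian' or 'lorentzian', got {self.shape!r}")

    def render(self, axis: np.ndarray) -> np.ndarray:
        x = np.asarray(axis, dtype=float) - self.center
        if self.shape == "gaussian":
            sigma = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return self.height * np.exp(-0.5 * (x / sigma) ** 2)
        gamma = self.width / 2.0
        return self.height * gamma**2 / (x**2 + gamma**2)


# Constituent band libraries.  Centres follow the published wood FTIR
# assignments (cellulose skeletal/CH bands 1317-1423; lignin aromatic
# 1505/1600 plus the coniferyl 1660 vs carbonyl 1640 pair that separates
# sapwood-type from heartwood-type lignin; extractives carbonyls at
# 1640/1660/1728).  Heights/widths are synthetic choices.
_LIBRARIES: dict[str, list[BandSpec]] = {
    "cellulose": [
        BandSpec(1317, 18, 1.0),
        BandSpec(1336, 16, 0.7),
        BandSpec(1368, 18, 0.8),
        BandSpec(1423, 22, 0.6),
    ],
    "lignin_sw": [
        BandSpec(1423, 22, 0.35),
        BandSpec(1460, 22, 0.45),
        BandSpec(1510, 22, 1.0),
        BandSpec(1600, 26, 0.8),
        BandSpec(1660, 20, 0.9),
    ],
    "lignin_hw": [
        BandSpec(1423, 22, 0.35),
        BandSpec(1460, 22, 0.45),
        BandSpec(1510, 22, 1.0),
        BandSpec(1600, 26, 0.8),
        BandSpec(1640, 20, 0.9),
    ],
    "extractives": [
        BandSpec(1280, 24, 0.4),
        BandSpec(1600, 26, 0.5),
        BandSpec(1640, 20, 0.7),
        BandSpec(1660, 20, 0.7),
        BandSpec(1728, 26, 1.0),
    ],
    "lumen_blank": [
        BandSpec(1250, 60, 0.3),
        BandSpec(1550, 80, 0.2),
    ],
}

PROFILES = ("cellulose", "lignin_sw", "lignin_hw", "extractives", "lumen_blank")


def build_band_library(profile: str) -> list[BandSpec]:
    """Return the default band list for a constituent profile.

    Profiles: ``cellulose``, ``lignin_sw`` (1660 cm^-1, no 1640),
    ``lignin_hw`` (1640 cm^-1, no 1660), ``extractives`` (1640, 1660 and
    1728 cm^-1 carbonyls), ``lumen_blank`` (weak broad background).
    """
    try:
        return list(_LIBRARIES[profile])
    except KeyError:
        raise ValueError(
            f"unknown profile {profile!r}; valid profiles: {', '.join(sorted(_LIBRARIES))}"
        ) from None


def render_pure_spectra(library: list[list[BandSpec]], axis: np.ndarray) -> np.ndarray:
    """Render each band list to a unit-2-norm spectrum on ``axis``.

    Returns a (components x channels) matrix with non-negative rows.
    """
    if not library:
        raise ValueError("empty band library")
    axis = np.asarray(axis, dtype=float)
    d = np.diff(axis)
    if axis.ndim != 1 or axis.size < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be 1-D and strictly monotonic")
    out = np.zeros((len(library), axis.size))
    for i, bands in enumerate(library):
        if not bands:
            raise ValueError(f"component {i} has an empty band list")
        for band in bands:
            out[i] += band.render(axis)
        nrm = np.linalg.norm(out[i])
        if nrm == 0:
            raise ValueError(f"component {i} renders to zero on the given axis")
        out[i] /= nrm
    return out


@dataclass(frozen=True)
class TissueGeometry:
    """Cartoon anatomy parameters (all lengths in pixels)."""

    ray_center_frac: float = 0.5   # ray stripe centre as fraction of width
    ray_width: int = 4
    cell_period: int = 8           # cell-wall lattice period
    wall_thickness: int = 3        # total wall band width (odd: centre = CML)


def _default_axis() -> np.ndarray:
    return np.arange(1200.0, 1750.0 + 1e-9, 2.0)


def default_presence(n_images: int, n_components: int, hw_start: int = 5) -> np.ndarray:
    """Presence matrix: sapwood lignin in rings 1..hw_start, heartwood
    lignin from ring hw_start on (1-based); everything else everywhere."""
    presence = np.ones((n_images, n_components), dtype=bool)
    if n_components >= 3:
        sw, hw = 1, 2  # indices in PROFILES
        for i in range(n_images):
            ring = i + 1
            presence[i, sw] = ring <= hw_start
            presence[i, hw] = ring >= hw_start
    return presence


@dataclass
class SceneParams:
    """Full description of a synthetic multiset scene."""

    n_images: int = 8
    image_shape: tuple[int, int] = (32, 32)
    axis: np.ndarray = field(default_factory=_default_axis)
    n_components: int = 5
    presence: np.ndarray | None = None  # defaults to default_presence()
    profiles: tuple[str, ...] = PROFILES
    tissue_geometry: TissueGeometry = field(default_factory=TissueGeometry)
    baseline_amplitude: float = 0.0
    baseline_period: float = 800.0
    noise_sd: float = 0.0
    saturation_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.n_components != len(self.profiles):
            self.profiles = tuple(PROFILES[: self.n_components])
            if len(self.profiles) != self.n_components:
                raise ValueError(
                    f"n_components={self.n_components} exceeds available profiles {len(PROFILES)}"
                )
        if self.presence is None:
            self.presence = default_presence(self.n_images, self.n_components)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (self.n_images, self.n_components):
            raise ValueError(
                f"presence shape {self.presence.shape} != ({self.n_images}, {self.n_components})"
            )
        if not np.all(self.presence.any(axis=1)):
            raise ValueError("every image must have at least one present component")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 <= self.saturation_fraction < 1):
            raise ValueError("saturation_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    """Generator truth for recovery tests.

    ``pure_spectra`` rows are unit 2-norm; ``concentrations[i]`` has
    shape (rows, cols, n_components) and is exactly zero wherever
    ``presence`` says a component is absent.
    """

    pure_spectra: np.ndarray
    concentrations: list[np.ndarray]
    baselines: list[np.ndarray]
    presence: np.ndarray
    axis: np.ndarray

    @property
    def n_components(self) -> int:
        return self.pure_spectra.shape[0]


def _rng(params: SceneParams, *key: int) -> np.random.Generator:
    return np.random.default_rng([params.seed & 0x7FFFFFFF, *key])


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], rel: float = 0.25) -> np.ndarray:
    """Positive multiplicative modulation field, smoothed white noise."""
    raw = rng.standard_normal(shape)
    # separable 5-tap binomial blur, reflect padding
    kern = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0
    pad = np.pad(raw, 2, mode="reflect")
    for axis in (0, 1):
        pad = np.apply_along_axis(lambda v: np.convolve(v, kern, mode="same"), axis, pad)
    sm = pad[2:-2, 2:-2]
    return np.clip(1.0 + rel * sm / max(sm.std(), 1e-12), 0.2, None)


def _tissue_masks(geo: TissueGeometry, shape: tuple[int, int]) -> dict[str, np.ndarray]:
    rows, cols = shape
    r = np.arange(rows)[:, None] * np.ones((1, cols), dtype=int)
    c = np.arange(cols)[None, :] * np.ones((rows, 1), dtype=int)
    t = geo.wall_thickness
    period = geo.cell_period
    wall = (r % period < t) | (c % period < t)
    centre = t // 2
    cml = (r % period == centre) | (c % period == centre)
    cml &= wall
    ray_c = int(round(geo.ray_center_frac * (cols - 1)))
    half = geo.ray_width / 2.0
    ray = np.abs(c - ray_c) <= half
    lumen = ~wall & ~ray
    wall_only = wall & ~ray
    cml_only = cml & ~ray
    return {"wall": wall_only, "cml": cml_only, "ray": ray, "lumen": lumen}


def render_tissue_maps(params: SceneParams, component_index: int, image_index: int) -> np.ndarray:
    """Deterministic non-negative abundance map for one component in one image.

    Layout per profile role: cellulose on wall flanks, lignin profiles on
    wall centres (CML/cell corners), extractives on the ray stripe,
    lumen_blank inside lumen holes.  The heartwood lignin profile also
    reaches into the ray.  Returns all-zeros when the presence matrix
    declares the component absent.
    """
    if not (0 <= component_index < params.n_components):
        raise IndexError(f"component_index {component_index} out of range")
    if not (0 <= image_index < params.n_images):
        raise IndexError(f"image_index {image_index} out of range")
    shape = params.image_shape
    if not params.presence[image_index, component_index]:
        return np.zeros(shape)
    profile = params.profiles[component_index]
    geo = params.tissue_geometry
    masks = _tissue_masks(geo, shape)
    rows, cols = shape
    r = np.arange(rows)[:, None] * np.ones((1, cols), dtype=int)
    c = np.arange(cols)[None, :] * np.ones((rows, 1), dtype=int)
    centre = geo.wall_thickness // 2
    # mixing is restricted to sub-regions so that no component's support
    # contains another's (keeps the noiseless factorization unique)
    horiz_cml = masks["cml"] & (r % geo.cell_period == centre)
    lumen_checker = masks["lumen"] & ((r + c) % 2 == 0)
    base = np.zeros(shape)
    if profile == "cellulose":
        base[masks["wall"]] = 1.0
        base[masks["cml"]] = 0.0
        base[horiz_cml] = 0.15
    elif profile in ("lignin_sw", "lignin_hw"):
        base[masks["cml"]] = 1.0
        if profile == "lignin_hw":
            base[masks["ray"]] = 0.5
        # sapwood lignin fades in its final (transition) ring
        present_rings = np.flatnonzero(params.presence[:, component_index])
        if profile == "lignin_sw" and image_index == present_rings[-1] and present_rings.size > 1:
            base *= 0.3
    elif profile == "extractives":
        base[masks["ray"]] = 1.0
        base[lumen_checker] = 0.1
    elif profile == "lumen_blank":
        base[masks["lumen"]] = 1.0
    else:  # generic fallback: uniform presence
        base[:] = 1.0
    rng = _rng(params, 101, image_index, component_index)
    return base * _smooth_field(rng, shape)


def simulate_multiset(params: SceneParams) -> tuple[list[SpectralImage], GroundTruth]:
    """Generate the image stack and its ground truth.

    Each pixel spectrum is sum_k c_k s_k plus a raised-cosine baseline of
    random phase and i.i.d. Gaussian noise; a ``saturation_fraction`` of
    pixels per image is flagged invalid in the mask.
    """
    axis = params.axis
    if axis.size < 8:
        raise ValueError(f"axis must have at least 8 channels, got {axis.size}")
    library = [build_band_library(p) for p in params.profiles]
    spectra = render_pure_spectra(library, axis)
    rows, cols = params.image_shape
    images: list[SpectralImage] = []
    concentrations: list[np.ndarray] = []
    baselines: list[np.ndarray] = []
    for i in range(params.n_images):
        cmaps = np.stack(
            [render_tissue_maps(params, k, i) for k in range(params.n_components)], axis=-1
        )
        cube = cmaps @ spectra  # (rows, cols, channels)
        if params.baseline_amplitude > 0:
            rng_b = _rng(params, 202, i)
            phase = rng_b.uniform(0, 2 * np.pi, size=(rows, cols, 1))
            amp = params.baseline_amplitude * rng_b.uniform(0.5, 1.0, size=(rows, cols, 1))
            arg = 2 * np.pi * axis[None, None, :] / params.baseline_period + phase
            baseline = 0.5 * amp * (1.0 + np.cos(arg))
        else:
            baseline = np.zeros_like(cube)
        cube = cube + baseline
        if params.noise_sd > 0:
            cube = cube + _rng(params, 303, i).normal(0.0, params.noise_sd, size=cube.shape)
        mask = np.ones((rows, cols), dtype=bool)
        if params.saturation_fraction > 0:
            sat = _rng(params, 404, i).random((rows, cols)) < params.saturation_fraction
            mask &= ~sat
        meta = {"section_id": f"X{i + 1}", "direction": "cross", "ring": i + 1}
        images.append(SpectralImage(cube=cube, axis=axis.copy(), mask=mask, meta=meta))
        concentrations.append(cmaps)
        baselines.append(baseline)
    truth = GroundTruth(
        pure_spectra=spectra,
        concentrations=concentrations,
        baselines=baselines,
        presence=params.presence.copy(),
        axis=axis.copy(),
    )
    return images, truth


def default_scene_params(
    seed: int = 0,
    noise_frac: float = 0.01,
    baseline_frac: float = 0.05,
    hw_start: int = 5,
    **overrides,
) -> SceneParams:
    """Default noisy scene: noise and baseline scaled to the clean
    scene's maximum absorbance (measured by a dry run without either)."""
    clean = SceneParams(
        seed=seed,
        presence=default_presence(
            overrides.get("n_images", 8), overrides.get("n_components", 5), hw_start
        ),
        **overrides,
    )
    images, _ = simulate_multiset(clean)
    peak = max(float(img.cube.max()) for img in images)
    return SceneParams(
        seed=seed,
        presence=clean.presence,
        noise_sd=noise_frac * peak,
        baseline_amplitude=baseline_frac * peak,
        **overrides,
    )


def save_ground_truth(truth: GroundTruth, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("pure_spectra", data=truth.pure_spectra)
        fh.create_dataset("presence", data=truth.presence)
        fh.create_dataset("axis", data=truth.axis)
        grp = fh.create_group("concentrations")
        grb = fh.create_group("baselines")
        for i, (cm, bl) in enumerate(zip(truth.concentrations, truth.baselines)):
            grp.create_dataset(str(i), data=cm)
            grb.create_dataset(str(i), data=bl)


def load_ground_truth(path: str) -> GroundTruth:
    import h5py

    with h5py.File(path, "r") as fh:
        n = len(fh["concentrations"])
        return GroundTruth(
            pure_spectra=fh["pure_spectra"][()],
            concentrations=[fh["concentrations"][str(i)][()] for i in range(n)],
            baselines=[fh["baselines"][str(i)][()] for i in range(n)],
            presence=fh["presence"][()].astype(bool),
            axis=fh["axis"][()],
        )
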