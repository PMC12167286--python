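"""Synthetic labeled hyperspectral scenes ("phantoms").

The surgical HSI datasets this package targets are not public, so the
phantom generator emulates their statistical structure: per-class smooth
reflectance spectra with absorption dips on a 500-1000 nm axis, a background
cloth class, organ-like smooth blobs, a multiplicative per-subject gain
(multiple images per subject, inducing the within-subject correlation that
hierarchical metric aggregation exists for), smooth illumination fields,
multiplicative + additive sensor noise, and three geometric
out-of-distribution variants: occlusion by hand/instrument shapes, organ
isolation, and spatial blur.

Label conventions: id 0 is the background cloth; ids 1..n_organ_classes are
organ classes; the last library class is reserved for the occluder
(hand/instrument), so standard scenes never show its spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon

from .errors import ConfigError, GenerationError
from .hsi_io import HsiCube, LabelLegend, SemanticMask

__all__ = [
    "SpectralLibrary", "PhantomConfig",
    "make_spectral_library", "render_scene", "make_dataset", "library_legend",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class SpectralLibrary:
    """K x C nonnegative reference reflectance spectra."""

    spectra: np.ndarray
    wavelengths: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.spectra.ndim != 2 or self.spectra.shape[0] < 2:
            raise ConfigError("library needs at least 2 classes")
        if self.spectra.shape[1] != len(self.wavelengths):
            raise ConfigError("spectra band count != wavelength count")
        if len(self.class_names) != self.spectra.shape[0]:
            raise ConfigError("class_names length != number of spectra")
        if not np.all(np.isfinite(self.spectra)) or np.any(self.spectra < 0):
            raise ConfigError("library spectra must be finite and nonnegative")

    @property
    def n_classes(self) -> int:
        return self.spectra.shape[0]

    @property
    def occluder_id(self) -> int:
        """The reserved occluder class (always the last library entry)."""
        return self.n_classes - 1


@dataclass
class PhantomConfig:
    """Study conditions for phantom generation."""

    n_subjects: int = 4
    images_per_subject: int = 4
    H: int = 32
    W: int = 32
    C: int = 25
    n_organ_classes: int = 3
    classes_per_image: tuple[int, int] = (1, 3)
    sigma_m: float = 0.05      # multiplicative noise std
    sigma_a: float = 0.01      # additive noise std
    illumination_amplitude: float = 0.1
    subject_gain_sigma: float = 0.1  # log-normal sigma of per-subject gain
    seed: int = 0
    ood_mode: str = "none"     # none | occlusion | isolation | blur
    blur_sigma: float = 1.5    # spatial Gaussian sigma for ood_mode="blur"

    def __post_init__(self):
        for name in ("n_subjects", "images_per_subject", "H", "W", "C",
                     "n_organ_classes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.sigma_m < 0 or self.sigma_a < 0:
            raise ConfigError("noise sigmas must be nonnegative")
        if self.ood_mode not in {"none", "occlusion", "isolation", "blur"}:
            raise ConfigError(f"unknown ood_mode: {self.ood_mode!r}")
        lo, hi = self.classes_per_image
        if not (1 <= lo <= hi <= self.n_organ_classes):
            raise ConfigError("classes_per_image range invalid")

    @property
    def n_classes(self) -> int:
        """Total library classes: background + organs + reserved occluder."""
        return self.n_organ_classes + 2


# --------------------------------------------------------------------------
# spectral library
# --------------------------------------------------------------------------

def _random_spectrum(rng: np.random.Generator, wl: np.ndarray) -> np.ndarray:
    """Smooth baseline (sigmoidal reflectance edge) minus 1-3 Gaussian dips."""
    edge = rng.uniform(550.0, 800.0)
    width = rng.uniform(40.0, 120.0)
    lo = rng.uniform(0.05, 0.3)
    hi = rng.uniform(0.4, 0.9)
    base = lo + (hi - lo) / (1.0 + np.exp(-(wl - edge) / width))
    # multiplicative absorption dips keep reflectance positive and the
    # band-to-band relative change bounded (smoothness invariant)
    for _ in range(rng.integers(1, 4)):
        center = rng.uniform(wl[0] + 20, wl[-1] - 20)
        sig = rng.uniform(25.0, 80.0)
        depth = rng.uniform(0.15, 0.55)
        base = base * (1.0 - depth * np.exp(-0.5 * ((wl - center) / sig) ** 2))
    return np.clip(base, 0.02, None)


def _l1norm(s: np.ndarray) -> np.ndarray:
    return s / np.sum(np.abs(s))


def min_pairwise_l1_distance(spectra: np.ndarray) -> float:
    """Minimum pairwise l1 distance between l1-normalized spectra."""
    norm = np.stack([_l1norm(s) for s in spectra])
    k = len(norm)
    dists = [np.abs(norm[i] - norm[j]).sum() for i in range(k) for j in range(i + 1, k)]
    return float(min(dists))


def make_spectral_library(n_classes: int, n_bands: int, seed: int,
                          wavelength_range: tuple[float, float] = (500.0, 1000.0),
                          separation_floor: float = 0.05,
                          max_retries: int = 25) -> SpectralLibrary:
    """Generate ``n_classes`` smooth, mutually distinct reference spectra.

    Class 0 is the background cloth (flat-ish with a broad dip); the last
    class is named as the occluder. All classes are at least
    ``separation_floor`` apart in normalized-l1 distance, retrying with fresh
    draws a bounded number of times before raising GenerationError.
    """
    if n_classes < 2:
        raise ConfigError("n_classes must be >= 2")
    if n_bands < 8:
        raise ConfigError("n_bands must be >= 8")
    wl = np.linspace(*wavelength_range, n_bands)
    seeds = np.random.SeedSequence(seed).spawn(max_retries)
    for attempt in range(max_retries):
        rng = np.random.default_rng(seeds[attempt])
        spectra = []
        # background cloth: flat-high with one broad absorption dip
        tilt = rng.uniform(-0.1, 0.1)
        cloth = 0.55 + tilt * (wl - wl.mean()) / (wl[-1] - wl[0])
        cloth = cloth * (1.0 - 0.35 * np.exp(
            -0.5 * ((wl - rng.uniform(600, 900)) / 120.0) ** 2))
        spectra.append(np.clip(cloth, 0.02, None))
        for _ in range(n_classes - 1):
            spectra.append(_random_spectrum(rng, wl))
        spectra = np.stack(spectra)
        if min_pairwise_l1_distance(spectra) >= separation_floor:
            names = (["background"]
                     + [f"organ_{i}" for i in range(1, n_classes - 1)]
                     + ["occluder"])
            return SpectralLibrary(spectra=spectra, wavelengths=wl,
                                   class_names=names[:n_classes])
    raise GenerationError(
        f"could not reach separation floor {separation_floor} in {max_retries} tries"
    )


def library_legend(library: SpectralLibrary) -> LabelLegend:
    return LabelLegend(
        entries={i: name for i, name in enumerate(library.class_names)},
        background_id=0,
    )


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _blob_mask(rng: np.random.Generator, h: int, w: int,
               r_frac: tuple[float, float] = (0.15, 0.3)) -> np.ndarray:
    """Random smooth closed shape: ellipse with low-order Fourier boundary."""
    cy = rng.uniform(0.25, 0.75) * h
    cx = rng.uniform(0.25, 0.75) * w
    r0 = rng.uniform(*r_frac) * min(h, w)
    aspect = rng.uniform(0.7, 1.4)
    theta = np.linspace(0, 2 * np.pi, 72, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 5):
        r += rng.uniform(0.0, 0.12) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    rot = rng.uniform(0, np.pi)
    ry = r0 * r * aspect
    rx = r0 * r / aspect
    y = cy + ry * np.sin(theta) * np.cos(rot) - rx * np.cos(theta) * np.sin(rot)
    x = cx + ry * np.sin(theta) * np.sin(rot) + rx * np.cos(theta) * np.cos(rot)
    rr, cc = draw_polygon(np.clip(y, 0, h - 1), np.clip(x, 0, w - 1), shape=(h, w))
    out = np.zeros((h, w), dtype=bool)
    out[rr, cc] = True
    return out


def _hand_mask(rng: np.random.Generator, h: int, w: int) -> np.ndarray:
    """Multi-lobed 'hand' (palm + fingers) or elongated 'instrument' shape."""
    out = np.zeros((h, w), dtype=bool)
    if rng.random() < 0.5:  # hand: palm ellipse + 3-4 finger bars
        cy = rng.uniform(0.35, 0.65) * h
        cx = rng.uniform(0.35, 0.65) * w
        pr = rng.uniform(0.12, 0.2) * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        out |= ((yy - cy) ** 2 / (1.3 * pr) ** 2 + (xx - cx) ** 2 / pr**2) <= 1.0
        ang0 = rng.uniform(0, 2 * np.pi)
        for i in range(rng.integers(3, 5)):
            ang = ang0 + i * 0.3 + rng.uniform(-0.1, 0.1)
            length = rng.uniform(1.2, 2.2) * pr
            fw = max(1.0, 0.35 * pr)
            t = np.linspace(0, 1, 32)
            fy = cy + t * length * np.sin(ang)
            fx = cx + t * length * np.cos(ang)
            for yv, xv in zip(fy, fx):
                out |= ((yy - yv) ** 2 + (xx - xv) ** 2) <= fw**2
    else:  # instrument: rotated elongated rectangle crossing the scene
        ang = rng.uniform(0, np.pi)
        cy = rng.uniform(0.3, 0.7) * h
        cx = rng.uniform(0.3, 0.7) * w
        half_len = 0.6 * max(h, w)
        half_w = rng.uniform(0.04, 0.08) * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        u = (xx - cx) * np.cos(ang) + (yy - cy) * np.sin(ang)
        v = -(xx - cx) * np.sin(ang) + (yy - cy) * np.cos(ang)
        out |= (np.abs(u) <= half_len) & (np.abs(v) <= half_w)
    return out


def _illumination(rng: np.random.Generator, h: int, w: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative illumination field, mean ~1."""
    if amplitude == 0:
        return np.ones((h, w))
    ang = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = ((yy / max(h - 1, 1) - 0.5) * np.sin(ang)
            + (xx / max(w - 1, 1) - 0.5) * np.cos(ang))
    phase = rng.uniform(0, 2 * np.pi)
    wave = 0.5 * np.sin(2 * np.pi * (xx / w + yy / h) * rng.uniform(0.5, 1.0) + phase)
    return 1.0 + amplitude * (ramp + 0.3 * wave)


# --------------------------------------------------------------------------
# scene rendering
# --------------------------------------------------------------------------

def render_scene(library: SpectralLibrary, config: PhantomConfig,
                 subject_id: str, seed: int,
                 subject_gain: float = 1.0) -> tuple[HsiCube, SemanticMask]:
    """Render one labeled scene; deterministic given ``seed``.

    Pixel spectrum = class reference x subject gain x illumination
    x (1 + N(0, sigma_m^2)) + N(0, sigma_a^2), clipped at 0.
    """
    if library.n_classes != config.n_classes:
        raise ConfigError(
            f"library has {library.n_classes} classes, config expects {config.n_classes}"
        )
    h, w = config.H, config.W
    organ_ids = list(range(1, 1 + config.n_organ_classes))
    rng = np.random.default_rng(seed)

    for _attempt in range(6):
        labels = np.zeros((h, w), dtype=np.int64)
        lo, hi = config.classes_per_image
        n_org = 1 if config.ood_mode == "isolation" else int(rng.integers(lo, hi + 1))
        chosen = rng.choice(organ_ids, size=n_org, replace=False)
        for cls in chosen:
            labels[_blob_mask(rng, h, w)] = int(cls)
        if config.ood_mode == "occlusion":
            labels[_hand_mask(rng, h, w)] = library.occluder_id
        present = set(np.unique(labels).tolist())
        if all(int(c) in present for c in chosen):
            break
    else:
        raise GenerationError("a requested class received zero pixels after retries")

    spectra = library.spectra[labels]                       # (h, w, C)
    illum = _illumination(rng, h, w, config.illumination_amplitude)
    cube = spectra * subject_gain * illum[..., None]
    if config.sigma_m > 0:
        cube = cube * (1.0 + rng.normal(0.0, config.sigma_m, cube.shape))
    if config.sigma_a > 0:
        cube = cube + rng.normal(0.0, config.sigma_a, cube.shape)
    if config.ood_mode == "blur":
        cube = gaussian_filter(cube, sigma=(config.blur_sigma, config.blur_sigma, 0))
    cube = np.clip(cube, 0.0, None)

    mask = SemanticMask(labels=labels, legend=library_legend(library))
    return (
        HsiCube(data=cube.astype(np.float32), wavelengths=library.wavelengths,
                subject_id=subject_id),
        mask,
    )


def make_dataset(config: PhantomConfig,
                 library: SpectralLibrary | None = None
                 ) -> list[tuple[HsiCube, SemanticMask, str]]:
    """Render n_subjects x images_per_subject scenes.

    Each subject carries one shared multiplicative gain (log-normal with
    sigma ``subject_gain_sigma``), so spectra correlate within subject.
    """
    if library is None:
        library = make_spectral_library(config.n_classes, config.C, seed=config.seed)
    root = np.random.SeedSequence(config.seed)
    gain_rng = np.random.default_rng(root.spawn(1)[0])
    scene_seeds = root.spawn(config.n_subjects * config.images_per_subject + 1)[1:]
    out = []
    idx = 0
    for s in range(config.n_subjects):
        subject_id = f"subject_{s:03d}"
        gain = float(np.exp(gain_rng.normal(0.0, config.subject_gain_sigma)))
        for _ in range(config.images_per_subject):
            child = np.random.default_rng(scene_seeds[idx])
            scene_seed = int(child.integers(0, 2**31 - 1))
            cube, mask = render_scene(library, config, subject_id,
                                      seed=scene_seed, subject_gain=gain)
            out.append((cube, mask, subject_id))
            idx += 1
    return out
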