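"""Synthetic ultrasound-like phantoms with ground truth.

Each phantom is a darker, roughly elliptical (optionally lobulated) lesion
centered in a brighter background, degraded the way tissue imaging degrades
ultrasound: multiplicative mean-1 speckle with a heavy (squared-Rayleigh
style, i.e. exponential) tail, Gaussian blur standing in for the system
point-spread function, a smooth additive intensity-inhomogeneity field, and
optionally a posterior acoustic shadow band below the lesion. Everything is
seeded and byte-reproducible, so the phantoms serve as the test bed that
replaces unavailable clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.transform import resize


class PhantomSpecError(ValueError):
    """Lesion geometry does not fit the frame."""


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 128
    width: int = 128
    lesion_shape: str = "ellipse"        # "ellipse" | "lobulated"
    center_jitter: float = 2.0           # max |offset| of lesion center, px
    semi_axes: tuple[float, float] = (28.0, 22.0)
    lobe_amplitude: float = 0.15         # radial modulation, fraction of radius
    n_lobes: int = 5
    rotation: float = 0.0                # radians
    background_mean: float = 150.0
    lesion_mean: float = 70.0
    speckle_sigma: float = 0.1           # std of the multiplicative field
    blur_sigma: float = 1.0              # px
    inhomogeneity_amplitude: float = 10.0  # intensity units
    shadow: bool = False
    shadow_depth: float = 30.0           # intensity drop at the lesion base
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lesion_shape not in ("ellipse", "lobulated"):
            raise PhantomSpecError(f"unknown lesion shape {self.lesion_shape!r}")
        if self.background_mean <= self.lesion_mean:
            raise PhantomSpecError("lesion must be darker than background")
        if not (0 <= self.speckle_sigma < 1):
            raise PhantomSpecError("speckle_sigma must be in [0, 1)")
        r_max = max(self.semi_axes) * (1.0 + max(0.0, self.lobe_amplitude)) \
            + self.center_jitter
        if (r_max + 4.0 > min(self.height, self.width) / 2.0):
            raise PhantomSpecError("lesion does not fit the frame with a 4-px margin")

    def to_dict(self) -> dict:
        return asdict(self)


def _geometry_rng(spec: PhantomSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 0])


def _texture_rng(spec: PhantomSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 1])


def _lesion_geometry(spec: PhantomSpec):
    rng = _geometry_rng(spec)
    jitter = rng.uniform(-spec.center_jitter, spec.center_jitter, size=2)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    cy = spec.height / 2.0 + jitter[0]
    cx = spec.width / 2.0 + jitter[1]
    return cy, cx, phase


def lesion_mask(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth lesion mask (uint8 0/1).

    Ellipse: rotated-ellipse inequality. Lobulated: the ellipse's polar
    radius modulated as r(theta) = r0(theta) * (1 + A*sin(n_lobes*theta +
    phase)), phase drawn from the spec seed — the malignant-like "lobulated
    with burrs" silhouette. Zero amplitude reduces to the exact ellipse.
    """
    cy, cx, phase = _lesion_geometry(spec)
    a, b = spec.semi_axes
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(spec.rotation), np.sin(spec.rotation)
    u = ct * dx + st * dy     # along semi-axis a
    v = -st * dx + ct * dy    # along semi-axis b
    if spec.lesion_shape == "ellipse" or spec.lobe_amplitude == 0.0:
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    else:
        rho = np.hypot(u, v)
        theta = np.arctan2(v, u)
        r0 = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        r_mod = r0 * (1.0 + spec.lobe_amplitude * np.sin(spec.n_lobes * theta + phase))
        mask = rho <= r_mod
    return mask.astype(np.uint8)


def _inhomogeneity_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.inhomogeneity_amplitude == 0.0:
        return np.zeros((spec.height, spec.width))
    coarse = rng.standard_normal((4, 4))
    field = resize(coarse, (spec.height, spec.width), order=3, mode="reflect",
                   anti_aliasing=False)
    field -= field.mean()
    peak = np.abs(field).max()
    if peak > 0:
        field = field / peak * spec.inhomogeneity_amplitude
    return field


def _shadow_field(spec: PhantomSpec, mask: np.ndarray) -> np.ndarray:
    """Posterior dark band: exponential falloff below the lesion."""
    shadow = np.zeros((spec.height, spec.width))
    rows = np.arange(spec.height)
    for c in range(spec.width):
        col = np.flatnonzero(mask[:, c])
        if col.size == 0:
            continue
        bottom = col[-1]
        below = rows > bottom
        shadow[below, c] = -spec.shadow_depth * np.exp(-(rows[below] - bottom) / 15.0)
    return shadow


def render_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(image uint8, truth mask uint8 0/1), fully determined by the spec.

    image = clip(blur((base + inhomogeneity + shadow) * speckle)) where the
    speckle field is 1 + sigma*(E - 1) with E ~ Exp(1): mean 1, standard
    deviation sigma, heavy upper tail, strictly positive for sigma < 1.
    """
    mask = lesion_mask(spec)
    rng = _texture_rng(spec)
    base = np.where(mask.astype(bool), spec.lesion_mean, spec.background_mean)
    img = base + _inhomogeneity_field(spec, rng)
    if spec.shadow:
        img = img + _shadow_field(spec, mask)
    if spec.speckle_sigma > 0:
        e = rng.exponential(1.0, size=img.shape)
        img = img * (1.0 + spec.speckle_sigma * (e - 1.0))
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma, mode="nearest")
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask


_DIFFICULTY = {
    # contrast (bg - lesion), speckle, lobe amplitude, inhomogeneity, shadow
    "easy": dict(background_mean=150.0, lesion_mean=70.0, speckle_sigma=0.1,
                 lobe_amplitude=0.0, lesion_shape="ellipse",
                 inhomogeneity_amplitude=8.0, shadow=False),
    "medium": dict(background_mean=140.0, lesion_mean=90.0, speckle_sigma=0.2,
                   lobe_amplitude=0.10, lesion_shape="lobulated",
                   inhomogeneity_amplitude=12.0, shadow=False),
    "hard": dict(background_mean=130.0, lesion_mean=100.0, speckle_sigma=0.3,
                 lobe_amplitude=0.20, lesion_shape="lobulated",
                 inhomogeneity_amplitude=15.0, shadow=True),
}


def phantom_suite(
    n: int, difficulty: str = "easy", seed: int = 1
) -> list[tuple[np.ndarray, np.ndarray, PhantomSpec]]:
    """A deterministic batch of n phantoms at the given difficulty.

    Lesion size and orientation jitter per item; all randomness derives
    from ``seed``, so the same call always returns the same suite.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if difficulty not in _DIFFICULTY:
        raise ValueError(f"difficulty must be one of {sorted(_DIFFICULTY)}")
    rng = np.random.default_rng([seed, 2])
    item_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for i in range(n):
        a = rng.uniform(26.0, 32.0)
        b = rng.uniform(20.0, 26.0)
        rot = rng.uniform(0.0, np.pi)
        spec = PhantomSpec(
            semi_axes=(a, b), rotation=rot, seed=int(item_seeds[i]),
            **_DIFFICULTY[difficulty],
        )
        img, mask = render_phantom(spec)
        out.append((img, mask, spec))
    return out
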