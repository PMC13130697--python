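"""Synthetic H&E-like colonic mucosa micrographs with ground truth.

The generator emulates the layered architecture of a colonic biopsy viewed
at 20x in bright field, from the top of the frame down:

* **lumen** -- near-white empty space above the mucosal surface;
* **surface epithelium** -- a columnar cell layer (default 25 um) with
  eosinophilic cytoplasm and a dark basal nuclear row;
* **subepithelial collagen band** -- the detection target: a glassy,
  homogeneous eosin-pink strip of configurable thickness directly beneath
  the epithelium, brighter per channel and far less dispersed than the
  lamina propria, demarcated below by a thin capillary/nuclear fringe as in
  real CC histology;
* **lamina propria** -- cell-busy connective tissue: a correlated colour
  field peppered with dark stromal/immune-cell nuclei and pale crypt or
  goblet-mucin gaps.

A smooth multiplicative illumination gradient emulates lamp inhomogeneity,
and per-sample colour jitter emulates staining variability between
acquisitions.  Optional artifacts (blood vessel, white tear, tissue fold)
reproduce the classic false-positive confounders.

Each sample carries the exact band mask (ground truth) and an emulated
pathologist's *rough annotation*: the truth dilated by a roughness radius
whose magnitude wanders slowly (+-40%) along the band, as a coarse brush
sweep would.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt, gaussian_filter

from .io import AnnotationMask, RgbImage

__all__ = [
    "SyntheticSpec",
    "SyntheticSample",
    "generate_sample",
    "generate_dataset",
]

Colour = tuple[float, float, float]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic micrograph generator.

    Geometry is given in pixels at ``pixel_size_um`` resolution; layer
    thicknesses in micrometres.  Defaults reproduce the nominal acquisition
    (1392 x 1040 px, 0.6 um/px); ``quarter_scale()`` gives the 348 x 260
    test-scale field of view at the same resolution.
    """

    height_px: int = 1040
    width_px: int = 1392
    pixel_size_um: float = 0.6

    band_thickness_um: float = 15.0  # 0 disables the band; range 0-40
    epithelium_thickness_um: float = 25.0
    lumen_fraction: float = 0.30

    lumen_colour: Colour = (0.97, 0.96, 0.97)
    lumen_sd: float = 0.015
    epithelium_colour: Colour = (0.68, 0.50, 0.72)
    epithelium_sd: float = 0.05
    band_colour: Colour = (0.85, 0.66, 0.81)
    band_sd: float = 0.02
    lamina_colour: Colour = (0.82, 0.60, 0.74)
    lamina_sd: float = 0.035
    nuclei_colour: Colour = (0.50, 0.35, 0.62)
    gap_colour: Colour = (0.95, 0.94, 0.96)

    nuclei_density: float = 0.002  # nuclei per px^2 of frame
    nuclei_radius_px: int = 2
    gap_density: float = 0.0007  # pale crypt/mucin gaps per px^2
    gap_radius_px: int = 4
    basal_row_px: int = 4  # dark nuclear row at the epithelium base
    fringe_px: int = 4  # capillary/nuclear fringe under the band

    illumination_amplitude: float = 0.10
    colour_jitter: float = 0.015
    texture_sigma_px: float = 3.0

    annotation_radius_px: int = 12
    annotation_jitter_fraction: float = 0.4

    vessel: bool = False
    tear: bool = False
    fold: bool = False

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.band_thickness_um <= 40.0:
            raise ValueError("band_thickness_um must lie in [0, 40]")
        if self.band_px >= self.height_px:
            raise ValueError("band thicker than the image")
        for name in ("lumen", "epithelium", "band", "lamina", "nuclei", "gap"):
            col = getattr(self, f"{name}_colour")
            if min(col) < 0.0 or max(col) > 1.0:
                raise ValueError(f"{name}_colour outside [0, 1]")
        if self.band_thickness_um > 0:
            if not all(
                b > t for b, t in zip(self.band_colour, self.lamina_colour)
            ):
                raise ValueError(
                    "band colour must exceed lamina colour per channel"
                )
            if not self.band_sd < self.lamina_sd:
                raise ValueError("band dispersion must be below lamina dispersion")
        if not 0.0 < self.lumen_fraction < 0.8:
            raise ValueError("lumen_fraction must lie in (0, 0.8)")
        if self.annotation_radius_px < 0:
            raise ValueError("annotation_radius_px must be >= 0")

    @property
    def band_px(self) -> int:
        return int(round(self.band_thickness_um / self.pixel_size_um))

    @property
    def epithelium_px(self) -> int:
        return int(round(self.epithelium_thickness_um / self.pixel_size_um))

    def quarter_scale(self) -> "SyntheticSpec":
        """The 348 x 260 px field of view used by desk-scale benchmarks."""
        return replace(self, height_px=260, width_px=348)


@dataclass
class SyntheticSample:
    """A generated micrograph with its ground truth and rough annotation."""

    image: RgbImage
    truth_band_mask: AnnotationMask
    rough_annotation: AnnotationMask
    region_masks: dict[str, np.ndarray]
    artifact_masks: dict[str, np.ndarray]
    spec: SyntheticSpec
    seed: int


def _smooth_field(
    rng: np.random.Generator, h: int, w: int, sigma: float
) -> np.ndarray:
    """Unit-variance spatially correlated Gaussian field."""
    noise = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _speckle(
    rng: np.random.Generator, h: int, w: int, density: float, radius: int
) -> np.ndarray:
    n = rng.poisson(density * h * w)
    mask = np.zeros((h, w), dtype=bool)
    if n:
        mask[rng.integers(0, h, n), rng.integers(0, w, n)] = True
        size = 2 * radius + 1
        mask = binary_dilation(mask, np.ones((size, size), dtype=bool))
    return mask


def _paint(
    img: np.ndarray, mask: np.ndarray, colour: Colour, jitter: np.ndarray
) -> None:
    for c in range(3):
        img[..., c][mask] = colour[c] + jitter[c]


def _add_artifacts(
    rng: np.random.Generator,
    img: np.ndarray,
    lamina: np.ndarray,
    spec: SyntheticSpec,
) -> dict[str, np.ndarray]:
    """Vessel / tear / fold confounders, restricted to the lamina propria."""
    h, w = img.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    masks: dict[str, np.ndarray] = {}
    lam_rows = np.where(lamina.any(axis=1))[0]
    lo = int(lam_rows.min() + 10) if len(lam_rows) else h // 2

    if spec.vessel:
        cy = rng.integers(min(lo + 10, h - 2), h - 10)
        cx = rng.integers(20, w - 20)
        ry, rx = rng.integers(6, 12), rng.integers(8, 16)
        dist = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        vessel = (dist <= 1.0) & lamina
        rim = (dist <= 1.0) & (dist >= 0.55) & lamina
        _paint(img, vessel, (0.86, 0.55, 0.55), np.zeros(3))
        _paint(img, rim, (0.70, 0.32, 0.36), np.zeros(3))
        masks["vessel"] = vessel

    if spec.tear:
        cy = rng.integers(min(lo + 10, h - 2), h - 10)
        cx = rng.integers(20, w - 20)
        ry, rx = rng.integers(8, 14), rng.integers(14, 26)
        wobble = 1.0 + 0.35 * _smooth_field(rng, h, w, 6)
        dist = (((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) * wobble
        tear = (dist <= 1.0) & lamina
        _paint(img, tear, (0.96, 0.95, 0.96), np.zeros(3))
        masks["tear"] = tear

    if spec.fold:
        theta = rng.uniform(0, np.pi)
        offset = rng.uniform(-0.2, 0.2)
        line = (xx - w / 2) * np.cos(theta) + (yy - h / 2) * np.sin(theta)
        fold = (np.abs(line - offset * h) < rng.integers(5, 10)) & lamina
        img[fold] *= 0.62
        masks["fold"] = fold

    return masks


def generate_sample(
    spec: SyntheticSpec, seed: Optional[int] = None
) -> SyntheticSample:
    """Generate one micrograph; bit-identical for a fixed (spec, seed)."""
    seed = spec.rng_seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    sig = spec.texture_sigma_px

    # mucosal surface contour: slow undulation with two harmonics
    x = np.arange(w)
    base = spec.lumen_fraction * h
    amp1 = rng.uniform(0.023, 0.042) * h
    amp2 = rng.uniform(0.0115, 0.023) * h
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    contour = (
        base
        + amp1 * np.sin(2 * np.pi * x / (0.9 * w) + ph1)
        + amp2 * np.sin(2 * np.pi * x / (0.35 * w) + ph2)
    ).astype(int)
    contour = np.clip(contour, 1, h - 1)

    epi_t, band_t = spec.epithelium_px, spec.band_px
    rows = np.arange(h)[:, None]
    lumen = rows < contour[None, :]
    epithelium = (rows >= contour) & (rows < contour + epi_t)
    band = (rows >= contour + epi_t) & (rows < contour + epi_t + band_t)
    lamina = ~(lumen | epithelium | band)

    jitter = rng.uniform(-spec.colour_jitter, spec.colour_jitter, 3)
    img = np.empty((h, w, 3))
    region_params = (
        ("lamina", lamina, spec.lamina_colour, spec.lamina_sd),
        ("lumen", lumen, spec.lumen_colour, spec.lumen_sd),
        ("epithelium", epithelium, spec.epithelium_colour, spec.epithelium_sd),
        ("band", band, spec.band_colour, spec.band_sd),
    )
    for c in range(3):
        channel = np.empty((h, w))
        for name, mask, colour, sd in region_params:
            f = colour[c] + jitter[c] + sd * _smooth_field(rng, h, w, sig)
            if name == "lamina":
                channel[:] = f
            else:
                channel[mask] = f[mask]
        img[..., c] = channel

    # dark basal nuclear row of the columnar epithelium
    if spec.basal_row_px > 0 and epi_t > spec.basal_row_px:
        basal = (rows >= contour + epi_t - spec.basal_row_px) & (
            rows < contour + epi_t
        )
        _paint(img, basal, spec.nuclei_colour, jitter)

    # capillary/nuclear fringe demarcating the band's lower border
    if spec.fringe_px > 0 and band_t > 0:
        fringe = (rows >= contour + epi_t + band_t) & (
            rows < contour + epi_t + band_t + spec.fringe_px
        )
        _paint(img, fringe, (0.58, 0.40, 0.64), jitter)

    nuclei = _speckle(rng, h, w, spec.nuclei_density, spec.nuclei_radius_px) & lamina
    _paint(img, nuclei, spec.nuclei_colour, jitter)
    gaps = _speckle(rng, h, w, spec.gap_density, spec.gap_radius_px) & lamina & ~nuclei
    _paint(img, gaps, spec.gap_colour, np.zeros(3))

    artifact_masks = _add_artifacts(rng, img, lamina, spec)

    # multiplicative illumination gradient in a random direction
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = np.cos(theta) * xx / w + np.sin(theta) * yy / h
    span = np.ptp(ramp)
    ramp = (ramp - ramp.min()) / (span if span > 0 else 1.0)
    img = np.clip(img * (1.0 - spec.illumination_amplitude * ramp)[..., None], 0, 1)

    # rough annotation: truth dilated by a slowly wandering radius
    if band_t > 0:
        d_out = distance_transform_edt(~band)
        d_in = distance_transform_edt(band)
        signed = d_out - d_in
        radius = spec.annotation_radius_px * (
            1.0
            + spec.annotation_jitter_fraction
            * np.tanh(_smooth_field(rng, 1, w, 0.086 * w)[0])
        )
        rough = signed <= radius[None, :]
    else:
        rough = np.zeros((h, w), dtype=bool)

    return SyntheticSample(
        image=RgbImage(img, spec.pixel_size_um, image_id=f"synthetic-{seed:08d}"),
        truth_band_mask=AnnotationMask(band, kind="ground_truth"),
        rough_annotation=AnnotationMask(rough, kind="rough_annotation"),
        region_masks={
            "lumen": lumen,
            "epithelium": epithelium,
            "band": band,
            "lamina": lamina,
            "nuclei": nuclei,
            "gaps": gaps,
        },
        artifact_masks=artifact_masks,
        spec=spec,
        seed=seed,
    )


def generate_dataset(
    spec: SyntheticSpec, n: int, seed: Optional[int] = None
) -> list[SyntheticSample]:
    """Generate ``n`` samples with per-sample seeds derived from a master seed.

    Inter-image variability (staining jitter, contour, texture) follows from
    the independent per-sample streams; the whole collection is reproducible
    from the master seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = spec.rng_seed if seed is None else int(seed)
    children = np.random.SeedSequence(master).spawn(n)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return [generate_sample(spec, s) for s in child_seeds]
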