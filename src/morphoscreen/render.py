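"""Synthetic whole-well image generation.

Wells are rendered directly as the z-collapsed, single-channel 2D projection
the downstream analysis consumes (the acquisition this emulates sums a short
z-stack into one additive image per well).  Each colony is drawn with one of
four actin architectures:

* ``polarized`` — round disk with a bright interior annulus (central actin
  belt) at ~0.45 of the colony radius;
* ``inverted`` — round disk with a bright, angularly clumped rim and a dark
  interior;
* ``non_polarized`` — round disk, radially flat mean with a fine speckled
  texture;
* ``spread`` — elongated, boundary-perturbed region with lower mean
  intensity and larger area at equal nominal radius.

Colonies never overlap (rejection-sampled placement with a separation
margin), so ground truth maps 1:1 onto connected components at zero noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .design import PlateLayout
from .effects import (
    PHENOTYPES,
    ColonyCountParams,
    PhenotypeEffectModel,
    sample_colony_count,
    sample_well_mixture,
)

log = logging.getLogger(__name__)

__all__ = [
    "ColonyIntensityParams",
    "WellImageParams",
    "WellImage",
    "render_colony",
    "generate_well",
    "generate_plate",
]


@dataclass(frozen=True)
class ColonyIntensityParams:
    """Foreground intensity levels (16-bit counts) for each architecture."""

    polarized_base: float = 700.0
    polarized_annulus: float = 2300.0
    annulus_inner: float = 0.32     # relative radius of actin-belt annulus
    annulus_outer: float = 0.50
    inverted_interior: float = 450.0
    inverted_rim: float = 1600.0
    rim_inner: float = 0.82         # inverted rim spans [rim_inner, 1]*R
    rim_clump_amplitude: float = 0.45
    non_polarized_level: float = 900.0
    spread_level: float = 520.0
    texture_amplitude: float = 0.25  # speckle amplitude (fraction of level)
    texture_scale_px: float = 1.5


@dataclass(frozen=True)
class WellImageParams:
    """Geometry and noise of a rendered well."""

    size_px: int = 1024
    pixel_size_um: float = 1.3
    background: float = 200.0
    noise_sd: float = 25.0
    radius_median_px: float = 11.0
    radius_sigma: float = 0.18       # log-normal sigma of colony radius
    spread_radius_factor: float = 1.5
    spread_elongation: tuple[float, float] = (1.6, 2.2)
    separation_px: float = 8.0
    max_place_tries: int = 200
    counts: ColonyCountParams = field(default_factory=ColonyCountParams)
    intensity: ColonyIntensityParams = field(default_factory=ColonyIntensityParams)


@dataclass
class WellImage:
    """Single-channel well raster plus metadata."""

    pixels: np.ndarray
    well_id: str
    pixel_size_um: float = 1.3


def _speckle(shape, rng: np.random.Generator, scale_px: float) -> np.ndarray:
    """Zero-mean, unit-ish amplitude smooth noise field."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, scale_px)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def render_colony(
    phenotype: str,
    radius: float,
    params: ColonyIntensityParams = ColonyIntensityParams(),
    rng: np.random.Generator | None = None,
    elongation: float = 1.0,
    orientation: float = 0.0,
    texture: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one colony patch.

    Returns ``(patch, mask)`` where ``patch`` holds foreground intensities
    (zero outside the colony) and ``mask`` is the boolean footprint.  The
    patch excludes background and noise; those are added at the well level.
    ``rng`` drives the texture/wobble draws and defaults to a fixed seed so
    a bare call is deterministic.
    """
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    rng = rng or np.random.default_rng(0)
    p = params

    bound = radius * (math.sqrt(elongation) * 1.35 if phenotype == "spread" else 1.05)
    half = int(math.ceil(bound)) + 2
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    rr = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)

    if phenotype == "spread":
        a = radius * math.sqrt(elongation)
        b = radius / math.sqrt(elongation)
        ct, st = math.cos(orientation), math.sin(orientation)
        u = xx * ct + yy * st
        v = -xx * st + yy * ct
        r_ell = np.hypot(u / a, v / b)
        # low-order Fourier wobble of the boundary -> irregular outline
        n_modes = 4
        amps = rng.uniform(0.04, 0.12, n_modes)
        phases = rng.uniform(0, 2 * np.pi, n_modes)
        wobble = np.ones_like(theta)
        for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
            wobble += amp * np.cos(k * theta + ph)
        mask = r_ell <= wobble
        patch = np.where(mask, p.spread_level, 0.0)
        if texture and p.texture_amplitude > 0:
            patch *= 1.0 + 1.2 * p.texture_amplitude * _speckle(
                patch.shape, rng, p.texture_scale_px
            )
    else:
        rnorm = rr / radius
        mask = rnorm <= 1.0
        if phenotype == "polarized":
            patch = np.where(mask, p.polarized_base, 0.0)
            ann = mask & (rnorm >= p.annulus_inner) & (rnorm < p.annulus_outer)
            patch[ann] = p.polarized_annulus
        elif phenotype == "inverted":
            patch = np.where(mask, p.inverted_interior, 0.0)
            rim = mask & (rnorm >= p.rim_inner)
            phase = rng.uniform(0, 2 * np.pi)
            clump = 1.0 + p.rim_clump_amplitude * np.cos(5 * theta + phase)
            patch[rim] = p.inverted_rim * clump[rim]
        else:  # non_polarized
            patch = np.where(mask, p.non_polarized_level, 0.0)
            if texture and p.texture_amplitude > 0:
                patch *= 1.0 + p.texture_amplitude * _speckle(
                    patch.shape, rng, p.texture_scale_px
                )
    patch = np.clip(patch, 0.0, None)
    patch[~mask] = 0.0
    return patch, mask


def _bounding_radius(phenotype: str, radius: float, elongation: float) -> float:
    if phenotype == "spread":
        return radius * math.sqrt(elongation) * 1.35
    return radius * 1.05


def generate_well(
    well_id: str,
    mixture: np.ndarray,
    rng: np.random.Generator,
    params: WellImageParams = WellImageParams(),
    n_colonies: int | None = None,
) -> tuple[WellImage, pd.DataFrame]:
    """Render one well given its phenotype mixture.

    Draws the colony count (unless given), per-colony phenotypes i.i.d. from
    ``mixture``, sizes and non-overlapping positions, then renders and adds
    background and Gaussian read noise.  Returns the image and the colony
    ground-truth table (``cx``/``cy`` are column/row pixel coordinates).
    """
    p = params
    if n_colonies is None:
        n_colonies = sample_colony_count(rng, p.counts)
    phenos = rng.choice(len(PHENOTYPES), size=n_colonies, p=mixture)

    img = np.zeros((p.size_px, p.size_px), float)
    placed: list[tuple[float, float, float]] = []  # (cy, cx, bounding radius)
    records = []
    colony_idx = 0
    for k in phenos:
        phenotype = PHENOTYPES[k]
        median = p.radius_median_px * (
            p.spread_radius_factor if phenotype == "spread" else 1.0
        )
        radius = float(median * np.exp(p.radius_sigma * rng.standard_normal()))
        elong = (
            float(rng.uniform(*p.spread_elongation)) if phenotype == "spread" else 1.0
        )
        orient = float(rng.uniform(0, np.pi))
        rb = _bounding_radius(phenotype, radius, elong)
        half = int(math.ceil(rb)) + 2   # patch half-width (as in render_colony)
        lo, hi = half + 1.0, p.size_px - half - 2.0
        if hi <= lo:
            log.warning("%s: colony larger than the well; dropped", well_id)
            continue
        pos = None
        for _ in range(p.max_place_tries):
            cy, cx = rng.uniform(lo, hi, size=2)
            if all(
                np.hypot(cy - y0, cx - x0) > rb + r0 + p.separation_px
                for y0, x0, r0 in placed
            ):
                pos = (cy, cx)
                break
        if pos is None:
            log.warning("%s: placement failed after %d tries; count reduced",
                        well_id, p.max_place_tries)
            continue
        cy, cx = pos
        patch, _ = render_colony(
            phenotype, radius, p.intensity, rng, elongation=elong, orientation=orient
        )
        half = patch.shape[0] // 2
        iy = int(np.clip(round(cy), half, p.size_px - half - 1))
        ix = int(np.clip(round(cx), half, p.size_px - half - 1))
        img[iy - half : iy + half + 1, ix - half : ix + half + 1] += patch
        placed.append((cy, cx, rb))
        records.append(
            {
                "well_id": well_id, "colony_id": colony_idx,
                "phenotype": phenotype, "cx": float(ix), "cy": float(iy),
                "radius": radius, "elongation": elong,
            }
        )
        colony_idx += 1

    img += p.background
    if p.noise_sd > 0:
        img += rng.normal(0.0, p.noise_sd, img.shape)
    pixels = np.clip(np.round(img), 0, 65535).astype(np.uint16)
    truth = pd.DataFrame(
        records,
        columns=["well_id", "colony_id", "phenotype", "cx", "cy", "radius",
                 "elongation"],
    )
    return WellImage(pixels, well_id, p.pixel_size_um), truth


def generate_plate(
    layout: PlateLayout,
    model: PhenotypeEffectModel | None = None,
    seed: int = 0,
    params: WellImageParams = WellImageParams(),
    out_dir: str | Path | None = None,
) -> tuple[dict[str, WellImage], pd.DataFrame]:
    """Render every well of a plate layout.

    The plate seed deterministically derives one independent stream per well,
    so any subset of wells re-renders byte-identically.  When ``out_dir`` is
    given, each well is written as ``<well_id>.tif`` (16-bit) along with a
    ``truth.csv`` ground-truth table.
    """
    model = model or PhenotypeEffectModel()
    ss = np.random.SeedSequence(seed)
    images: dict[str, WellImage] = {}
    tables = []
    for child, (well_id, cid, _rep) in zip(ss.spawn(len(layout.wells)), layout.wells):
        rng = np.random.default_rng(child)
        cond = layout.conditions[cid]
        n = sample_colony_count(rng, params.counts)
        mix = sample_well_mixture(model, cond, rng)
        wimg, truth = generate_well(well_id, mix, rng, params, n_colonies=n)
        images[well_id] = wimg
        tables.append(truth)
    truth = pd.concat(tables, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for well_id, wimg in images.items():
            tifffile.imwrite(out / f"{well_id}.tif", wimg.pixels)
        truth.to_csv(out / "truth.csv", index=False)
    return images, truth


def zero_noise(params: WellImageParams) -> WellImageParams:
    """Copy of ``params`` with read noise and speckle texture disabled."""
    return replace(
        params,
        noise_sd=0.0,
        intensity=replace(params.intensity, texture_amplitude=0.0,
                          rim_clump_amplitude=0.0),
    )
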