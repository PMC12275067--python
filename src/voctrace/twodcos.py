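"""Synchronous generalized two-dimensional correlation spectroscopy (2DCOS).

A perturbation series of m spectra is centered against a reference spectrum
(by default its own mean) to give the dynamic spectrum; the synchronous map
is the covariance of the dynamic intensity series between every pair of
wavenumbers:

    Phi(n1, n2) = (1 / norm) * f(n1)^T f(n2)

with ``norm`` either m - 1 (sample covariance, the default) or m (the
convention some instruments print).  The map is rendered as a fixed-size
8-bit RGB raster through a diverging blue-white-red colormap; rendering is
min-max normalized per image and therefore invariant to positive rescaling
of the map, so the normalization choice does not affect the imagery.

One image per sample is produced by treating the sample's replicate scans as
the perturbation series, centered on the data-set mean spectrum (the
``global-mean`` mode); a ``self-mean`` mode centers on the sample's own
replicate mean instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .containers import SpectrumSet

#: Diverging colormap: blue = negative correlation, red/white = positive.
COLORMAP = "RdBu_r"


@dataclass
class DynamicSpectrum:
    """Deviation spectra of a perturbation series (m x p)."""

    deviations: np.ndarray
    wavenumbers: np.ndarray

    @property
    def m(self) -> int:
        return self.deviations.shape[0]


@dataclass
class SyncMap:
    """Synchronous correlation map Phi (p x p) with its wavenumber grid."""

    phi: np.ndarray
    wavenumbers: np.ndarray
    norm: float


def dynamic_spectrum(
    spectra: np.ndarray,
    wavenumbers: np.ndarray | None = None,
    reference: np.ndarray | None = None,
) -> DynamicSpectrum:
    """Subtract the reference (default: series mean) from each spectrum."""
    y = np.asarray(spectra, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2:
        raise ValueError("need an m x p matrix with m >= 2")
    ref = y.mean(axis=0) if reference is None else np.asarray(reference, float)
    wn = np.arange(y.shape[1], dtype=float) if wavenumbers is None else np.asarray(wavenumbers)
    return DynamicSpectrum(deviations=y - ref, wavenumbers=wn)


def sync_map(d: DynamicSpectrum, norm: str = "m-1") -> SyncMap:
    """Synchronous map: scaled cross-product of deviation series."""
    if norm == "m-1":
        denom = d.m - 1
    elif norm in ("m", "paper"):
        denom = d.m
    else:
        raise ValueError("norm must be 'm-1' or 'm'")
    if denom <= 0:
        raise ValueError("perturbation series too short")
    phi = d.deviations.T @ d.deviations / denom
    return SyncMap(phi=phi, wavenumbers=d.wavenumbers, norm=float(denom))


def render_image(sync: SyncMap, size: int = 128) -> Image.Image:
    """Render a map as a size x size 8-bit RGB image.

    Bilinear resampling to the target size, per-image min-max normalization,
    fixed diverging colormap.  Axes follow spectroscopic display convention:
    wavenumber decreases left -> right and bottom -> top.
    """
    phi = np.asarray(sync.phi, dtype=float)
    if phi.shape[0] < 2:
        raise ValueError("map must be at least 2 x 2")
    lo, hi = phi.min(), phi.max()
    if hi - lo == 0:
        warnings.warn("constant map; rendering flat mid-colormap image")
        unit = np.full_like(phi, 0.5)
    else:
        unit = (phi - lo) / (hi - lo)

    # orient: row index = n2 increasing upward, column index = n1
    if sync.wavenumbers[0] < sync.wavenumbers[-1]:  # ascending grid: flip both
        unit = unit[::-1, ::-1]
    img = Image.fromarray(np.ascontiguousarray(unit[::-1]))  # row 0 at top
    img = img.resize((size, size), resample=Image.BILINEAR)
    rgba = colormaps[COLORMAP](np.asarray(img, dtype=float))
    return Image.fromarray((rgba[..., :3] * 255).round().astype(np.uint8))


def per_sample_sync_images(
    s: SpectrumSet,
    size: int = 128,
    mode: str = "global-mean",
    norm: str = "m-1",
    out_dir: str | Path | None = None,
    image_format: str = "png",
) -> dict[str, Image.Image]:
    """One synchronous 2DCOS image per sample from its replicate scans.

    ``global-mean``: reference is the data-set mean spectrum (replicate scans
    deviate from the cohort, so between-class composition differences reach
    the maps).  ``self-mean``: reference is the sample's own replicate mean.
    """
    if mode not in ("global-mean", "self-mean"):
        raise ValueError("mode must be 'global-mean' or 'self-mean'")
    global_ref = s.absorbance.mean(axis=0)
    images: dict[str, Image.Image] = {}
    for sid in s.samples:
        scans = s.scans_of(sid)
        if scans.shape[0] < 2:
            raise ValueError(f"sample {sid} has < 2 scans; need a perturbation series")
        ref = global_ref if mode == "global-mean" else None
        d = dynamic_spectrum(scans, s.wavenumbers, reference=ref)
        images[sid] = render_image(sync_map(d, norm=norm), size=size)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, img in images.items():
            img.save(out / f"{sid}_{s.origins.get(sid, 'NA')}.{image_format}")
    return images
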