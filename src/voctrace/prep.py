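"""Replicate averaging and the five spectral preprocessing operators.

All operators act row-wise on a :class:`~voctrace.containers.SpectrumSet`,
preserve scan order and labels, and record their name in the set's
provenance metadata:

* ``SG`` — Savitzky-Golay smoothing (11-point window, cubic polynomial);
* ``1stDer`` / ``2ndDer`` — Savitzky-Golay derivatives w.r.t. wavenumber,
  scaled by the grid step so values are per cm^-1 (per cm^-2);
* ``SNV`` — standard normal variate (row centering/scaling);
* ``MSC`` — multiplicative scatter correction against a reference spectrum.

Edges of the SG filters are handled by polynomial fits on the truncated
window (scipy's ``interp`` mode), so no points are lost or padded.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import savgol_filter

from .containers import SpectrumSet

METHODS = ("raw", "SG", "1stDer", "2ndDer", "SNV", "MSC")


def average_replicates(s: SpectrumSet) -> SpectrumSet:
    """Collapse replicate scans to one mean spectrum per sample."""
    samples = s.samples
    counts = {sid: s.sample_ids.count(sid) for sid in samples}
    if len(set(counts.values())) > 1:
        warnings.warn("unequal replicate counts; averaging available scans")
    rows = np.vstack([s.scans_of(sid).mean(axis=0) for sid in samples])
    return SpectrumSet(
        wavenumbers=s.wavenumbers,
        absorbance=rows,
        sample_ids=samples,
        replicates=[1] * len(samples),
        origins=s.origins,
        meta={**s.meta, "replicates_averaged": True},
    )


def _check_window(s: SpectrumSet, window: int, polyorder: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if s.n_points < window:
        raise ValueError(f"spectrum has {s.n_points} points < window {window}")


def sg_smooth(s: SpectrumSet, window: int = 11, polyorder: int = 3) -> SpectrumSet:
    """Savitzky-Golay least-squares local polynomial smoothing."""
    _check_window(s, window, polyorder)
    out = savgol_filter(s.absorbance, window, polyorder, axis=1, mode="interp")
    return s.with_absorbance(out, method="SG", window=window, polyorder=polyorder)


def derivative(
    s: SpectrumSet, order: int = 1, window: int = 11, polyorder: int = 3
) -> SpectrumSet:
    """Savitzky-Golay derivative with respect to wavenumber.

    The physical grid step enters through ``delta``, so a first derivative of
    a*nu + b returns a regardless of grid direction or spacing.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    _check_window(s, window, polyorder)
    if order > polyorder:
        raise ValueError("order must be <= polyorder")
    step = float(np.mean(np.diff(s.wavenumbers)))  # signed; negative if descending
    out = savgol_filter(
        s.absorbance, window, polyorder, deriv=order, delta=abs(step), axis=1, mode="interp"
    )
    if step < 0:  # odd derivatives flip sign on a descending axis
        out = out * ((-1.0) ** order)
    return s.with_absorbance(out, method=f"{order}stDer" if order == 1 else "2ndDer")


def snv(s: SpectrumSet) -> SpectrumSet:
    """Standard normal variate: each scan to mean 0, SD 1."""
    x = s.absorbance
    sd = x.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = [s.sample_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance scans cannot be SNV-scaled: {bad}")
    out = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return s.with_absorbance(out, method="SNV")


def msc(s: SpectrumSet, reference: np.ndarray | None = None) -> SpectrumSet:
    """Multiplicative scatter correction.

    Each scan is regressed on the reference spectrum, x ~ a + b*ref, and
    corrected to (x - a)/b.  The reference defaults to the set's mean scan;
    pass the calibration-set reference when transforming held-out data.
    """
    x = s.absorbance
    if reference is None:
        if x.shape[0] < 2:
            raise ValueError("MSC needs >= 2 scans or an explicit reference")
        reference = x.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    refc = ref - ref.mean()
    denom = float(refc @ refc)
    b = (x - x.mean(axis=1, keepdims=True)) @ refc / denom
    if (np.abs(b) < 1e-8).any():
        bad = [s.sample_ids[i] for i in np.flatnonzero(np.abs(b) < 1e-8)]
        raise ValueError(f"MSC slope ~ 0 for scans: {bad}")
    a = x.mean(axis=1) - b * ref.mean()
    out = (x - a[:, None]) / b[:, None]
    return s.with_absorbance(out, method="MSC", msc_reference=ref)


def preprocess(s: SpectrumSet, method: str, **kwargs) -> SpectrumSet:
    """Dispatch a named preprocessing method (``raw`` is the identity)."""
    if method == "raw":
        return s.with_absorbance(s.absorbance.copy(), method="raw")
    if method == "SG":
        return sg_smooth(s, **kwargs)
    if method == "1stDer":
        return derivative(s, order=1, **kwargs)
    if method == "2ndDer":
        return derivative(s, order=2, **kwargs)
    if method == "SNV":
        return snv(s)
    if method == "MSC":
        return msc(s, **kwargs)
    raise ValueError(f"unknown preprocessing method {method!r}; choose from {METHODS}")
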