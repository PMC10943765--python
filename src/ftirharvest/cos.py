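"""Generalized two-dimensional correlation spectroscopy.

Given a series of spectra measured along a perturbation (time, month,
replicate scan, ...), the synchronous map Phi(v1, v2) measures in-phase
intensity co-variation between two wavenumbers and the asynchronous map
Psi(v1, v2) — obtained through the Hilbert–Noda transformation matrix —
measures out-of-phase (sequential) variation.  Their elementwise product,
the integrated map, concentrates features present in both.  Rendered as
images, these maps are the input to the residual-CNN classifier.

With dynamic spectra S (rows = m perturbation steps, columns = wavenumbers):

    Phi = S^T S / (m - 1)
    Psi = S^T N S / (m - 1),   N_jk = 0 if j = k else 1 / (pi (k - j))

Phi is symmetric with a non-negative diagonal; Psi is antisymmetric with a
zero diagonal (Noda's rules).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "DynamicSpectra",
    "CosMaps",
    "dynamic_spectra",
    "hilbert_noda",
    "synchronous",
    "asynchronous",
    "integrated",
    "compute_cos_maps",
    "cos_for_sample",
    "cos_for_month",
    "render_cos_image",
    "decimate_grid",
]


@dataclass
class DynamicSpectra:
    """Reference-subtracted perturbation series.

    values: (m, p) matrix, rows ordered along the perturbation;
    reference: the spectrum that was subtracted (zeros for reference='none').
    """

    values: np.ndarray
    reference: np.ndarray

    @property
    def m(self) -> int:
        return self.values.shape[0]


@dataclass
class CosMaps:
    """Synchronous (phi), asynchronous (psi) and integrated maps on a
    wavenumber-by-wavenumber grid, plus the number of perturbation steps."""

    phi: np.ndarray
    psi: np.ndarray
    integrated: np.ndarray
    axis: np.ndarray
    m: int


def dynamic_spectra(s: SpectraSet, reference: str = "mean") -> DynamicSpectra:
    """Build dynamic spectra from a perturbation-ordered SpectraSet.

    ``reference`` is 'mean' (default; every column then sums to zero),
    'first' (subtract the first spectrum) or 'none'.
    """
    if s.n_spectra < 2:
        raise ValueError("a perturbation series needs at least 2 spectra")
    x = s.absorbance
    if reference == "mean":
        ref = x.mean(axis=0)
    elif reference == "first":
        ref = x[0].copy()
    elif reference == "none":
        ref = np.zeros(s.n_points)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return DynamicSpectra(values=x - ref, reference=ref)


def hilbert_noda(m: int) -> np.ndarray:
    """Hilbert–Noda transformation matrix: zero diagonal, 1/(pi (k - j))
    off-diagonal.  Antisymmetric by construction."""
    if m < 2:
        raise ValueError("Hilbert-Noda matrix needs m >= 2")
    j, k = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    with np.errstate(divide="ignore"):
        n = 1.0 / (np.pi * (k - j))
    np.fill_diagonal(n, 0.0)
    return n


def synchronous(d: DynamicSpectra) -> np.ndarray:
    """Synchronous correlation map Phi = S^T S / (m - 1)."""
    s = d.values
    return s.T @ s / (d.m - 1)


def asynchronous(d: DynamicSpectra) -> np.ndarray:
    """Asynchronous correlation map Psi = S^T N S / (m - 1) with N the
    Hilbert–Noda matrix."""
    s = d.values
    n = hilbert_noda(d.m)
    return s.T @ n @ s / (d.m - 1)


def integrated(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Integrated map: elementwise product of synchronous and asynchronous."""
    if phi.shape != psi.shape:
        raise ValueError(f"shape mismatch {phi.shape} vs {psi.shape}")
    return phi * psi


def compute_cos_maps(s: SpectraSet, reference: str = "mean") -> CosMaps:
    """All three correlation maps for a perturbation-ordered SpectraSet."""
    d = dynamic_spectra(s, reference=reference)
    phi = synchronous(d)
    psi = asynchronous(d)
    return CosMaps(phi=phi, psi=psi, integrated=integrated(phi, psi),
                   axis=s.wavenumbers.copy(), m=d.m)


def decimate_grid(s: SpectraSet, max_points: int = 256) -> SpectraSet:
    """Uniform-stride decimation to at most ``max_points`` grid points,
    keeping the O(p^2) correlation maps tractable."""
    p = s.n_points
    if p <= max_points:
        return s
    stride = int(np.ceil(p / max_points))
    keep = np.arange(0, p, stride)
    return SpectraSet(s.wavenumbers[keep], s.absorbance[:, keep], s.meta.copy())


def cos_for_sample(
    s: SpectraSet,
    sample_key: tuple,
    augmentation: int = 0,
    seed: int = 0,
    max_points: int = 256,
    reference: str = "mean",
) -> CosMaps:
    """Correlation maps for one sample, using its replicate scans as the
    perturbation series.

    ``sample_key`` is (month, part, sample_id).  With ``augmentation`` > 0,
    the series is extended by bootstrap-perturbed copies: a randomly chosen
    replicate plus Gaussian noise at the per-wavenumber replicate-residual
    scale, drawn from a generator seeded with ``seed`` (fully reproducible).
    """
    month, part, sample_id = sample_key
    mask = (
        (s.meta["month"] == month)
        & (s.meta["part"] == part)
        & (s.meta["sample_id"] == sample_id)
    ).to_numpy()
    if not mask.any():
        raise KeyError(f"no spectra for sample {sample_key}")
    sub = decimate_grid(s.select(mask), max_points=max_points)
    x = sub.absorbance
    if x.shape[0] + max(augmentation, 0) < 2:
        raise ValueError(
            "perturbation series needs >= 2 spectra; provide more replicates "
            "or augmentation >= 2"
        )
    if augmentation > 0:
        rng = np.random.default_rng(seed)
        resid_sd = x.std(axis=0, ddof=0) if x.shape[0] > 1 else np.abs(x[0]) * 0.01
        extra = []
        for _ in range(augmentation):
            base = x[rng.integers(0, x.shape[0])]
            extra.append(base + rng.normal(0.0, 1.0, size=base.shape) * resid_sd)
        x = np.vstack([x, np.vstack(extra)])
    series = SpectraSet(
        sub.wavenumbers,
        x,
        sub.meta.iloc[[0] * x.shape[0]].assign(replicate=np.arange(1, x.shape[0] + 1)),
    )
    return compute_cos_maps(series, reference=reference)


def cos_for_month(
    s: SpectraSet, part: str, max_points: int = 256, reference: str = "mean"
) -> CosMaps:
    """Month-level overview maps: the perturbation series is the sequence of
    monthly mean spectra (months in calendar order) for one plant part."""
    mask = (s.meta["part"] == part).to_numpy()
    sub = decimate_grid(s.select(mask), max_points=max_points)
    months = np.sort(sub.meta["month"].unique())
    if len(months) < 2:
        raise ValueError("month-level maps need spectra from >= 2 months")
    rows = [sub.absorbance[(sub.meta["month"] == mth).to_numpy()].mean(axis=0)
            for mth in months]
    import pandas as pd

    meta = pd.DataFrame(
        {"sample_id": [f"month-{mth}" for mth in months], "month": months,
         "part": part, "replicate": 1}
    )
    series = SpectraSet(sub.wavenumbers, np.vstack(rows), meta)
    return compute_cos_maps(series, reference=reference)


def render_cos_image(
    maps: CosMaps,
    which: str = "phi",
    size_px: int = 224,
    colormap: str = "jet",
    path=None,
) -> np.ndarray:
    """Render one correlation map as an RGB image array (and optionally PNG).

    The matrix is min–max scaled to [0, 1] (a constant matrix maps to a
    uniform 0.5), passed through the named matplotlib colormap and resampled
    to ``size_px`` x ``size_px`` with bilinear interpolation.  Fully
    deterministic: fixed inputs give a byte-identical PNG.

    Returns the (size_px, size_px, 3) uint8 array.
    """
    import matplotlib

    from PIL import Image

    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    mat = {"phi": maps.phi, "psi": maps.psi, "integrated": maps.integrated}[which]
    lo, hi = float(mat.min()), float(mat.max())
    scaled = np.full_like(mat, 0.5) if hi == lo else (mat - lo) / (hi - lo)
    cmap = matplotlib.colormaps[colormap]
    rgb = (cmap(scaled)[..., :3] * 255).round().astype(np.uint8)
    img = Image.fromarray(rgb).resize((size_px, size_px), Image.BILINEAR)
    if path is not None:
        img.save(path, format="PNG")
    return np.asarray(img)
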