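"""Spectral pretreatments and calibration/test partitioning.

Covers the scatter and resolution corrections standard in diffuse-reflectance
chemometrics — Savitzky–Golay smoothing and derivatives (FD/SD), multiplicative
scatter correction (MSC), standard normal variate (SNV) — plus the
Kennard–Stone maximin split used to carve a representative 70/30
calibration/test partition.

Derivatives are implemented as Savitzky–Golay filters (the standard
chemometric practice); the same polynomial is extended to the edges so the
wavenumber grid is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial.distance import cdist

from .spectra import SpectraSet

__all__ = [
    "PreprocessSpec",
    "SplitResult",
    "DegenerateSpectrumError",
    "derivative",
    "msc",
    "snv",
    "sg_smooth",
    "apply_preprocess",
    "kennard_stone_split",
]


class DegenerateSpectrumError(ValueError):
    """A spectrum is flat/constant where the transform needs variation."""


@dataclass(frozen=True)
class PreprocessSpec:
    """Pretreatment choice with Savitzky–Golay window settings.

    method: one of raw, fd, sd, msc, snv, sg.
    window: odd number of points (default 9); polyorder: polynomial degree
    (default 2, must be < window).  Window settings only matter for
    fd/sd/sg.
    """

    method: str = "raw"
    window: int = 9
    polyorder: int = 2

    def __post_init__(self):
        if self.method not in ("raw", "fd", "sd", "msc", "snv", "sg"):
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be odd and >= 3")
        if not 1 <= self.polyorder < self.window:
            raise ValueError("need 1 <= polyorder < window")


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/test row indices from a deterministic split."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    train_fraction: float


def _check_sg(window: int, polyorder: int, n_cols: int) -> None:
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if window > n_cols:
        raise ValueError(f"window {window} exceeds spectrum length {n_cols}")


def derivative(s: SpectraSet, order: int, window: int = 9, polyorder: int = 2) -> SpectraSet:
    """Savitzky–Golay derivative with respect to wavenumber, row-wise.

    ``order`` 1 gives the first derivative (FD), 2 the second (SD).  The sign
    convention is a true d/d(wavenumber): on the conventional descending
    4000->450 grid the index direction is flipped accordingly.
    """
    if order not in (1, 2):
        raise ValueError(f"derivative order must be 1 or 2, got {order}")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    _check_sg(window, polyorder, s.n_points)
    step = float(np.mean(np.diff(s.wavenumbers)))
    out = savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder,
        deriv=order, delta=abs(step), axis=1, mode="interp",
    )
    if step < 0 and order == 1:
        out = -out  # d/dv on a descending grid
    return s.with_absorbance(out)


def sg_smooth(s: SpectraSet, window: int = 9, polyorder: int = 2) -> SpectraSet:
    """Savitzky–Golay zero-order smoothing, row-wise; grid unchanged."""
    _check_sg(window, polyorder, s.n_points)
    out = savgol_filter(
        s.absorbance, window_length=window, polyorder=polyorder, axis=1, mode="interp"
    )
    return s.with_absorbance(out)


def msc(s: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference r (x ~ a + b r, ordinary
    least squares) and returned as (x - a) / b, removing additive offsets and
    multiplicative path-length effects.  The reference defaults to the mean
    spectrum of the set.
    """
    if s.n_points < 2:
        raise ValueError("MSC needs at least two wavenumber points")
    ref = s.absorbance.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (s.n_points,):
        raise ValueError("reference length does not match grid")
    rc = ref - ref.mean()
    denom = float(rc @ rc)
    if denom == 0.0:
        raise DegenerateSpectrumError("reference spectrum is constant")
    x = s.absorbance
    b = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(b == 0.0):
        row = int(np.flatnonzero(b == 0.0)[0])
        raise DegenerateSpectrumError(f"row {row}: zero regression slope against reference")
    a = x.mean(axis=1) - b * ref.mean()
    return s.with_absorbance((x - a[:, None]) / b[:, None])


def snv(s: SpectraSet) -> SpectraSet:
    """Standard normal variate: centre and scale each spectrum by its own
    mean and (sample) standard deviation."""
    x = s.absorbance
    sd = x.std(axis=1, ddof=1)
    if np.any(sd == 0.0):
        row = int(np.flatnonzero(sd == 0.0)[0])
        raise DegenerateSpectrumError(f"row {row}: constant spectrum has no SNV transform")
    return s.with_absorbance((x - x.mean(axis=1, keepdims=True)) / sd[:, None])


def apply_preprocess(s: SpectraSet, spec: PreprocessSpec) -> SpectraSet:
    """Dispatch a :class:`PreprocessSpec` onto a SpectraSet."""
    if spec.method == "raw":
        return s
    if spec.method == "fd":
        return derivative(s, 1, spec.window, spec.polyorder)
    if spec.method == "sd":
        return derivative(s, 2, spec.window, spec.polyorder)
    if spec.method == "msc":
        return msc(s)
    if spec.method == "snv":
        return snv(s)
    return sg_smooth(s, spec.window, spec.polyorder)


def kennard_stone_split(x: np.ndarray, train_fraction: float = 0.7) -> SplitResult:
    """Kennard–Stone maximin selection of a calibration subset.

    Seeds with the two rows at maximum Euclidean distance, then repeatedly
    adds the row whose minimum distance to the already-selected set is
    largest, until round(n * train_fraction) rows are selected (half-up
    rounding).  Ties break to the lowest row index, making the split fully
    deterministic.  Remaining rows form the test set.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("Kennard-Stone needs at least two rows")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(np.floor(n * train_fraction + 0.5))
    n_train = min(max(n_train, 1), n - 1)

    d = cdist(x, x)
    # seed pair: maximum distance, ties to lexicographically smallest (i, j);
    # np.argmax scans row-major so it already honours that tie-break
    i, j = np.unravel_index(np.argmax(d), d.shape)
    if i == j:  # all pairwise distances zero (duplicate-only data)
        i, j = 0, 1
    selected = [min(i, j), max(i, j)][:n_train]
    remaining = [k for k in range(n) if k not in selected]
    min_d = d[selected].min(axis=0)
    while len(selected) < n_train:
        best, best_val = remaining[0], -np.inf
        for k in remaining:
            v = min_d[k]
            if v > best_val:  # strict: ties keep the lowest index
                best, best_val = k, v
        selected.append(best)
        remaining.remove(best)
        min_d = np.minimum(min_d, d[best])
    return SplitResult(
        train_indices=np.array(selected, dtype=int),
        test_indices=np.array(remaining, dtype=int),
        train_fraction=train_fraction,
    )
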