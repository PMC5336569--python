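"""Spectral preprocessing: referencing, alignment, trimming, normalization,
binning, and Pareto scaling.

The steps run in the fixed order reference -> align -> trim -> normalize ->
(scale); set-level operations log each step and reject repeats or
out-of-order calls.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import META_COLUMNS, FeatureMatrix, Spectrum, SpectrumSet
from .errors import ProcessingOrderError, ReferencingError, ValidationError

__all__ = [
    "reference_to_tsp", "reference_set", "align_set", "trim_spectrum",
    "trim_set", "normalize_total", "to_feature_matrix", "ParetoScaler",
    "pareto_scale",
    "WATER_WINDOW", "KEEP_WINDOW", "TSP_TARGET",
]

#: Residual-water exclusion window (ppm, closed interval).
WATER_WINDOW = (4.67, 4.85)
#: Retained analysis window (ppm, closed interval).
KEEP_WINDOW = (0.5, 9.5)
#: Chemical-shift reference target for the TSP signal (ppm).
TSP_TARGET = -0.017

_STEP_ORDER = ("reference", "align", "trim", "normalize")
_EPS = 1e-9


def _check_order(sset: SpectrumSet, step: str) -> None:
    done = sset.steps_applied()
    if step in done:
        raise ProcessingOrderError(f"step {step!r} already applied")
    later = _STEP_ORDER[_STEP_ORDER.index(step) + 1:]
    applied_later = [s for s in later if s in done]
    if applied_later:
        raise ProcessingOrderError(
            f"cannot run {step!r} after {applied_later[0]!r}")


def _shift_edge_fill(y: np.ndarray, k: int) -> np.ndarray:
    """Shift a 1-D array by k bins toward higher index, filling gaps with the
    edge value."""
    if k == 0:
        return y.copy()
    out = np.empty_like(y)
    if k > 0:
        out[k:] = y[:-k]
        out[:k] = y[0]
    else:
        out[:k] = y[-k:]
        out[k:] = y[-1]
    return out


# ---------------------------------------------------------------------------
# referencing
# ---------------------------------------------------------------------------

def reference_to_tsp(s: Spectrum, tsp_target: float = TSP_TARGET,
                     search_window: tuple[float, float] = (-0.25, 0.25),
                     prominence_sds: float = 10.0) -> Spectrum:
    """Shift a spectrum (integer bins, edge padded) so the maximum inside the
    search window lands on the grid point nearest the TSP target.

    The peak must rise ``prominence_sds`` standard deviations above the
    window median; otherwise a :class:`ReferencingError` is raised.
    """
    lo, hi = min(search_window), max(search_window)
    mask = (s.ppm >= lo - _EPS) & (s.ppm <= hi + _EPS)
    if not mask.any():
        raise ReferencingError("spectrum does not cover the TSP search window")
    window = s.intensity[mask]
    prominence = prominence_sds * window.std()
    if window.max() - np.median(window) <= prominence or prominence == 0.0:
        raise ReferencingError("no reference peak above the prominence threshold")
    idx_window = np.flatnonzero(mask)
    i_peak = idx_window[int(np.argmax(window))]
    i_target = int(np.argmin(np.abs(s.ppm - tsp_target)))
    shift = i_target - i_peak
    return Spectrum(s.ppm.copy(), _shift_edge_fill(s.intensity, shift),
                    meta=dict(s.meta))


def reference_set(sset: SpectrumSet, tsp_target: float = TSP_TARGET,
                  **kwargs) -> SpectrumSet:
    """Apply :func:`reference_to_tsp` to every spectrum of a set."""
    _check_order(sset, "reference")
    out = np.vstack([
        reference_to_tsp(sset.spectrum(i), tsp_target=tsp_target, **kwargs).intensity
        for i in range(len(sset))
    ])
    res = sset.copy_with(intensities=out)
    res.log_step("reference", tsp_target=tsp_target)
    return res


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _best_lag(ref: np.ndarray, y: np.ndarray, max_lag: int) -> int:
    """Integer lag in [-max_lag, max_lag] maximizing the cross-correlation of
    ``y`` (shifted) against ``ref``; ties broken toward the smallest |lag|."""
    p = ref.size
    lags = np.arange(-max_lag, max_lag + 1)
    scores = np.empty(lags.size)
    for i, k in enumerate(lags):
        a, b = max(0, k), p + min(0, k)
        scores[i] = float(ref[a:b] @ y[a - k:b - k])
    best = scores.max()
    candidates = lags[scores >= best - _EPS * max(abs(best), 1.0)]
    return int(candidates[np.argmin(np.abs(candidates))])


def align_set(sset: SpectrumSet,
              segments: list[tuple[float, float]] | None = None,
              max_shift: float = 0.02) -> SpectrumSet:
    """Two-pass, median-referenced, per-segment integer-bin alignment.

    For each segment (default: the whole axis as one segment) and each
    spectrum, the integer-bin shift maximizing cross-correlation against the
    set's median spectrum is applied, gaps filled with the segment-edge
    value.  The median reference is recomputed once after a first pass; the
    cumulative shift per spectrum and segment is capped at ``max_shift``
    (a warning is issued when the cap binds).
    """
    _check_order(sset, "align")
    step = abs(sset.step)
    max_lag = int(round(max_shift / step))
    if segments is None:
        seg_masks = [np.ones(sset.ppm.size, dtype=bool)]
    else:
        seg_masks = []
        for lo, hi in segments:
            lo, hi = min(lo, hi), max(lo, hi)
            if hi - lo < 2 * max_shift:
                raise ValidationError(
                    f"segment ({lo}, {hi}) narrower than 2 x max_shift")
            seg_masks.append((sset.ppm >= lo - _EPS) & (sset.ppm <= hi + _EPS))

    out = sset.intensities.copy()
    n = len(sset)
    for mask in seg_masks:
        seg = out[:, mask]
        applied = np.zeros(n, dtype=int)
        for _ in range(2):  # two-pass scheme
            ref = np.median(seg, axis=0)
            for i in range(n):
                k = _best_lag(ref, seg[i], max_lag)
                total = applied[i] + k
                if abs(total) > max_lag:
                    total = int(np.clip(total, -max_lag, max_lag))
                    k = total - applied[i]
                    warnings.warn("alignment shift capped at max_shift",
                                  stacklevel=2)
                seg[i] = _shift_edge_fill(seg[i], k)
                applied[i] = total
        out[:, mask] = seg
    res = sset.copy_with(intensities=out)
    res.log_step("align", max_shift=max_shift,
                 segments=None if segments is None else list(map(tuple, segments)))
    return res


# ---------------------------------------------------------------------------
# trimming and normalization
# ---------------------------------------------------------------------------

def _trim_mask(ppm: np.ndarray,
               water: tuple[float, float] = WATER_WINDOW,
               keep: tuple[float, float] = KEEP_WINDOW) -> np.ndarray:
    in_keep = (ppm >= keep[0] - _EPS) & (ppm <= keep[1] + _EPS)
    in_water = (ppm >= water[0] - _EPS) & (ppm <= water[1] + _EPS)
    return in_keep & ~in_water


def trim_spectrum(s: Spectrum, water: tuple[float, float] = WATER_WINDOW,
                  keep: tuple[float, float] = KEEP_WINDOW) -> Spectrum:
    """Drop the residual-water window and everything outside the retained
    analysis window (both intervals closed)."""
    mask = _trim_mask(s.ppm, water, keep)
    if not mask.any():
        raise ValidationError("trimming removed the whole spectrum")
    return Spectrum(s.ppm[mask], s.intensity[mask], meta=dict(s.meta))


def trim_set(sset: SpectrumSet, water: tuple[float, float] = WATER_WINDOW,
             keep: tuple[float, float] = KEEP_WINDOW) -> SpectrumSet:
    _check_order(sset, "trim")
    mask = _trim_mask(sset.ppm, water, keep)
    if not mask.any():
        raise ValidationError("trimming removed the whole spectrum")
    res = sset.copy_with(intensities=sset.intensities[:, mask],
                         ppm=sset.ppm[mask])
    res.log_step("trim", water=tuple(water), keep=tuple(keep))
    return res


def normalize_total(sset: SpectrumSet) -> SpectrumSet:
    """Divide each spectrum by its own total intensity (row sums become 1),
    suppressing sample-amount (dilution) variation."""
    _check_order(sset, "normalize")
    totals = sset.intensities.sum(axis=1)
    if np.any(totals <= 0):
        bad = sset.meta.loc[totals <= 0, "sample_id"].tolist()
        raise ValidationError(f"non-positive total intensity for {bad}")
    res = sset.copy_with(intensities=sset.intensities / totals[:, None])
    res.log_step("normalize")
    return res


# ---------------------------------------------------------------------------
# feature matrix
# ---------------------------------------------------------------------------

def to_feature_matrix(sset: SpectrumSet,
                      bin_width: float | None = None) -> FeatureMatrix:
    """Turn an (aligned, trimmed) spectrum set into a samples x variables
    matrix.

    With ``bin_width`` None, columns are the grid points themselves.
    Otherwise columns are means over half-open ppm bins of that width; a
    point on a bin boundary is assigned to the higher-ppm bin only.  Column
    labels are bin centers.
    """
    meta = sset.meta.set_index("sample_id")[list(META_COLUMNS[1:])]
    meta.insert(0, "sample_id", meta.index)
    if bin_width is None:
        values = pd.DataFrame(sset.intensities, index=meta.index,
                              columns=np.round(sset.ppm, 6))
    else:
        if bin_width < abs(sset.step) - _EPS:
            raise ValidationError("bin_width smaller than the grid step")
        origin = float(sset.ppm.min())
        idx = np.floor((sset.ppm - origin) / bin_width + _EPS).astype(int)
        centers = origin + (np.unique(idx) + 0.5) * bin_width
        sums = np.zeros((len(sset), np.unique(idx).size))
        remap = {b: j for j, b in enumerate(np.unique(idx))}
        counts = np.zeros(sums.shape[1])
        for col, b in enumerate(idx):
            j = remap[b]
            sums[:, j] += sset.intensities[:, col]
            counts[j] += 1
        values = pd.DataFrame(sums / counts, index=meta.index,
                              columns=np.round(centers, 6))
        values = values[sorted(values.columns, reverse=True)]
    normalized = "normalize" in sset.steps_applied()
    return FeatureMatrix(values, meta, normalized=normalized, scaling="none")


# ---------------------------------------------------------------------------
# Pareto scaling
# ---------------------------------------------------------------------------

class ParetoScaler(BaseEstimator, TransformerMixin):
    """Pareto scaling: divide each variable by the square root of its
    standard deviation (n-1 denominator), optionally mean-centering first.

    A compromise between unit-variance scaling and no scaling that damps the
    dominance of intense NMR signals without blowing up baseline noise.
    Zero-variance columns become all-zero when centering, and are left
    unscaled (with a warning) otherwise.
    """

    def __init__(self, center: bool = True):
        self.center = center

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("Pareto scaling needs >= 2 rows")
        sd = X.std(axis=0, ddof=1)
        zero = sd == 0.0
        if zero.any() and not self.center:
            warnings.warn(f"{int(zero.sum())} zero-variance columns left unscaled",
                          stacklevel=2)
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(zero, 1.0, np.sqrt(np.where(zero, 1.0, sd)))
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if self.center:
            X = X - self.mean_
        return X / self.scale_


def pareto_scale(m: FeatureMatrix, centered: bool = True) -> FeatureMatrix:
    """Pareto-scale a feature matrix, updating its provenance flag."""
    if m.scaling != "none":
        raise ProcessingOrderError(f"matrix already scaled ({m.scaling})")
    scaler = ParetoScaler(center=centered).fit(m.X)
    values = pd.DataFrame(scaler.transform(m.X), index=m.values.index,
                          columns=m.values.columns)
    return m.copy_with(values=values,
                       scaling="pareto_centered" if centered else "pareto_uncentered")
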