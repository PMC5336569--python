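"""In-memory containers for spectra and feature matrices.

A :class:`Spectrum` is a single processed 1D NMR trace (intensity versus
chemical shift in ppm); a :class:`SpectrumSet` holds many spectra on one
common ppm grid together with sample metadata and an append-only log of the
preprocessing steps applied so far.  A :class:`FeatureMatrix` is the
samples x variables table the multivariate analyses consume, carrying
normalization/scaling provenance flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical metadata columns for a sample.
META_COLUMNS = ("sample_id", "sex", "temperature_C", "replicate")


@dataclass
class Spectrum:
    """A single 1D spectrum on a strictly monotone ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValidationError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValidationError("intensities must be finite")

    @property
    def step(self) -> float:
        """Grid step (signed; negative for the descending NMR convention)."""
        return float(self.ppm[1] - self.ppm[0])


class SpectrumSet:
    """A collection of spectra sharing one ppm grid.

    Parameters
    ----------
    ppm : array, shape (p,)
        Common chemical-shift axis, strictly monotone (stored as given;
        the simulator emits it descending, the NMR convention).
    intensities : array, shape (n, p)
        One row per sample.
    meta : DataFrame
        One row per sample with at least the columns in ``META_COLUMNS``.
    """

    def __init__(self, ppm, intensities, meta: pd.DataFrame,
                 processing_log: list[dict] | None = None):
        self.ppm = np.asarray(ppm, dtype=float)
        self.intensities = np.asarray(intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.ppm.size:
            raise ValidationError("intensities must be (n_samples, n_points)")
        if len(meta) != self.intensities.shape[0]:
            raise ValidationError("metadata rows must match spectra")
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        if meta["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in metadata")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")
        self.meta = meta.reset_index(drop=True)
        self.processing_log: list[dict] = list(processing_log or [])

    # -- bookkeeping ----------------------------------------------------
    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def step(self) -> float:
        return float(self.ppm[1] - self.ppm[0])

    def steps_applied(self) -> list[str]:
        return [entry["step"] for entry in self.processing_log]

    def log_step(self, step: str, **params) -> None:
        self.processing_log.append({"step": step, **params})

    def copy_with(self, intensities=None, ppm=None) -> "SpectrumSet":
        return SpectrumSet(
            self.ppm if ppm is None else ppm,
            self.intensities if intensities is None else intensities,
            self.meta.copy(),
            processing_log=[dict(e) for e in self.processing_log],
        )

    def select(self, mask) -> "SpectrumSet":
        """Row subset (boolean mask or index array), log preserved."""
        mask = np.asarray(mask)
        return SpectrumSet(self.ppm.copy(), self.intensities[mask],
                           self.meta.loc[mask].reset_index(drop=True),
                           processing_log=[dict(e) for e in self.processing_log])

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.ppm.copy(), self.intensities[i].copy(),
                        meta=self.meta.iloc[i].to_dict())


class FeatureMatrix:
    """Samples x variables matrix with scaling provenance.

    ``values`` is a DataFrame indexed by sample_id; ``meta`` carries the
    sample metadata aligned on the same index.  ``scaling`` is one of
    ``"none"``, ``"pareto_centered"``, ``"pareto_uncentered"``.
    """

    SCALINGS = ("none", "pareto_centered", "pareto_uncentered")

    def __init__(self, values: pd.DataFrame, meta: pd.DataFrame,
                 normalized: bool = False, scaling: str = "none"):
        if values.index.duplicated().any():
            raise ValidationError("duplicate row labels")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate column labels")
        if scaling not in self.SCALINGS:
            raise ValidationError(f"unknown scaling {scaling!r}")
        self.values = values
        self.meta = meta
        self.normalized = bool(normalized)
        self.scaling = scaling

    @property
    def X(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def copy_with(self, values=None, scaling=None) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy() if values is None else values,
            self.meta.copy(),
            normalized=self.normalized,
            scaling=self.scaling if scaling is None else scaling,
        )

    def validate_normalized(self, tol: float = 1e-9) -> None:
        """Check the row-sum invariant of a normalized, unscaled matrix."""
        if self.normalized and self.scaling == "none":
            sums = self.values.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=tol):
                raise ValidationError("normalized rows must sum to 1")
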