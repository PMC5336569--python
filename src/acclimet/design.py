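"""Experimental design of the developmental-temperature study.

The study rears Drosophila melanogaster from egg to adult at 10 constant
temperatures spanning the permissible range (12-32 C), with both sexes,
five replicate pools of 40 flies per sex x temperature for NMR, 20 vials of
40 eggs per temperature for viability/developmental time, and 20 flies per
sex per temperature for the thermal-limit assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: The 10 constant developmental temperatures (degrees C).
DEFAULT_TEMPERATURES = (12.0, 15.5, 18.0, 20.0, 22.0, 25.0, 27.0, 29.5, 31.0, 32.0)

#: Temperatures treated as "extreme" by the U-shape prior.
EXTREME_TEMPERATURES = frozenset({12.0, 15.5, 31.0, 32.0})


@dataclass(frozen=True)
class SimulationDesign:
    """Layout of a simulated dataset.

    Attributes
    ----------
    temperatures : tuple of float
        Developmental temperatures in C, strictly increasing, within [12, 32].
    sexes : tuple of str
        Sex labels, default ``("female", "male")``.
    replicates_per_cell : int
        Pooled-fly spectra per sex x temperature cell.
    vials_per_temperature : int
        Vials of eggs set up per temperature.
    eggs_per_vial : int
        Eggs deposited per vial.
    flies_assayed_per_cell : int
        Individuals per sex x temperature in each thermal-limit assay.
    ppm_grid : (min_ppm, max_ppm, step)
        Chemical-shift axis specification; must cover [-0.1, 9.6] so both the
        TSP reference peak and the 9.5-0.5 ppm analysis window exist.
    """

    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    sexes: tuple[str, ...] = ("female", "male")
    replicates_per_cell: int = 5
    vials_per_temperature: int = 20
    eggs_per_vial: int = 40
    flies_assayed_per_cell: int = 20
    ppm_grid: tuple[float, float, float] = (-0.1, 9.6, 0.001)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValidationError("temperatures must be strictly increasing")
        if t.min() < 12.0 or t.max() > 32.0:
            raise ValidationError("temperatures must lie within [12, 32] C")
        if self.replicates_per_cell < 2:
            raise ValidationError("replicates_per_cell must be >= 2")
        if self.eggs_per_vial < 1:
            raise ValidationError("eggs_per_vial must be >= 1")
        lo, hi, step = self.ppm_grid
        if not (lo <= -0.1 and hi >= 9.6 and step > 0):
            raise ValidationError("ppm grid must cover [-0.1, 9.6] with positive step")

    # -- derived quantities --------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.temperatures) * len(self.sexes)

    @property
    def n_spectra(self) -> int:
        return self.n_cells * self.replicates_per_cell

    def ppm_axis(self) -> np.ndarray:
        """Descending ppm axis (NMR display convention)."""
        lo, hi, step = self.ppm_grid
        n = int(round((hi - lo) / step)) + 1
        return np.linspace(hi, lo, n)

    def temperature_mean_sd(self) -> tuple[float, float]:
        """Mean and (population) SD of the design temperatures, used to
        standardize temperature in the quadratic phenotype models."""
        t = np.asarray(self.temperatures, dtype=float)
        return float(t.mean()), float(t.std())


def default_design() -> SimulationDesign:
    """The study's own design: 10 temperatures x 2 sexes x 5 replicate pools
    (100 spectra), 20 vials of 40 eggs per temperature, 20 flies per sex per
    temperature in each tolerance assay."""
    return SimulationDesign()
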