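"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study's measured data: 1D 1H-NMR spectra of
pooled-fly extracts across 10 developmental temperatures and both sexes,
and individual/vial-level functional phenotypes (CT_min, CT_max,
developmental time, egg-to-adult viability).  Each simulated metabolite is
planted with one of the reaction-norm shapes the analysis is built to
detect -- linear, inverted-U (lower at the extreme temperatures), sex
dimorphic, or null -- and the planted assignment is exported as a truth
table so recovery can be scored.

Peaks are Lorentzian singlets at the catalogued chemical shifts (multiplet
fine structure is not modelled; the analysis integrates ranges, not
coupling patterns).  Nuisance structure mirrors what the preprocessing has
to undo: a per-sample dilution factor (total-intensity normalization), a
global per-sample ppm jitter (referencing/alignment), and additive
baseline noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import SpectrumSet
from .design import EXTREME_TEMPERATURES, SimulationDesign, default_design
from .errors import ValidationError

__all__ = [
    "MetaboliteTruth",
    "SexEffect",
    "NuisanceModel",
    "BackgroundModel",
    "PhenotypeTruth",
    "default_design",
    "default_metabolite_truths",
    "simulate_spectra",
    "simulate_phenotypes",
    "truth_table",
    "expected_area",
]

NORM_CLASSES = ("linear_up", "linear_down", "ushape_up", "ushape_down",
                "sex_dimorphic", "null")

#: Area of the TSP reference peak (arbitrary units); TSP sits in the buffer
#: at fixed concentration, so its area is *not* subject to dilution.
TSP_AREA = 1.0
TSP_PPM = -0.017


@dataclass(frozen=True)
class SexEffect:
    """Multiplicative female/male offset for one metabolite.

    ``kind`` is ``"none"``, ``"constant"`` (temperature-independent), or
    ``"intermediate_peak"`` (offset largest at benign temperatures, the
    pattern the sex-difference analysis is designed to see).  The factor is
    applied to female areas; males stay at baseline.
    """

    kind: str = "none"
    magnitude: float = 0.0
    peak_temperature: float = 22.0
    width: float = 7.0

    def factor(self, temperature: float) -> float:
        if self.kind == "none":
            return 1.0
        if self.kind == "constant":
            return 1.0 + self.magnitude
        if self.kind == "intermediate_peak":
            g = math.exp(-(((temperature - self.peak_temperature) / self.width) ** 2))
            return 1.0 + self.magnitude * g
        raise ValidationError(f"unknown sex-effect kind {self.kind!r}")


@dataclass(frozen=True)
class MetaboliteTruth:
    """Planted ground truth for one simulated metabolite."""

    name: str
    shifts: tuple[float, ...]
    integration_range: tuple[float, float]  # (high ppm, low ppm)
    norm_class: str
    baseline: float = 1.0
    effect_size: float = 0.6
    sex_effect: SexEffect = field(default_factory=SexEffect)
    peak_width: float = 0.002  # FWHM, ppm

    def __post_init__(self) -> None:
        if self.norm_class not in NORM_CLASSES:
            raise ValidationError(f"unknown norm_class {self.norm_class!r}")
        if self.baseline <= 0:
            raise ValidationError("baseline must be positive")
        if not math.isfinite(self.effect_size):
            raise ValidationError("effect size must be finite")
        hi, lo = self.integration_range
        if hi <= lo:
            raise ValidationError(f"{self.name}: integration range high must exceed low")


def modifier(truth: MetaboliteTruth, temperature: float, sex: str,
             design: SimulationDesign) -> float:
    """Class-dependent multiplicative reaction-norm modifier of peak area.

    Linear classes scale as ``1 +/- e * (T - Tbar) / (Tmax - Tmin)`` so the
    fractional change over the whole range is the effect size.  U-shape
    classes are two-state: areas move by ``+/- e`` at the four extreme
    temperatures (12, 15.5, 31, 32 C) relative to the intermediate ones --
    the same two-state structure the U-shape prior encodes.
    """
    t = np.asarray(design.temperatures)
    e = truth.effect_size
    cls = truth.norm_class
    if cls == "linear_up" or cls == "linear_down":
        sgn = 1.0 if cls == "linear_up" else -1.0
        m = 1.0 + sgn * e * (temperature - t.mean()) / (t.max() - t.min())
    elif cls == "ushape_up" or cls == "ushape_down":
        sgn = 1.0 if cls == "ushape_up" else -1.0
        m = 1.0 + sgn * e * (temperature in EXTREME_TEMPERATURES)
    else:  # sex_dimorphic, null
        m = 1.0
    if sex == "female":
        m *= truth.sex_effect.factor(temperature)
    return max(m, 0.0)


def expected_area(truth: MetaboliteTruth, temperature: float, sex: str,
                  design: SimulationDesign) -> float:
    """Noiseless, undiluted total peak area of a metabolite in one cell."""
    return truth.baseline * modifier(truth, temperature, sex, design)


@dataclass(frozen=True)
class NuisanceModel:
    """Per-sample nuisance effects the preprocessing must undo.

    ``area_log_sd`` is replicate-level biological variability: each
    metabolite's area in each sample (catalogued or unassigned) is
    multiplied by an independent log-normal factor.  In pooled-fly NMR data
    this between-replicate variation, not detector noise, dominates the
    error of integrated intensities.
    """

    baseline_noise_sd: float = 0.3
    dilution_log_sd: float = 0.15
    jitter_ppm: float = 0.005
    area_log_sd: float = 0.10

    def __post_init__(self) -> None:
        if min(self.baseline_noise_sd, self.dilution_log_sd, self.jitter_ppm,
               self.area_log_sd) < 0:
            raise ValidationError("nuisance magnitudes must be non-negative")

    @classmethod
    def none(cls) -> "NuisanceModel":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class BackgroundModel:
    """Unassigned small-molecule signal underlying the catalogued peaks.

    A fly-extract CPMG spectrum contains far more resonances than the 30
    catalogued metabolites; the catalogue is a minority of the total
    intensity.  Modelled as many sharp singlets of null reaction norm at
    deterministic pseudo-random positions kept clear of the catalogue's
    integration ranges and characteristic shifts, each varying between
    replicates like any other metabolite.  (Broad macromolecule signal is
    not modelled: the CPMG filter attenuates it.)
    """

    n_peaks: int = 150
    total_area: float = 300.0
    fwhm: float = 0.002
    positions: tuple[float, ...] | None = None  # None: generated per catalogue

    def __post_init__(self) -> None:
        if self.total_area < 0 or self.fwhm <= 0 or self.n_peaks < 0:
            raise ValidationError("background area/peaks must be >= 0, fwhm > 0")

    @classmethod
    def none(cls) -> "BackgroundModel":
        return cls(n_peaks=0, total_area=0.0)

    def resolve_positions(self, exclude: list[tuple[float, float]],
                          low: float = 0.6, high: float = 9.4) -> tuple[float, ...]:
        """Deterministic unassigned-peak positions avoiding the exclusion
        windows (fixed internal seed: positions are part of the scenario,
        not of the noise)."""
        if self.positions is not None:
            return self.positions
        rng = np.random.default_rng(20161207)
        out: list[float] = []
        while len(out) < self.n_peaks:
            x = float(rng.uniform(low, high))
            if any(lo <= x <= hi for lo, hi in exclude):
                continue
            out.append(round(x, 4))
        return tuple(out)


def _exclusion_windows(truths: list["MetaboliteTruth"],
                       margin: float = 0.02) -> list[tuple[float, float]]:
    wins = [(4.67 - margin, 4.85 + margin)]  # residual water region
    for t in truths:
        hi, lo = t.integration_range
        wins.append((lo - margin, hi + margin))
        for s in t.shifts:
            wins.append((s - margin, s + margin))
    return wins


# ---------------------------------------------------------------------------
# default metabolite panel
# ---------------------------------------------------------------------------

# Reaction-norm classes for the default panel mirror the study system's
# published pattern: ten metabolites (mostly free amino acids) move linearly
# with developmental temperature, five energy carriers/sugars are depleted at
# both temperature extremes (inverted-U), five are sex dimorphic with the
# dimorphism peaking at benign temperatures, and ten are unresponsive.
# Classes respect the catalogue's signal overlaps: glutamate's integration
# window contains the methionine sulfoxide 2.32 ppm resonance, so the two
# must share a class for either window to be interpretable.
_DEFAULT_CLASSES: dict[str, str] = {
    "Arginine": "linear_down", "Glutamate": "linear_down",
    "Isoleucine": "linear_down", "Leucine": "linear_down",
    "Methionine sulfoxide": "linear_down", "Phenylalanine": "linear_down",
    "Proline": "linear_down", "Tryptophan": "linear_down",
    "Tyrosine": "linear_down", "Phosphocholine": "linear_up",
    "NAD+": "ushape_down", "NADP+": "ushape_down", "AMP": "ushape_down",
    "Mannose": "ushape_down", "beta-Alanine": "ushape_down",
    "Galactoside": "sex_dimorphic", "Glucose": "sex_dimorphic",
    "Maltose": "sex_dimorphic", "Acetate": "sex_dimorphic",
    "Lactate": "sex_dimorphic",
    "Nicotinamide ribotide": "null", "Fatty acid": "null",
    "3-Hydroxykynurenine": "null", "Alanine": "null", "Asparagine": "null",
    "Aspartate": "null", "Histidine": "null", "Glutamine": "null",
    "Hydroxyisovalerate": "null", "Valine": "null",
}

_BASELINE_CYCLE = (1.0, 1.4, 0.8, 1.8, 0.6, 1.2)


def default_metabolite_truths(effect_size: float = 0.6,
                              sex_magnitude: float = 0.5) -> list[MetaboliteTruth]:
    """The default 30-metabolite panel (10 linear, 5 inverted-U, 5 sex
    dimorphic, 10 null) built on the catalogued chemical shifts and
    integration ranges."""
    from .reaction_norms import load_metabolite_definitions

    defs = load_metabolite_definitions()
    truths = []
    for i, d in enumerate(defs):
        cls = _DEFAULT_CLASSES[d.name]
        sex = (SexEffect("intermediate_peak", sex_magnitude)
               if cls == "sex_dimorphic" else SexEffect())
        shifts = tuple(d.shifts)
        hi, lo = d.integration_range
        if not any(lo - 0.01 <= s <= hi + 0.01 for s in shifts):
            # the integration range is, by construction, centered on a real
            # resonance even when the catalogue's shift list omits it
            # (beta-alanine: CH2 near 2.55 ppm)
            shifts = shifts + (round((hi + lo) / 2.0, 3),)
        truths.append(MetaboliteTruth(
            name=d.name,
            shifts=shifts,
            integration_range=d.integration_range,
            norm_class=cls,
            baseline=_BASELINE_CYCLE[i % len(_BASELINE_CYCLE)],
            effect_size=effect_size,
            sex_effect=sex,
        ))
    return truths


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def _lorentzian(ppm: np.ndarray, center: float, area: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return area * (gamma / math.pi) / ((ppm - center) ** 2 + gamma ** 2)


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    # Documented sub-seed scheme: one stream per sample, keyed by the
    # dataset seed and the sample's position in the design enumeration.
    return np.random.default_rng([int(seed), int(index)])


def simulate_spectra(design: SimulationDesign,
                     truths: list[MetaboliteTruth],
                     nuisance: NuisanceModel | None = None,
                     seed: int = 0,
                     background: BackgroundModel | None = None) -> SpectrumSet:
    """Simulate one raw (unnormalized, unaligned) spectrum per design cell
    x replicate.

    Sample enumeration order is temperature-major, then sex, then replicate.
    Each metabolite contributes equal-area Lorentzian singlets at each of its
    characteristic shifts; the whole sample (except the TSP reference) is
    scaled by a log-normal dilution factor and shifted by a global ppm
    jitter, and Gaussian baseline noise is added and clipped at zero.
    """
    nuisance = nuisance or NuisanceModel()
    background = background if background is not None else BackgroundModel()
    names = [t.name for t in truths]
    if not names:
        raise ValidationError("truths must be non-empty")
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate metabolite definitions: {dupes}")
    ppm = design.ppm_axis()
    lo, hi, _ = design.ppm_grid
    if nuisance.jitter_ppm > min(TSP_PPM - lo, 0.05):
        raise ValidationError("jitter exceeds the grid margin around the TSP peak")

    bg_positions = (background.resolve_positions(_exclusion_windows(truths))
                    if background.total_area > 0 and background.n_peaks > 0
                    else ())
    bg_area_each = (background.total_area / len(bg_positions)
                    if bg_positions else 0.0)
    rows, meta_rows = [], []
    index = 0
    for temperature in design.temperatures:
        for sex in design.sexes:
            for rep in range(design.replicates_per_cell):
                rng = _sample_rng(seed, index)
                dilution = (math.exp(rng.normal(0.0, nuisance.dilution_log_sd))
                            if nuisance.dilution_log_sd > 0 else 1.0)
                # jitter is quantized to the grid: it models the referencing
                # offset the (integer-bin) preprocessing must undo, not
                # sub-bin lineshape effects
                step = design.ppm_grid[2]
                jitter = (round(rng.uniform(-nuisance.jitter_ppm,
                                            nuisance.jitter_ppm) / step) * step
                          if nuisance.jitter_ppm > 0 else 0.0)
                y = np.zeros_like(ppm)
                for truth in truths:
                    area = expected_area(truth, temperature, sex, design) * dilution
                    if nuisance.area_log_sd > 0:
                        area *= math.exp(rng.normal(0.0, nuisance.area_log_sd))
                    per_peak = area / len(truth.shifts)
                    for shift in truth.shifts:
                        y += _lorentzian(ppm, shift + jitter, per_peak, truth.peak_width)
                for pos in bg_positions:
                    a = bg_area_each * dilution
                    if nuisance.area_log_sd > 0:
                        a *= math.exp(rng.normal(0.0, nuisance.area_log_sd))
                    y += _lorentzian(ppm, pos + jitter, a, background.fwhm)
                y += _lorentzian(ppm, TSP_PPM + jitter, TSP_AREA, 0.002)
                if nuisance.baseline_noise_sd > 0:
                    y += rng.normal(0.0, nuisance.baseline_noise_sd, size=y.size)
                    np.clip(y, 0.0, None, out=y)
                rows.append(y)
                meta_rows.append({
                    "sample_id": f"{sex[0].upper()}{temperature:g}_r{rep + 1}",
                    "sex": sex,
                    "temperature_C": temperature,
                    "replicate": rep + 1,
                })
                index += 1
    sset = SpectrumSet(ppm, np.vstack(rows), pd.DataFrame(meta_rows))
    sset.log_step("simulate", seed=int(seed),
                  baseline_noise_sd=nuisance.baseline_noise_sd,
                  dilution_log_sd=nuisance.dilution_log_sd,
                  jitter_ppm=nuisance.jitter_ppm)
    return sset


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeTruth:
    """Generating parameters of the four functional-phenotype models.

    CT_min/CT_max are linear in raw temperature (C); male coefficients are
    deviations from females.  Viability is logit-quadratic and developmental
    time log-quadratic in standardized temperature, with a vial random
    intercept for developmental time.
    """

    # viability/devtime quadratics anchor the study's printed curve shape:
    # viability ~43%/75%/45% at 12/22/32 C; devtime ~49 d at 12 C falling to
    # ~7.5 d at 29.5 C with a slight rise toward 32 C
    ctmin: tuple[float, float, float] = (-4.578, 0.412, 0.55)
    ctmax: tuple[float, float, float, float, float] = (37.601, 0.123, -0.692, 0.019, 0.5)
    viability: tuple[float, float, float, float] = (1.1, -0.18, -0.57, 2.0)
    devtime: tuple[float, float, float, float, float] = (2.322, -0.530, 0.221, 0.03, 0.05)

    def __post_init__(self) -> None:
        if self.ctmin[2] < 0 or self.ctmax[4] < 0 or self.devtime[4] < 0:
            raise ValidationError("residual/random-effect SDs must be non-negative")
        if self.viability[3] < 1:
            raise ValidationError("overdispersion factor must be >= 1")
        if self.viability[2] >= 0:
            raise ValidationError("viability quadratic coefficient must be negative")


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_phenotypes(design: SimulationDesign,
                        truth: PhenotypeTruth | None = None,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate fly-level trait records and vial-level emergence counts.

    Returns
    -------
    flies : DataFrame
        Columns ``sex, temperature_C, trait, value, vial_id`` with trait in
        {"ctmin", "ctmax", "devtime"}; vial_id is set for devtime only.
    vials : DataFrame
        Columns ``temperature_C, vial_id, eggs, adults``.
    """
    truth = truth or PhenotypeTruth()
    if len(design.temperatures) < 2:
        raise ValidationError("need >= 2 temperatures (quadratic unidentifiable)")
    rng = np.random.default_rng([int(seed), 7_777_777])
    t_mean, t_sd = design.temperature_mean_sd()
    is_male = {s: float(s == "male") for s in design.sexes}

    fly_rows: list[dict] = []
    vial_rows: list[dict] = []

    a0, a1, a_sd = truth.ctmin
    b0, b1, b_sex, b_int, b_sd = truth.ctmax
    for temperature in design.temperatures:
        for sex in design.sexes:
            m = is_male[sex]
            mu_min = a0 + a1 * temperature
            mu_max = b0 + b1 * temperature + m * (b_sex + b_int * temperature)
            for trait, mu, sd in (("ctmin", mu_min, a_sd), ("ctmax", mu_max, b_sd)):
                vals = mu + (rng.normal(0.0, sd, design.flies_assayed_per_cell)
                             if sd > 0 else np.zeros(design.flies_assayed_per_cell))
                fly_rows += [{"sex": sex, "temperature_C": temperature,
                              "trait": trait, "value": float(v), "vial_id": None}
                             for v in vals]

    v0, v1, v2, phi = truth.viability
    d0, d1, d2, d_sex, d_vsd = truth.devtime
    n_eggs = design.eggs_per_vial
    for temperature in design.temperatures:
        z = (temperature - t_mean) / t_sd
        p = _invlogit(v0 + v1 * z + v2 * z * z)
        log_mu = d0 + d1 * z + d2 * z * z
        for v in range(design.vials_per_temperature):
            vial_id = f"T{temperature:g}_v{v + 1}"
            if phi > 1 and n_eggs > 1:
                rho = (phi - 1.0) / (n_eggs - 1.0)
                s = (1.0 - rho) / rho
                p_vial = rng.beta(max(p * s, 1e-9), max((1.0 - p) * s, 1e-9))
            else:
                p_vial = p
            adults = int(rng.binomial(n_eggs, p_vial))
            vial_rows.append({"temperature_C": temperature, "vial_id": vial_id,
                              "eggs": n_eggs, "adults": adults})
            u = rng.normal(0.0, d_vsd) if d_vsd > 0 else 0.0
            for egg in range(n_eggs):
                sex = design.sexes[egg % len(design.sexes)]
                mu = math.exp(log_mu + d_sex * is_male[sex] + u)
                value = max(1, int(rng.poisson(mu)))
                fly_rows.append({"sex": sex, "temperature_C": temperature,
                                 "trait": "devtime", "value": value,
                                 "vial_id": vial_id})

    flies = pd.DataFrame(fly_rows)
    flies["value"] = flies["value"].astype(float)  # devtime stays integer-valued
    return flies, pd.DataFrame(vial_rows)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

_SIGNS = {
    "linear_up": ("+", "0"), "linear_down": ("-", "0"),
    "ushape_up": ("0", "+"), "ushape_down": ("0", "-"),
    "sex_dimorphic": ("0", "0"), "null": ("0", "0"),
}


def truth_table(truths: list[MetaboliteTruth]) -> pd.DataFrame:
    """Expected correlation signs per metabolite against the linear and
    U-shape temperature targets -- the oracle for recovery testing."""
    rows = []
    for t in truths:
        if t.norm_class not in _SIGNS:
            raise ValidationError(f"unknown norm_class {t.norm_class!r}")
        lin, ush = _SIGNS[t.norm_class]
        rows.append({"name": t.name, "norm_class": t.norm_class,
                     "linear_sign": lin, "ushape_sign": ush})
    return pd.DataFrame(rows)
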