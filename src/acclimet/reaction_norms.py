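"""Metabolite-level reaction norms.

Integrates catalogued chemical-shift ranges into per-sample metabolite
intensities, correlates them with temperature-derived component scores and
phenotype-prediction scores, screens the correlations with a sequential
Bonferroni (Holm) correction run against an assumed family of 100
metabolites, classifies each metabolite's reaction norm (linear vs
inverted-U, by sex), and quantifies metabolome sex differences with an
uncentered difference-matrix PCA.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import FeatureMatrix, SpectrumSet
from .design import EXTREME_TEMPERATURES
from .errors import ValidationError
from .spectra_prep import pareto_scale

__all__ = [
    "MetaboliteDefinition", "load_metabolite_definitions",
    "MetaboliteIntensityTable", "integrate_metabolites",
    "CorrelationResult", "correlate_with_target", "holm_significance",
    "classify_reaction_norms", "ushape_prior_encoding",
    "sex_difference_matrix", "SexDifferenceResult", "sex_difference_analysis",
    "TARGETS",
]

#: Correlation targets recognized by the screening step.
TARGETS = ("linear_component", "ushape_component", "linear_prior",
           "ushape_prior", "devtime", "viability", "sexdiff")

_EPS = 1e-9
#: Half-width (ppm) of the verification window around each characteristic shift.
VERIFY_HALF_WINDOW = 0.005


@dataclass(frozen=True)
class MetaboliteDefinition:
    """Catalogue entry: name, characteristic shifts, integration range."""

    name: str
    shifts: tuple[float, ...]
    integration_range: tuple[float, float]  # (high, low), ppm

    def __post_init__(self) -> None:
        hi, lo = self.integration_range
        if hi <= lo:
            raise ValidationError(
                f"{self.name}: integration range high ({hi}) must exceed low ({lo})")
        near = any(lo - 0.05 <= s <= hi + 0.05 for s in self.shifts)
        if not near:
            # Catalogue quirk: a range can sit on a resonance that is not in
            # the (possibly incomplete) shift list; flag, don't fail.
            warnings.warn(
                f"{self.name}: integration range does not overlap any listed "
                "characteristic shift", stacklevel=2)


def load_metabolite_definitions(source=None) -> list[MetaboliteDefinition]:
    """Load metabolite definitions from a CSV (columns ``name``, ``shifts``
    semicolon-separated, ``range_high``, ``range_low``).  With no source the
    bundled 30-metabolite catalogue is returned."""
    if source is None:
        source = resources.files("acclimet") / "data" / "metabolite_definitions.csv"
        with resources.as_file(source) as path:
            df = pd.read_csv(path)
    else:
        df = pd.read_csv(source)
    if df["name"].duplicated().any():
        dupes = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValidationError(f"duplicate metabolite names: {dupes}")
    defs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # known catalogue quirk (beta-alanine)
        for row in df.itertuples(index=False):
            shifts = tuple(float(s) for s in str(row.shifts).split(";"))
            defs.append(MetaboliteDefinition(
                name=row.name, shifts=shifts,
                integration_range=(float(row.range_high), float(row.range_low))))
    return defs


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

@dataclass
class MetaboliteIntensityTable:
    """Integrated intensities: samples x metabolites, with sample metadata."""

    values: pd.DataFrame
    meta: pd.DataFrame


def _window_sum(sset: SpectrumSet, lo: float, hi: float) -> np.ndarray | None:
    mask = (sset.ppm >= lo - _EPS) & (sset.ppm <= hi + _EPS)
    if not mask.any():
        return None
    return sset.intensities[:, mask].sum(axis=1)


def filter_integrable(sset: SpectrumSet, defs: list[MetaboliteDefinition]
                      ) -> tuple[list[MetaboliteDefinition], list[str]]:
    """Split definitions into those whose integration range overlaps the
    retained ppm axis and those falling entirely in trimmed regions (the
    catalogue's nicotinamide ribotide range sits above the 9.5 ppm edge)."""
    kept, dropped = [], []
    for d in defs:
        hi, lo = d.integration_range
        (kept if _window_sum(sset, lo, hi) is not None else dropped).append(d)
    if dropped:
        dropped = [d.name for d in dropped]
        warnings.warn(f"integration ranges outside the retained window, "
                      f"skipped: {dropped}", stacklevel=2)
        return kept, dropped
    return kept, []


def integrate_metabolites(sset: SpectrumSet,
                          defs: list[MetaboliteDefinition]) -> MetaboliteIntensityTable:
    """Total intensity within each metabolite's integration range (closed
    interval on ppm values)."""
    cols = {}
    for d in defs:
        hi, lo = d.integration_range
        s = _window_sum(sset, lo, hi)
        if s is None:
            raise ValidationError(
                f"integration range of {d.name!r} lies outside the retained "
                "ppm window")
        cols[d.name] = s
    meta = sset.meta.set_index("sample_id")
    values = pd.DataFrame(cols, index=meta.index)
    meta = meta.reset_index()
    return MetaboliteIntensityTable(values=values, meta=meta)


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    """Correlation of one metabolite with one target in one sex context."""

    metabolite: str
    target: str
    sex_context: str  # "female" | "male" | "both"
    r: float
    p: float
    significant: bool = False
    verified: bool | None = None
    excluded: bool = False
    shift_correlations: dict[float, float] = field(default_factory=dict)


def correlate_with_target(table: MetaboliteIntensityTable,
                          target_scores,
                          defs: list[MetaboliteDefinition],
                          sset: SpectrumSet | None = None,
                          target: str = "linear_component",
                          sex_context: str = "both",
                          verify_alpha: float = 0.05) -> list[CorrelationResult]:
    """Pearson correlation of integrated intensities with target scores.

    When a spectrum set is supplied, each metabolite's other characteristic
    shifts are checked in +/-0.005 ppm windows: ``verified`` is True when
    every shift window whose own correlation is individually significant
    (p < ``verify_alpha``) agrees in sign with the integration-range
    correlation.  Constant intensity columns are flagged ``excluded`` and
    get no p-value.
    """
    t = np.asarray(target_scores, dtype=float)
    if len(table.values) != t.size:
        raise ValidationError("table rows must match target scores")
    results = []
    for d in defs:
        x = table.values[d.name].to_numpy(dtype=float)
        if np.std(x) == 0:
            warnings.warn(f"{d.name}: constant intensity column excluded",
                          stacklevel=2)
            results.append(CorrelationResult(d.name, target, sex_context,
                                             float("nan"), float("nan"),
                                             excluded=True))
            continue
        r, p = stats.pearsonr(x, t)
        shift_rs: dict[float, float] = {}
        verified: bool | None = None
        if sset is not None:
            agree = True
            for shift in d.shifts:
                s = _window_sum(sset, shift - VERIFY_HALF_WINDOW,
                                shift + VERIFY_HALF_WINDOW)
                if s is None or np.std(s) == 0:
                    continue
                r_s, p_s = stats.pearsonr(s, t)
                shift_rs[shift] = float(r_s)
                if p_s < verify_alpha and np.sign(r_s) != np.sign(r):
                    agree = False
            verified = agree
        results.append(CorrelationResult(d.name, target, sex_context,
                                         float(r), float(p), verified=verified,
                                         shift_correlations=shift_rs))
    return results


def holm_significance(results: list[CorrelationResult],
                      assumed_m: int = 100,
                      alpha: float = 0.05) -> list[CorrelationResult]:
    """Step-down sequential Bonferroni over an assumed family of
    ``assumed_m`` metabolites, applied per (target, sex_context) family.

    P-values are sorted ascending; the i-th (1-based) is significant iff
    every p_(j<=i) <= alpha / (assumed_m - j + 1) -- the denominators start
    at the assumed total, not at the number actually tested, so untested
    metabolites still count against the family-wise error budget.
    """
    out = [replace(r) for r in results]
    families: dict[tuple[str, str], list[int]] = {}
    for i, r in enumerate(out):
        r.significant = False
        if not r.excluded:
            families.setdefault((r.target, r.sex_context), []).append(i)
    for fam in families.values():
        k = len(fam)
        if assumed_m < k:
            raise ValidationError(
                f"assumed_m={assumed_m} smaller than {k} tested metabolites")
        order = sorted(fam, key=lambda i: out[i].p)
        for rank, i in enumerate(order, start=1):
            if out[i].p <= alpha / (assumed_m - rank + 1):
                out[i].significant = True
            else:
                break  # step-down halts at the first failure
    return out


def ushape_prior_encoding(temperatures) -> np.ndarray:
    """Two-state encoding of the U-shape prior: extreme temperatures
    (12, 15.5, 31, 32 C) -> 1, intermediate (18-29.5 C) -> 0."""
    temps = np.asarray(temperatures, dtype=float)
    out = np.empty(temps.size, dtype=float)
    for i, t in enumerate(temps):
        if t in EXTREME_TEMPERATURES:
            out[i] = 1.0
        elif 18.0 <= t <= 29.5:
            out[i] = 0.0
        else:
            raise ValidationError(f"temperature {t} is not a design temperature")
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _sign(r: float) -> str:
    return "+" if r > 0 else "-"

_SHAPE_TARGETS = {"linear": ("linear_component", "linear_prior"),
                  "ushape": ("ushape_component", "ushape_prior")}


def classify_reaction_norms(results: list[CorrelationResult]) -> pd.DataFrame:
    """Per-metabolite, per-sex reaction-norm labels.

    A metabolite gets a linear (or U-shape) label in a sex when it is
    significant on the corresponding rotated-component target OR the prior
    target; the sign is taken from the significant correlation (component
    preferred on conflict).  Both shapes may co-occur.  Returns a DataFrame
    with columns metabolite, sex, linear_sign, ushape_sign, label --
    signs in {"+", "-", "0"}; label e.g. "linear-", "linear-/ushape+",
    "none".
    """
    by_key: dict[tuple[str, str, str], CorrelationResult] = {}
    sexes = set()
    mets: list[str] = []
    for r in results:
        by_key[(r.metabolite, r.target, r.sex_context)] = r
        if r.sex_context in ("female", "male"):
            sexes.add(r.sex_context)
        if r.metabolite not in mets:
            mets.append(r.metabolite)
    rows = []
    for met in mets:
        for sex in sorted(sexes):
            signs = {}
            for shape, targets in _SHAPE_TARGETS.items():
                sig = [by_key[(met, tg, sex)]
                       for tg in targets
                       if (met, tg, sex) in by_key
                       and by_key[(met, tg, sex)].significant]
                signs[shape] = _sign(sig[0].r) if sig else "0"
            parts = [f"{shape}{signs[shape]}" for shape in ("linear", "ushape")
                     if signs[shape] != "0"]
            rows.append({"metabolite": met, "sex": sex,
                         "linear_sign": signs["linear"],
                         "ushape_sign": signs["ushape"],
                         "label": "/".join(parts) if parts else "none"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sex-difference analysis
# ---------------------------------------------------------------------------

def sex_difference_matrix(sset: SpectrumSet) -> FeatureMatrix:
    """Spectral sex-difference matrix.

    Per temperature: each female spectrum minus the pointwise median male
    spectrum (rows tagged ``F-medM``) and the pointwise median female
    spectrum minus each male spectrum (rows tagged ``medF-M``).  Left
    uncentered downstream so score deviations from zero measure the sex
    difference itself.
    """
    meta = sset.meta
    rows, row_meta = [], []
    for temperature in sorted(meta["temperature_C"].unique()):
        at_t = meta["temperature_C"] == temperature
        f_idx = np.flatnonzero(at_t & (meta["sex"] == "female"))
        m_idx = np.flatnonzero(at_t & (meta["sex"] == "male"))
        if f_idx.size == 0 or m_idx.size == 0:
            raise ValidationError(
                f"temperature {temperature:g} is missing one sex")
        med_m = np.median(sset.intensities[m_idx], axis=0)
        med_f = np.median(sset.intensities[f_idx], axis=0)
        for i in f_idx:
            rows.append(sset.intensities[i] - med_m)
            row_meta.append({"row_id": f"{meta['sample_id'].iat[i]}|F-medM",
                             "contrast": "F-medM",
                             "temperature_C": temperature,
                             "source_sample": meta["sample_id"].iat[i]})
        for i in m_idx:
            rows.append(med_f - sset.intensities[i])
            row_meta.append({"row_id": f"{meta['sample_id'].iat[i]}|medF-M",
                             "contrast": "medF-M",
                             "temperature_C": temperature,
                             "source_sample": meta["sample_id"].iat[i]})
    rm = pd.DataFrame(row_meta).set_index("row_id")
    values = pd.DataFrame(np.vstack(rows), index=rm.index,
                          columns=np.round(sset.ppm, 6))
    return FeatureMatrix(values, rm, normalized=False, scaling="none")


@dataclass
class SexDifferenceResult:
    """Uncentered PCA of the sex-difference matrix and its temperature fits."""

    pc1_scores: pd.Series
    cubic_fits: dict[str, dict]
    score_length: pd.Series  # per temperature: sqrt(sum_k mean-score_k^2)
    explained_variance_ratio: np.ndarray
    degenerate: bool = False


def sex_difference_analysis(diff: FeatureMatrix,
                            n_components: int = 5) -> SexDifferenceResult:
    """Uncentered PCA of the (Pareto-scaled, uncentered) difference matrix,
    a cubic temperature model of PC1 per row tagging, and the total score
    length per temperature."""
    from .chemometrics import PCAModel

    temps = diff.meta["temperature_C"].to_numpy(dtype=float)
    if np.allclose(diff.X, 0.0):
        warnings.warn("all-zero difference matrix; returning zero scores",
                      stacklevel=2)
        zeros = pd.Series(np.zeros(len(diff.values)), index=diff.values.index)
        lengths = pd.Series(0.0, index=sorted(set(temps)))
        return SexDifferenceResult(zeros, {}, lengths,
                                   np.zeros(n_components), degenerate=True)
    scaled = pareto_scale(diff, centered=False) if diff.scaling == "none" else diff
    k = min(n_components, scaled.X.shape[0], scaled.X.shape[1])
    pca = PCAModel(n_components=k, center=False).fit(scaled.X)
    scores = pca.scores_
    # orient PC1 so larger scores mean larger sex difference
    if np.mean(scores[:, 0]) < 0:
        scores = scores.copy()
        scores[:, 0] *= -1.0
    pc1 = pd.Series(scores[:, 0], index=diff.values.index, name="PC1")
    fits: dict[str, dict] = {}
    for contrast in ("F-medM", "medF-M"):
        mask = (diff.meta["contrast"] == contrast).to_numpy()
        if not mask.any():
            continue
        t = temps[mask]
        X = sm.add_constant(np.column_stack([t, t ** 2, t ** 3]))
        fit = sm.OLS(pc1.to_numpy()[mask], X).fit()
        fits[contrast] = {
            "coef": fit.params.tolist(),
            "F": float(fit.fvalue),
            "df": (int(fit.df_model), int(fit.df_resid)),
            "p": float(fit.f_pvalue),
        }
    uniq_t = sorted(set(temps))
    lengths = {}
    for temperature in uniq_t:
        m = scores[temps == temperature].mean(axis=0)
        lengths[temperature] = float(np.sqrt(np.sum(m ** 2)))
    return SexDifferenceResult(pc1, fits, pd.Series(lengths),
                               pca.explained_variance_ratio_)
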