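"""Functional-phenotype models.

Four models of how development temperature shapes fly phenotypes:

* CT_min, CT_max: ordinary least squares on sex, temperature and their
  interaction, reduced by sequential F-tests (a main effect is never
  dropped while part of a retained interaction).
* Egg-to-adult viability: binomial-logit regression on standardized
  temperature and its square, with quasi-likelihood (Pearson chi2/df)
  correction of the standard errors for overdispersion.
* Developmental time: Poisson generalized linear mixed model with a vial
  random intercept, fitted by Laplace-approximated maximum likelihood
  (random intercepts are independent across vials, so the marginal
  likelihood factorizes into one-dimensional integrals), fixed effects
  tested by likelihood-ratio tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import ValidationError

__all__ = [
    "FittedModel", "fit_thermal_limit", "fit_viability", "fit_devtime",
    "PoissonRandomIntercept", "phenotype_targets",
]

ALPHA_DEFAULT = 0.05
_ZERO_RSS = 1e-10


@dataclass
class FittedModel:
    """A reduced model with its term-by-term reduction table."""

    formula: str
    family: str  # "gaussian" | "quasibinomial" | "poisson-mixed"
    coefficients: dict[str, dict]  # name -> {"estimate", "se"}
    reduction_table: list[dict]    # term, statistic, value, df, p, kept
    dispersion: float | None = None
    random_effect_sd: float | None = None
    loglik: float | None = None
    extras: dict = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        """Rows for a text rendering: term, estimate, SE, statistic(df), p."""
        tests = {t["term"]: t for t in self.reduction_table}
        rows = []
        for name, c in self.coefficients.items():
            t = tests.get(name)
            rows.append({
                "term": name,
                "estimate": c["estimate"],
                "se": c["se"],
                "statistic": None if t is None else t["value"],
                "df": None if t is None else t["df"],
                "p": None if t is None else t["p"],
            })
        for name, t in tests.items():
            if not t["kept"]:
                rows.append({"term": name, "estimate": None, "se": None,
                             "statistic": t["value"], "df": t["df"], "p": t["p"]})
        return rows


def _f_test(rss_full: float, df_full: int, rss_red: float, n_drop: int
            ) -> tuple[float, float]:
    """Model-comparison F-test robust to a saturated (zero-residual) fit."""
    delta = max(rss_red - rss_full, 0.0)
    if rss_full < _ZERO_RSS:
        return (0.0, 1.0) if delta < _ZERO_RSS else (math.inf, 0.0)
    f = (delta / n_drop) / (rss_full / df_full)
    return f, float(stats.f.sf(f, n_drop, df_full))


# ---------------------------------------------------------------------------
# thermal limits (OLS)
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, cols: dict[str, np.ndarray]):
    X = sm.add_constant(pd.DataFrame(cols)) if cols else \
        pd.DataFrame({"const": np.ones(y.size)})
    return sm.OLS(y, X).fit()


def fit_thermal_limit(records: pd.DataFrame, trait: str,
                      alpha: float = ALPHA_DEFAULT,
                      keep_full: bool = False) -> FittedModel:
    """Sequentially reduced linear model of CT_min or CT_max.

    ``records`` needs columns sex, temperature_C, trait, value.  Starts from
    ``value ~ sex + temperature + sex:temperature``; the interaction is
    dropped when its F-test p >= alpha, after which each main effect is
    tested against the additive model.  Main effects inside a retained
    interaction are kept unconditionally.

    With ``keep_full`` no term is dropped and the returned coefficients are
    the full-model (unconditional) estimates a simulation study compares
    against the generating values; the interaction test is still reported.
    """
    if trait not in ("ctmin", "ctmax"):
        raise ValidationError(f"unknown thermal-limit trait {trait!r}")
    df = records[records["trait"] == trait]
    sexes = sorted(df["sex"].unique())
    temps = df["temperature_C"].unique()
    if len(sexes) != 2 or temps.size < 3:
        raise ValidationError("need both sexes and >= 3 temperatures")
    counts = df.groupby(["sex", "temperature_C"]).size()
    if counts.min() < 2 or len(counts) < len(sexes) * temps.size:
        raise ValidationError("need >= 2 observations per sex x temperature cell")
    y = df["value"].to_numpy(dtype=float)
    male = (df["sex"] == sexes[1]).to_numpy(dtype=float)  # deviation coding
    t = df["temperature_C"].to_numpy(dtype=float)
    terms = {"sex": male, "temperature": t, "sex:temperature": male * t}

    full = _ols(y, terms)
    additive = _ols(y, {k: terms[k] for k in ("sex", "temperature")})
    f_int, p_int = _f_test(full.ssr, int(full.df_resid), additive.ssr, 1)
    table = [{"term": "sex:temperature", "statistic": "F", "value": f_int,
              "df": (1, int(full.df_resid)), "p": p_int, "kept": p_int < alpha}]
    if keep_full:
        kept = list(terms)
        final = full
    elif p_int < alpha:
        kept = list(terms)
        # halt rule: mains inside the significant interaction stay untested
        final = full
    else:
        kept = []
        for term in ("sex", "temperature"):
            other = [k for k in ("sex", "temperature") if k != term]
            reduced = _ols(y, {k: terms[k] for k in other})
            f, p = _f_test(additive.ssr, int(additive.df_resid), reduced.ssr, 1)
            table.append({"term": term, "statistic": "F", "value": f,
                          "df": (1, int(additive.df_resid)), "p": p,
                          "kept": p < alpha})
            if p < alpha:
                kept.append(term)
        final = _ols(y, {k: terms[k] for k in kept})
    coefs = {name: {"estimate": float(est), "se": float(se)}
             for name, est, se in zip(final.params.index, final.params,
                                      final.bse)}
    formula = f"{trait} ~ " + (" + ".join(kept) if kept else "1")
    return FittedModel(formula=formula, family="gaussian", coefficients=coefs,
                       reduction_table=table,
                       extras={"sex_reference": sexes[0], "n": int(y.size)})


# ---------------------------------------------------------------------------
# viability (quasi-binomial)
# ---------------------------------------------------------------------------

def fit_viability(vials: pd.DataFrame) -> FittedModel:
    """Quadratic logistic regression of egg-to-adult viability on
    standardized temperature, with quasi-binomial SE correction.

    ``vials`` needs columns temperature_C, eggs, adults.  Influential points
    are retained; the temperature effect is tested by a dispersion-scaled
    likelihood-ratio (deviance) test with 2 df.
    """
    t = vials["temperature_C"].to_numpy(dtype=float)
    if np.unique(t).size < 3:
        raise ValidationError("need >= 3 temperatures")
    adults = vials["adults"].to_numpy(dtype=float)
    eggs = vials["eggs"].to_numpy(dtype=float)
    if np.any(adults < 0) or np.any(adults > eggs):
        raise ValidationError("adults must lie in [0, eggs]")
    if np.all(adults == 0) or np.all(adults == eggs):
        raise ValidationError("complete separation: all vials empty or full")
    z = (t - t.mean()) / t.std()
    endog = np.column_stack([adults, eggs - adults])
    X = sm.add_constant(pd.DataFrame({"temperature_z": z,
                                      "temperature_z2": z ** 2}))
    fit = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    dispersion = float(fit.pearson_chi2 / fit.df_resid)
    null = sm.GLM(endog, np.ones((len(vials), 1)),
                  family=sm.families.Binomial()).fit()
    chi2 = float((null.deviance - fit.deviance) / dispersion)
    p = float(stats.chi2.sf(chi2, 2))
    coefs = {name: {"estimate": float(est),
                    "se": float(se) * math.sqrt(dispersion)}
             for name, est, se in zip(fit.params.index, fit.params, fit.bse)}
    b1, b2 = fit.params["temperature_z"], fit.params["temperature_z2"]
    extras = {"n_vials": int(len(vials)), "binomial_se_scale": math.sqrt(dispersion)}
    if b2 < 0:
        extras["vertex_temperature"] = float(t.mean() - t.std() * b1 / (2 * b2))
    table = [{"term": "temperature (linear+quadratic)", "statistic": "chi2",
              "value": chi2, "df": 2, "p": p, "kept": True}]
    return FittedModel(formula="adults/eggs ~ temperature_z + temperature_z2",
                       family="quasibinomial", coefficients=coefs,
                       reduction_table=table, dispersion=dispersion,
                       extras=extras)


# ---------------------------------------------------------------------------
# developmental time (Poisson GLMM, Laplace)
# ---------------------------------------------------------------------------

class PoissonRandomIntercept:
    """Poisson log-link regression with an independent Gaussian random
    intercept per group, fitted by Laplace-approximated maximum likelihood.

    With independent intercepts the marginal likelihood factorizes over
    groups; each group's one-dimensional integral is approximated by
    Laplace's method around the conditional mode (found by a vectorized
    Newton iteration).  ``sigma`` is bounded below by a small positive value
    so the sigma -> 0 limit recovers the plain Poisson GLM.
    """

    def __init__(self, min_sigma: float = 1e-6):
        self.min_sigma = min_sigma

    # -- likelihood -----------------------------------------------------
    def _prepare(self, X, y, groups):
        order = np.argsort(groups, kind="stable")
        self._X = np.asarray(X, dtype=float)[order]
        self._y = np.asarray(y, dtype=float)[order]
        g = np.asarray(groups)[order]
        _, starts = np.unique(g, return_index=True)
        self._starts = starts
        self._sy = np.add.reduceat(self._y, starts)
        self._logfact = float(np.sum([math.lgamma(v + 1) for v in self._y]))

    def _loglik(self, params: np.ndarray) -> float:
        beta, sigma = params[:-1], max(params[-1], self.min_sigma)
        eta = self._X @ beta
        mu = np.exp(eta)
        A = np.add.reduceat(mu, self._starts)
        yeta = np.add.reduceat(self._y * eta, self._starts)
        s2 = sigma * sigma
        u = np.zeros_like(A)
        for _ in range(50):
            eu = np.exp(u)
            grad = self._sy - eu * A - u / s2
            hess = -eu * A - 1.0 / s2
            step = grad / hess
            u -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        eu = np.exp(u)
        ll = float(np.sum(yeta + self._sy * u - eu * A
                          - u * u / (2.0 * s2)
                          - 0.5 * np.log(s2 * eu * A + 1.0))) - self._logfact
        return ll

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(y < 1) or np.any(y != np.round(y)):
            raise ValidationError("counts must be integers >= 1")
        self._prepare(X, y, groups)
        start = sm.GLM(self._y, self._X, family=sm.families.Poisson()).fit()
        x0 = np.append(start.params, 0.05)
        bounds = [(None, None)] * X.shape[1] + [(0.0, None)]
        res = optimize.minimize(lambda p: -self._loglik(p), x0,
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12})
        self.params_ = res.x[:-1]
        self.sigma_ = float(max(res.x[-1], 0.0))
        self.loglik_ = float(-res.fun)
        # observed-information SEs for the fixed effects (numeric Hessian)
        try:
            h = _numeric_hessian(self._loglik, res.x)
            cov = np.linalg.inv(-h)
            self.bse_ = np.sqrt(np.clip(np.diag(cov)[:-1], 0.0, None))
        except np.linalg.LinAlgError:
            self.bse_ = np.full(X.shape[1], np.nan)
        return self


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    h = np.empty((n, n))
    f0 = f(x)
    steps = eps * np.maximum(np.abs(x), 1.0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fij = f(x + ei + ej)
            fi = f(x + ei)
            fj = f(x + ej)
            h[i, j] = h[j, i] = (fij - fi - fj + f0) / (steps[i] * steps[j])
    return h


def _devtime_design(df: pd.DataFrame, terms: list[str]) -> np.ndarray:
    t = df["temperature_C"].to_numpy(dtype=float)
    z = (t - t.mean()) / t.std()
    male = (df["sex"] == sorted(df["sex"].unique())[1]).to_numpy(dtype=float)
    cols = {"const": np.ones(len(df)), "temperature_z": z,
            "temperature_z2": z ** 2, "sex": male,
            "sex:temperature_z": male * z, "sex:temperature_z2": male * z ** 2}
    return np.column_stack([cols[k] for k in ["const"] + terms]), \
        ["const"] + terms


def fit_devtime(records: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> FittedModel:
    """Poisson GLMM of developmental time (days) with a vial random
    intercept and quadratic standardized temperature plus sex fixed effects.

    The sex x temperature interaction (both product terms, 2 df) is tested
    first by likelihood-ratio test and dropped when non-significant; sex and
    the temperature pair are then tested the same way, halting on a
    retained interaction.
    """
    df = records[records["trait"] == "devtime"]
    if df.empty or df["vial_id"].isna().any():
        raise ValidationError("devtime records must carry vial_id")
    y = df["value"].to_numpy(dtype=float)
    if np.any(y != np.round(y)) or np.any(y < 1):
        raise ValidationError("devtime must be integer days >= 1")
    vials_per_t = df.groupby("temperature_C")["vial_id"].nunique()
    if vials_per_t.min() < 2:
        raise ValidationError("need >= 2 vials per temperature")
    groups = df["vial_id"].to_numpy()

    def fit_terms(terms):
        X, names = _devtime_design(df, terms)
        model = PoissonRandomIntercept().fit(X, y, groups)
        return model, names

    full_terms = ["temperature_z", "temperature_z2", "sex",
                  "sex:temperature_z", "sex:temperature_z2"]
    full, _ = fit_terms(full_terms)
    no_int, _ = fit_terms(full_terms[:3])
    chi2_int = 2.0 * (full.loglik_ - no_int.loglik_)
    p_int = float(stats.chi2.sf(max(chi2_int, 0.0), 2))
    table = [{"term": "sex:temperature", "statistic": "chi2",
              "value": max(chi2_int, 0.0), "df": 2, "p": p_int,
              "kept": p_int < alpha}]
    if p_int < alpha:
        kept = full_terms
        final, names = full, ["const"] + full_terms
    else:
        kept = ["temperature_z", "temperature_z2", "sex"]
        sub = {"sex": ["temperature_z", "temperature_z2"],
               "temperature": ["sex"]}
        for term, remaining in sub.items():
            reduced, _ = fit_terms(remaining)
            chi2 = max(2.0 * (no_int.loglik_ - reduced.loglik_), 0.0)
            ddf = 1 if term == "sex" else 2
            p = float(stats.chi2.sf(chi2, ddf))
            table.append({"term": term, "statistic": "chi2", "value": chi2,
                          "df": ddf, "p": p, "kept": p < alpha})
        drop = [t["term"] for t in table[1:] if not t["kept"]]
        if "sex" in drop:
            kept = [k for k in kept if k != "sex"]
        if "temperature" in drop:
            kept = [k for k in kept if not k.startswith("temperature")]
        final, names = fit_terms(kept)
    coefs = {name: {"estimate": float(est), "se": float(se)}
             for name, est, se in zip(names, final.params_, final.bse_)}
    return FittedModel(formula="devtime ~ " + " + ".join(kept or ["1"]),
                       family="poisson-mixed", coefficients=coefs,
                       reduction_table=table,
                       random_effect_sd=final.sigma_, loglik=final.loglik_,
                       extras={"n": int(len(df)),
                               "n_vials": int(df["vial_id"].nunique())})


# ---------------------------------------------------------------------------
# OPLS phenotype targets
# ---------------------------------------------------------------------------

def phenotype_targets(flies: pd.DataFrame, vials: pd.DataFrame,
                      spectra_meta: pd.DataFrame) -> pd.DataFrame:
    """Condition-level phenotype values for each spectrum sample.

    Developmental time is averaged per sex x temperature; viability is
    pooled over sexes per temperature (no sex-specific counts exist).
    Returns a DataFrame indexed by sample_id with columns ``devtime`` and
    ``viability``.
    """
    dev = flies[flies["trait"] == "devtime"]
    dev_means = dev.groupby(["sex", "temperature_C"])["value"].mean()
    via = vials.groupby("temperature_C").apply(
        lambda d: d["adults"].sum() / d["eggs"].sum(), include_groups=False)
    rows = {}
    for row in spectra_meta.itertuples(index=False):
        key = (row.sex, row.temperature_C)
        if key not in dev_means.index:
            raise ValidationError(
                f"no developmental-time data for condition {key}")
        if row.temperature_C not in via.index:
            raise ValidationError(
                f"no viability data for temperature {row.temperature_C:g}")
        rows[row.sample_id] = {"devtime": float(dev_means[key]),
                               "viability": float(via[row.temperature_C])}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")
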