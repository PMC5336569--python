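"""End-to-end orchestration: simulate -> preprocess -> chemometrics ->
reaction norms -> phenotypes -> report, under a single validated config
with full provenance (config hash + seed stamped on every artifact).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chemometrics as chem
from . import phenotype_models as phen
from . import reaction_norms as rn
from . import spectra_prep as prep
from . import synthetic_data as synth
from .containers import FeatureMatrix, SpectrumSet
from .errors import ValidationError
from .io import write_json

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_report",
           "score_recovery", "parse_components"]


def parse_components(a) -> tuple[int, int]:
    """Parse a component count: the conventional '1+n' string (1 predictive
    + n orthogonal) or a bare integer n of orthogonal components."""
    if isinstance(a, int):
        return 1, a
    parts = str(a).split("+")
    if len(parts) != 2 or not all(p.strip().isdigit() for p in parts):
        raise ValidationError(f"cannot parse component count {a!r}")
    pred, orth = (int(p) for p in parts)
    if pred != 1:
        raise ValidationError("OPLS uses exactly 1 predictive component")
    return pred, orth


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    seed: int = 0
    design: dict = field(default_factory=dict)
    nuisance: dict = field(default_factory=dict)
    background: dict = field(default_factory=dict)
    effect_size: float = 0.6
    sex_magnitude: float = 0.5
    align_max_shift: float = 0.02
    bin_width: float | None = None
    components: dict = field(default_factory=lambda: {
        "linear_prior": "1+2", "ushape_prior": "1+1",
        "devtime": "1+2", "viability": "1+2"})
    oplsda_n_pred: int = 2
    oplsda_n_orth: int | str = "cv"  # "cv": selected from {0..3} by CV accuracy
    pca_components: int = 2
    holm_assumed_m: int = 100
    holm_alpha: float = 0.05
    sexdiff_components: int = 5
    outdir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        for sub, target in (("design", synth.SimulationDesign),
                            ("nuisance", synth.NuisanceModel),
                            ("background", synth.BackgroundModel)):
            extra = set(getattr(cfg, sub)) - {f.name for f in fields(target)}
            if extra:
                raise ValidationError(f"unknown {sub} keys: {sorted(extra)}")
        for key in cfg.components:
            parse_components(cfg.components[key])
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- factories ------------------------------------------------------
    def build_design(self) -> synth.SimulationDesign:
        d = dict(self.design)
        for key in ("temperatures", "sexes", "ppm_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return synth.SimulationDesign(**d)

    def build_nuisance(self) -> synth.NuisanceModel:
        return synth.NuisanceModel(**self.nuisance)

    def build_background(self) -> synth.BackgroundModel:
        b = dict(self.background)
        if "positions" in b:
            b["positions"] = tuple(b["positions"])
        return synth.BackgroundModel(**b)


@dataclass
class ReportBundle:
    """Everything a run produces, ready for rendering."""

    config: dict
    config_hash: str
    seed: int
    opls_table: pd.DataFrame
    correlations: pd.DataFrame
    classification: pd.DataFrame
    confusion: pd.DataFrame
    truth: pd.DataFrame
    newick: str
    dendrogram_labels: list[str]
    phenotype_fits: dict[str, phen.FittedModel]
    sexdiff_fits: dict[str, dict]
    sexdiff_score_length: pd.Series
    rotation_summary: dict[str, float]
    oplsda_n_orth: int


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _simulate_stage(cfg: PipelineConfig):
    design = cfg.build_design()
    truths = synth.default_metabolite_truths(effect_size=cfg.effect_size,
                                             sex_magnitude=cfg.sex_magnitude)
    raw = synth.simulate_spectra(design, truths, cfg.build_nuisance(),
                                 seed=cfg.seed, background=cfg.build_background())
    flies, vials = synth.simulate_phenotypes(design, seed=cfg.seed)
    return design, truths, raw, flies, vials


def preprocess(raw: SpectrumSet, max_shift: float = 0.02,
               bin_width: float | None = None
               ) -> tuple[SpectrumSet, FeatureMatrix]:
    """Reference -> align -> trim -> normalize -> feature matrix."""
    sset = prep.reference_set(raw)
    sset = prep.align_set(sset, max_shift=max_shift)
    sset = prep.trim_set(sset)
    sset = prep.normalize_total(sset)
    return sset, prep.to_feature_matrix(sset, bin_width=bin_width)


def _condition_labels(meta: pd.DataFrame) -> np.ndarray:
    return np.array([f"{'F' if s == 'female' else 'M'}{t:g}"
                     for s, t in zip(meta["sex"], meta["temperature_C"])])


def _opls_row(fm_sub: FeatureMatrix, y: np.ndarray, groups: np.ndarray,
              n_orth: int, parameter: str, metabolome: str) -> tuple[dict, chem.OPLS]:
    scaled = prep.pareto_scale(fm_sub, centered=True)
    model = chem.OPLS(n_orthogonal=n_orth).fit(scaled.X, y)
    model.q2_ = chem.grouped_q2(fm_sub.X, y, groups, n_orth=n_orth)
    row = {"predicted_parameter": parameter, "metabolome": metabolome,
           "A": model.A_, "N": model.n_samples_,
           "R2": round(model.R2X_, 4), "R2Y": round(model.R2Y_, 4),
           "Q2": round(model.q2_, 4)}
    return row, model


def _diff_to_spectrumset(diff: FeatureMatrix) -> SpectrumSet:
    ppm = np.asarray(diff.values.columns, dtype=float)
    meta = pd.DataFrame({
        "sample_id": diff.values.index,
        "sex": "difference",
        "temperature_C": diff.meta["temperature_C"].to_numpy(),
        "replicate": 0,
    })
    return SpectrumSet(ppm, diff.X, meta)


def run_pipeline(cfg: PipelineConfig, cache_dir=None) -> ReportBundle:
    """Execute every stage in order and return the report bundle.

    With ``cache_dir`` set, the simulated and preprocessed spectra are
    cached on disk keyed by the config hash, and re-runs reuse them.
    """
    defs = rn.load_metabolite_definitions()
    if cfg.holm_assumed_m < len(defs):
        raise ValidationError(
            f"holm_assumed_m={cfg.holm_assumed_m} < {len(defs)} tested metabolites")

    design, truths, raw, flies, vials = _cached_inputs(cfg, cache_dir)
    sset, fm = preprocess(raw, max_shift=cfg.align_max_shift,
                          bin_width=cfg.bin_width)

    # -- phenotype models ----------------------------------------------
    fits = {
        "ctmin": phen.fit_thermal_limit(flies, "ctmin"),
        "ctmax": phen.fit_thermal_limit(flies, "ctmax"),
        "viability": phen.fit_viability(vials),
        "devtime": phen.fit_devtime(flies),
    }
    targets = phen.phenotype_targets(flies, vials, sset.meta)
    targets = targets.loc[fm.values.index]

    # -- per-sex PCA, rotation, OPLS models -----------------------------
    temps_all = fm.meta["temperature_C"].to_numpy(dtype=float)
    opls_rows: list[dict] = []
    score_targets: dict[tuple[str, str], np.ndarray] = {}
    rotation_summary: dict[str, float] = {}
    sex_masks = {"female": (fm.meta["sex"] == "female").to_numpy(),
                 "male": (fm.meta["sex"] == "male").to_numpy()}
    for sex in ("male", "female"):
        mask = sex_masks[sex]
        sub = FeatureMatrix(fm.values.loc[mask], fm.meta.loc[mask],
                            normalized=fm.normalized, scaling=fm.scaling)
        temps = temps_all[mask]
        scaled = prep.pareto_scale(sub, centered=True)
        pca = chem.PCAModel(n_components=cfg.pca_components, center=True).fit(scaled.X)
        rot = chem.rotate_to_target(pca, temps)
        rotation_summary[f"r_linear_{sex}"] = round(rot.r_linear, 4)
        rotation_summary[f"angle_deg_{sex}"] = round(np.degrees(rot.angle), 2)
        score_targets[("linear_component", sex)] = rot.linear_scores
        score_targets[("ushape_component", sex)] = rot.ushape_scores

        label = sex.capitalize()
        ys = {
            "Linear prior": temps,
            "U-shape prior": rn.ushape_prior_encoding(temps),
            "Developmental time": targets["devtime"].to_numpy()[mask],
        }
        key_of = {"Linear prior": "linear_prior", "U-shape prior": "ushape_prior",
                  "Developmental time": "devtime"}
        for parameter, y in ys.items():
            n_orth = parse_components(cfg.components[key_of[parameter]])[1]
            row, model = _opls_row(sub, y, temps, n_orth, parameter, label)
            opls_rows.append(row)
            score_targets[(key_of[parameter], sex)] = model.scores_

    # viability: sexes pooled
    n_orth = parse_components(cfg.components["viability"])[1]
    y_via = targets["viability"].to_numpy()
    row, model = _opls_row(fm, y_via, _condition_labels(fm.meta), n_orth,
                           "Egg-to-adult viability", "Both")
    opls_rows.append(row)
    score_targets[("viability", "both")] = model.scores_
    opls_table = pd.DataFrame(opls_rows)

    # -- OPLS-DA + Ward HCA over sex x temperature conditions -----------
    classes = _condition_labels(fm.meta)
    if cfg.oplsda_n_orth == "cv":
        accs = {}
        for k in range(4):
            accs[k] = chem.cross_val_accuracy(fm.X, classes,
                                              n_pred=cfg.oplsda_n_pred,
                                              n_orth=k, seed=cfg.seed)
        chosen_orth = max(sorted(accs), key=lambda k: accs[k])
    else:
        chosen_orth = int(cfg.oplsda_n_orth)
    oplsda = chem.OPLSDA(n_predictive=cfg.oplsda_n_pred,
                         n_orthogonal=chosen_orth).fit(fm.X, classes)
    labels, means = oplsda.condition_mean_scores(classes)
    dendro = chem.hca_ward(means, labels)
    newick = dendro.to_newick()

    # -- sex-difference analysis ----------------------------------------
    diff = rn.sex_difference_matrix(sset)
    sexdiff = rn.sex_difference_analysis(diff, n_components=cfg.sexdiff_components)

    # -- metabolite-level correlations ----------------------------------
    defs, skipped_defs = rn.filter_integrable(sset, defs)
    table = rn.integrate_metabolites(sset, defs)
    results: list[rn.CorrelationResult] = []
    for sex in ("male", "female"):
        mask = sex_masks[sex]
        sub_set = sset.select(mask)
        sub_table = rn.MetaboliteIntensityTable(
            values=table.values.loc[mask], meta=table.meta.loc[mask])
        for target in ("linear_component", "ushape_component", "linear_prior",
                       "ushape_prior", "devtime"):
            y = (score_targets[(target, sex)] if (target, sex) in score_targets
                 else targets["devtime"].to_numpy()[mask])
            results += rn.correlate_with_target(sub_table, y, defs, sub_set,
                                                target=target, sex_context=sex)
    results += rn.correlate_with_target(table, score_targets[("viability", "both")],
                                        defs, sset, target="viability",
                                        sex_context="both")
    diff_set = _diff_to_spectrumset(diff)
    diff_table = rn.integrate_metabolites(diff_set, defs)
    results += rn.correlate_with_target(diff_table,
                                        sexdiff.pc1_scores.to_numpy(),
                                        defs, diff_set, target="sexdiff",
                                        sex_context="both")
    results = rn.holm_significance(results, assumed_m=cfg.holm_assumed_m,
                                   alpha=cfg.holm_alpha)
    classification = rn.classify_reaction_norms(results)
    truth = synth.truth_table(truths)
    confusion = _confusion(classification, truth)

    corr_df = pd.DataFrame([{
        "metabolite": r.metabolite, "target": r.target,
        "sex_context": r.sex_context, "r": None if r.excluded else round(r.r, 4),
        "p": None if r.excluded else r.p, "significant": r.significant,
        "verified": r.verified, "excluded": r.excluded,
    } for r in results])

    return ReportBundle(
        config=cfg.to_dict(), config_hash=cfg.hash(), seed=cfg.seed,
        opls_table=opls_table, correlations=corr_df,
        classification=classification, confusion=confusion, truth=truth,
        newick=newick, dendrogram_labels=list(dendro.labels),
        phenotype_fits=fits, sexdiff_fits=sexdiff.cubic_fits,
        sexdiff_score_length=sexdiff.score_length,
        rotation_summary=rotation_summary, oplsda_n_orth=int(chosen_orth))


def _cached_inputs(cfg: PipelineConfig, cache_dir):
    if cache_dir is None:
        return _simulate_stage(cfg)
    cache = Path(cache_dir) / cfg.hash()
    raw_npz = cache / "raw.npz"
    if raw_npz.exists():
        design = cfg.build_design()
        truths = synth.default_metabolite_truths(effect_size=cfg.effect_size,
                                                 sex_magnitude=cfg.sex_magnitude)
        data = np.load(raw_npz, allow_pickle=False)
        meta = pd.read_csv(cache / "raw_meta.csv")
        raw = SpectrumSet(data["ppm"], data["intensities"], meta)
        raw.log_step("simulate", seed=cfg.seed, cached=True)
        flies = pd.read_csv(cache / "flies.csv", float_precision="round_trip")
        vials = pd.read_csv(cache / "vials.csv", float_precision="round_trip")
        return design, truths, raw, flies, vials
    design, truths, raw, flies, vials = _simulate_stage(cfg)
    cache.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(raw_npz, ppm=raw.ppm, intensities=raw.intensities)
    raw.meta.to_csv(cache / "raw_meta.csv", index=False)
    # %.17g keeps float64 round-trip exact
    flies.to_csv(cache / "flies.csv", index=False, float_format="%.17g")
    vials.to_csv(cache / "vials.csv", index=False, float_format="%.17g")
    return design, truths, raw, flies, vials


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(classification: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Score recovered reaction-norm labels against the planted truth.

    Returns the fraction of planted linear/U-shape metabolite x sex cells
    with the correct label and sign, and whether any planted-null metabolite
    was flagged on a temperature target in either sex.
    """
    cls = classification.set_index(["metabolite", "sex"])
    planted_ok = planted_total = 0
    null_flagged = []
    for row in truth.itertuples(index=False):
        for sex in ("female", "male"):
            if (row.name, sex) not in cls.index:
                continue  # not testable (integration range trimmed away)
            got = cls.loc[(row.name, sex)]
            if row.norm_class.startswith("linear"):
                planted_total += 1
                planted_ok += int(got["linear_sign"] == row.linear_sign)
            elif row.norm_class.startswith("ushape"):
                planted_total += 1
                planted_ok += int(got["ushape_sign"] == row.ushape_sign)
            elif row.norm_class == "null":
                if got["label"] != "none":
                    null_flagged.append((row.name, sex))
    return {
        "planted_correct_fraction": planted_ok / max(planted_total, 1),
        "n_planted_cells": planted_total,
        "null_flagged": null_flagged,
        "any_null_flagged": bool(null_flagged),
    }


def _confusion(classification: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    merged = classification.merge(truth.rename(columns={"name": "metabolite"}),
                                  on="metabolite")
    return (merged.groupby(["norm_class", "label"]).size()
            .rename("count").reset_index())


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fit_to_dict(f: phen.FittedModel) -> dict:
    return {
        "formula": f.formula, "family": f.family,
        "coefficients": f.coefficients, "reduction_table": f.reduction_table,
        "dispersion": f.dispersion, "random_effect_sd": f.random_effect_sd,
        "loglik": f.loglik, "extras": f.extras,
    }


def _phenotype_text(fits: dict[str, phen.FittedModel]) -> str:
    lines = ["Trait\tTerm\tEstimate\tSE\tStatistic(df)\tP"]
    for trait, f in fits.items():
        for row in f.to_rows():
            est = "" if row["estimate"] is None else f"{row['estimate']:.4g}"
            se = "" if row["se"] is None else f"{row['se']:.4g}"
            stat = ("" if row["statistic"] is None
                    else f"{row['statistic']:.4g}({row['df']})")
            p = "" if row["p"] is None else f"{row['p']:.4g}"
            lines.append(f"{trait}\t{row['term']}\t{est}\t{se}\t{stat}\t{p}")
    return "\n".join(lines) + "\n"


def render_report(bundle: ReportBundle, outdir) -> dict[str, Path]:
    """Write the report bundle as CSV/JSON/Newick artifacts plus a
    human-readable summary; every artifact is stamped via the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def save_csv(name: str, df: pd.DataFrame):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p

    save_csv("opls_models", bundle.opls_table)
    save_csv("correlations", bundle.correlations)
    save_csv("classification", bundle.classification)
    save_csv("confusion", bundle.confusion)
    save_csv("truth_table", bundle.truth)
    paths["dendrogram"] = out / "dendrogram.newick"
    paths["dendrogram"].write_text(bundle.newick + "\n")
    paths["phenotypes_json"] = write_json(
        {k: _fit_to_dict(f) for k, f in bundle.phenotype_fits.items()},
        out / "phenotypes.json")
    paths["phenotypes_txt"] = out / "phenotypes.txt"
    paths["phenotypes_txt"].write_text(_phenotype_text(bundle.phenotype_fits))
    paths["sexdiff"] = write_json(
        {"cubic_fits": bundle.sexdiff_fits,
         "score_length_by_temperature":
             {f"{k:g}": v for k, v in bundle.sexdiff_score_length.items()}},
        out / "sexdiff.json")

    sig = bundle.classification[bundle.classification["label"] != "none"]
    lines = [f"acclimet run {bundle.config_hash} (seed {bundle.seed})", ""]
    if sig.empty:
        lines.append("No metabolite reached significance on any target.")
    else:
        for (label, sex), grp in sig.groupby(["label", "sex"]):
            mets = ", ".join(sorted(grp["metabolite"]))
            lines.append(f"{label} ({sex}): {mets}")
    lines += ["", "OPLS model table:", bundle.opls_table.to_string(index=False)]
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")

    paths["manifest"] = write_json(
        {"config_hash": bundle.config_hash, "seed": bundle.seed,
         "config": bundle.config,
         "oplsda_n_orth": bundle.oplsda_n_orth,
         "rotation": bundle.rotation_summary,
         "artifacts": sorted(p.name for p in paths.values())},
        out / "manifest.json")
    return paths
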