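"""Metabolite-level analysis: catalogue loading, range integration,
correlation screening with shift verification, the sequential Bonferroni
rule, reaction-norm labels, and the sex-difference construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acclimet.errors import ValidationError
from acclimet.reaction_norms import (CorrelationResult, MetaboliteDefinition,
                                     classify_reaction_norms,
                                     correlate_with_target, holm_significance,
                                     integrate_metabolites,
                                     load_metabolite_definitions,
                                     sex_difference_analysis,
                                     sex_difference_matrix,
                                     ushape_prior_encoding)
from conftest import make_set


# ---------------------------------------------------------------------------
# catalogue
# ---------------------------------------------------------------------------

class TestCatalogue:
    def test_bundled_catalogue_entries(self):
        defs = {d.name: d for d in load_metabolite_definitions()}
        assert len(defs) == 30
        assert defs["Glucose"].shifts == (5.21,)
        assert defs["Glucose"].integration_range == (5.213, 5.207)
        assert defs["AMP"].shifts == (8.60, 8.25, 6.13)
        assert defs["AMP"].integration_range == (8.609, 8.584)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValidationError, match="exceed"):
            MetaboliteDefinition("bad", (2.0,), (1.9, 2.1))

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "defs.csv"
        p.write_text("name,shifts,range_high,range_low\n"
                     "A,2.0,2.01,1.99\nA,3.0,3.01,2.99\n")
        with pytest.raises(ValidationError, match="duplicate"):
            load_metabolite_definitions(p)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _lorentzian(ppm, center, area, fwhm=0.002):
    g = fwhm / 2
    return area * (g / np.pi) / ((ppm - center) ** 2 + g ** 2)


class TestIntegration:
    def test_zero_spectra_integrate_to_zero(self):
        ppm = np.linspace(9.5, 0.5, 9001)
        sset = make_set(ppm, np.zeros((2, ppm.size)))
        table = integrate_metabolites(sset, [
            MetaboliteDefinition("A", (2.0,), (2.05, 1.95))])
        assert (table.values.to_numpy() == 0).all()

    def test_unit_lorentzian_integral_within_two_percent(self):
        ppm = np.linspace(9.5, 0.5, 9001)
        step = 0.001
        sset = make_set(ppm, _lorentzian(ppm, 2.0, 1.0)[None, :])
        table = integrate_metabolites(sset, [
            MetaboliteDefinition("A", (2.0,), (2.1, 1.9))])
        # sum over grid points ~ area / step for a window >> FWHM
        assert table.values.iloc[0, 0] == pytest.approx(1.0 / step, rel=0.02)

    def test_range_outside_window_names_metabolite(self):
        ppm = np.linspace(9.5, 5.0, 4501)
        sset = make_set(ppm, np.ones((1, ppm.size)))
        with pytest.raises(ValidationError, match="Alanine"):
            integrate_metabolites(sset, [
                MetaboliteDefinition("Alanine", (1.47,), (1.474, 1.460))])

    def test_dilution_invariance_after_normalization(self):
        from acclimet.spectra_prep import normalize_total
        ppm = np.linspace(9.5, 0.5, 9001)
        base = _lorentzian(ppm, 2.0, 1.0) + _lorentzian(ppm, 7.0, 2.0)
        sset = make_set(ppm, np.vstack([base, 3.7 * base]))
        table = integrate_metabolites(normalize_total(sset), [
            MetaboliteDefinition("A", (2.0,), (2.1, 1.9))])
        vals = table.values.to_numpy().ravel()
        assert vals[0] == pytest.approx(vals[1], abs=1e-9)


# ---------------------------------------------------------------------------
# correlation + verification
# ---------------------------------------------------------------------------

class TestCorrelation:
    def test_perfect_correlation(self):
        ppm = np.linspace(9.5, 0.5, 9001)
        t = np.arange(10, dtype=float)
        rows = np.array([_lorentzian(ppm, 2.0, 1.0 + v) for v in t])
        sset = make_set(ppm, rows)
        defs = [MetaboliteDefinition("A", (2.0,), (2.1, 1.9))]
        table = integrate_metabolites(sset, defs)
        res = correlate_with_target(table, t, defs, sset)[0]
        assert res.r == pytest.approx(1.0) and res.p < 1e-10

    def test_planted_linear_down_negative_at_all_shifts(self, design):
        from acclimet.synthetic_data import (BackgroundModel, MetaboliteTruth,
                                             NuisanceModel, simulate_spectra)
        truth = MetaboliteTruth("M", (3.0, 6.0), (3.05, 2.95), "linear_down",
                                effect_size=0.6)
        sset = simulate_spectra(design, [truth], NuisanceModel.none(), seed=0,
                                background=BackgroundModel.none())
        defs = [MetaboliteDefinition("M", (3.0, 6.0), (3.05, 2.95))]
        table = integrate_metabolites(sset, defs)
        t = sset.meta["temperature_C"].to_numpy(float)
        res = correlate_with_target(table, t, defs, sset)[0]
        assert res.r == pytest.approx(-1.0, abs=1e-9)
        assert res.verified is True
        assert all(r < -0.999 for r in res.shift_correlations.values())

    def test_constant_column_excluded_with_warning(self):
        ppm = np.linspace(9.5, 0.5, 901)
        sset = make_set(ppm, np.ones((5, ppm.size)))
        defs = [MetaboliteDefinition("A", (2.0,), (2.1, 1.9))]
        table = integrate_metabolites(sset, defs)
        with pytest.warns(UserWarning, match="constant"):
            res = correlate_with_target(table, np.arange(5.0), defs, sset)[0]
        assert res.excluded and np.isnan(res.p)


# ---------------------------------------------------------------------------
# sequential Bonferroni
# ---------------------------------------------------------------------------

def _results(ps):
    return [CorrelationResult(f"m{i}", "linear_prior", "male", 0.5, p)
            for i, p in enumerate(ps)]


def brute_force_holm(ps, m, alpha):
    """Explicit prefix check of the step-down rule."""
    order = np.argsort(ps)
    flags = [False] * len(ps)
    for rank, idx in enumerate(order, start=1):
        ok = all(ps[order[j - 1]] <= alpha / (m - j + 1)
                 for j in range(1, rank + 1))
        if not ok:
            break
        flags[idx] = True
    return flags


class TestHolm:
    def test_strictest_threshold_is_alpha_over_assumed_m(self):
        out = holm_significance(_results([0.0004]), assumed_m=100)
        assert out[0].significant
        out = holm_significance(_results([0.0006]), assumed_m=100)
        assert not out[0].significant

    def test_all_ones_never_significant(self):
        out = holm_significance(_results([1.0] * 8))
        assert not any(r.significant for r in out)

    def test_assumed_m_smaller_than_tested_rejected(self):
        with pytest.raises(ValidationError):
            holm_significance(_results([0.01] * 5), assumed_m=3)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=12),
           st.integers(12, 100))
    def test_matches_brute_force_prefix_check(self, ps, m):
        out = holm_significance(_results(ps), assumed_m=m)
        assert [r.significant for r in out] == brute_force_holm(ps, m, 0.05)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=10))
    def test_assumed_m_equal_k_is_textbook_holm(self, ps):
        from statsmodels.stats.multitest import multipletests
        out = holm_significance(_results(ps), assumed_m=len(ps))
        oracle = multipletests(ps, alpha=0.05, method="holm")[0]
        assert [r.significant for r in out] == oracle.tolist()


class TestUshapeEncoding:
    @pytest.mark.parametrize("t,code", [
        (12.0, 1), (15.5, 1), (31.0, 1), (32.0, 1),
        (18.0, 0), (20.0, 0), (22.0, 0), (25.0, 0), (27.0, 0), (29.5, 0)])
    def test_two_state_encoding(self, t, code):
        assert ushape_prior_encoding([t])[0] == code

    def test_unknown_temperature_rejected(self):
        with pytest.raises(ValidationError):
            ushape_prior_encoding([16.0])


class TestClassification:
    def _res(self, met, target, sex, r, sig):
        return CorrelationResult(met, target, sex, r, 1e-6 if sig else 0.5,
                                 significant=sig)

    def test_labels_follow_significance_and_sign(self):
        results = [
            self._res("P", "linear_component", "male", -0.9, True),
            self._res("P", "linear_prior", "male", -0.8, True),
            self._res("N", "linear_component", "male", 0.2, False),
            self._res("N", "ushape_prior", "male", 0.1, False),
            self._res("U", "ushape_component", "male", -0.7, True),
            self._res("U", "ushape_prior", "male", -0.75, True),
        ]
        out = classify_reaction_norms(results).set_index("metabolite")
        assert out.loc["P", "label"] == "linear-"
        assert out.loc["N", "label"] == "none"
        assert out.loc["U", "label"] == "ushape-"

    def test_both_shapes_may_coexist(self):
        results = [
            self._res("X", "linear_prior", "female", 0.8, True),
            self._res("X", "ushape_prior", "female", -0.7, True),
        ]
        out = classify_reaction_norms(results)
        assert out.iloc[0]["label"] == "linear+/ushape-"


# ---------------------------------------------------------------------------
# sex differences
# ---------------------------------------------------------------------------

def _paired_set(f_rows, m_rows, temperatures):
    ppm = np.linspace(9.5, 0.5, f_rows.shape[1])
    rows = np.vstack([f_rows, m_rows])
    sexes = ["female"] * len(f_rows) + ["male"] * len(m_rows)
    temps = list(temperatures) * 2
    return make_set(ppm, rows, temperatures=temps, sexes=sexes)


class TestSexDifference:
    def test_identical_sexes_give_zero_matrix(self):
        rows = np.tile(np.linspace(1, 2, 50), (4, 1))
        sset = _paired_set(rows, rows, [12.0, 12.0, 22.0, 22.0])
        diff = sex_difference_matrix(sset)
        assert np.allclose(diff.X, 0.0)

    def test_row_count_per_temperature(self, noiseless_spectra):
        diff = sex_difference_matrix(noiseless_spectra)
        counts = diff.meta.groupby("temperature_C").size()
        assert (counts == 10).all() and len(diff.values) == 100

    def test_constant_offset_appears_in_every_row(self):
        base = np.tile(np.linspace(1, 2, 50), (2, 1))
        f = base.copy()
        f[:, 10] += 0.5  # planted female-male offset at one peak
        sset = _paired_set(f, base, [12.0, 12.0])
        diff = sex_difference_matrix(sset)
        np.testing.assert_allclose(diff.X[:, 10], 0.5, atol=1e-12)

    def test_missing_sex_rejected(self):
        rows = np.ones((2, 30))
        ppm = np.linspace(9.5, 0.5, 30)
        sset = make_set(ppm, rows, temperatures=[12.0, 12.0],
                        sexes=["female", "female"])
        with pytest.raises(ValidationError, match="missing"):
            sex_difference_matrix(sset)

    def test_sex_swap_negates_rows(self, noiseless_spectra):
        diff = sex_difference_matrix(noiseless_spectra)
        swapped = noiseless_spectra.copy_with()
        swapped.meta["sex"] = swapped.meta["sex"].map(
            {"female": "male", "male": "female"})
        diff_sw = sex_difference_matrix(swapped)
        a = np.sort(diff.X, axis=0)
        b = np.sort(-diff_sw.X, axis=0)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_matrix_yields_zero_scores_with_warning(self):
        rows = np.tile(np.linspace(1, 2, 40), (4, 1))
        sset = _paired_set(rows, rows, [12.0, 12.0, 22.0, 22.0])
        diff = sex_difference_matrix(sset)
        with pytest.warns(UserWarning, match="zero"):
            res = sex_difference_analysis(diff)
        assert (res.pc1_scores == 0).all()
        assert (res.score_length == 0).all()

    def test_cubic_fit_degrees_of_freedom(self, noiseless_spectra):
        diff = sex_difference_matrix(noiseless_spectra)
        res = sex_difference_analysis(diff)
        # 50 rows per tagging, 4 coefficients -> (3, 46)
        assert res.cubic_fits["F-medM"]["df"] == (3, 46)
        assert res.cubic_fits["medF-M"]["df"] == (3, 46)
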